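"""Domain types for protein structures and conformational ensembles.

The data model is deliberately small: a structure is an ordered list of
residues, each an ordered list of atoms with Ångström coordinates; an
ensemble is one topology plus a stack of coordinate frames, standing in
for an exported molecular-dynamics trajectory at one temperature.

Coordinates are Ångström everywhere.  Residue numbering is the author
numbering from the PDB file (1-based, inclusive ranges).  Multi-model
PDB is the only ensemble carrier; binary trajectory formats are out of
scope — export frames to PDB first.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: the 20 standard three-letter amino-acid codes
STANDARD_AA: frozenset[str] = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}


class PDBFormatError(ValueError):
    """Raised for malformed or unusable PDB input."""


@dataclass(frozen=True)
class ResidueKey:
    """Identity of one residue: chain, author number, insertion code, name.

    Equality and hashing use all four fields; uniqueness inside a
    structure is enforced on the ``(chain_id, resnum, icode)`` triple,
    so the same position may not appear twice even under two names.
    """

    chain_id: str
    resnum: int
    icode: str = ""
    resname: str = ""

    @property
    def position(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resnum, self.icode)

    @property
    def is_standard(self) -> bool:
        return self.resname in STANDARD_AA

    @property
    def label(self) -> str:
        """Compact label like ``G124`` (one-letter code + number)."""
        one = THREE_TO_ONE.get(self.resname, "X")
        return f"{one}{self.resnum}{self.icode}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chain_id}:{self.resname}{self.resnum}{self.icode}"


@dataclass
class AtomRecord:
    """One atom: serial, name, element and Cartesian coordinates (Å)."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.name!r}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: non-finite coordinates")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.serial <= 0:
            raise ValueError("atom serial must be positive")


@dataclass
class Residue:
    key: ResidueKey
    atoms: list[AtomRecord]

    def atom(self, name: str) -> AtomRecord | None:
        """First atom with this name, or None (e.g. CB on glycine)."""
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has(self, name: str) -> bool:
        return self.atom(name) is not None

    def representative_atom(self) -> AtomRecord | None:
        """CB, falling back to CA for residues without a β carbon."""
        return self.atom("CB") or self.atom("CA")


@dataclass
class StructureModel:
    """A single static structure: ordered residues with their atoms."""

    residues: list[Residue]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, int, str], ResidueKey] = {}
        for r in self.residues:
            pos = r.key.position
            if pos in seen:
                raise PDBFormatError(
                    f"duplicate residue key {r.key} (already seen as {seen[pos]})"
                )
            seen[pos] = r.key

    # -- basic views -------------------------------------------------

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    @property
    def keys(self) -> list[ResidueKey]:
        return [r.key for r in self.residues]

    def iter_atoms(self) -> Iterator[tuple[ResidueKey, AtomRecord]]:
        for r in self.residues:
            for a in r.atoms:
                yield r.key, a

    def get(self, key: ResidueKey) -> Residue:
        for r in self.residues:
            if r.key == key or r.key.position == key.position:
                return r
        raise KeyError(f"residue {key} not in structure")

    def find(self, chain_id: str, resnum: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.key.position == (chain_id, resnum, icode):
                return r
        raise KeyError(f"residue {chain_id}:{resnum}{icode} not in structure")

    # -- coordinate access -------------------------------------------

    def all_coords(self) -> np.ndarray:
        """(n_atoms, 3) array in flat atom order."""
        return np.array([a.coords for _, a in self.iter_atoms()], dtype=float)

    def atom_indices(self, names: Sequence[str]) -> np.ndarray:
        """Flat-order indices of atoms whose name is in ``names``."""
        wanted = set(names)
        return np.array(
            [i for i, (_, a) in enumerate(self.iter_atoms()) if a.name in wanted],
            dtype=int,
        )

    def coords(self, names: Sequence[str] = ("CA",)) -> np.ndarray:
        return self.all_coords()[self.atom_indices(names)]

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """Copy of this structure with coordinates replaced (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(
                f"expected coords of shape ({self.n_atoms}, 3), got {coords.shape}"
            )
        out: list[Residue] = []
        i = 0
        for r in self.residues:
            atoms = []
            for a in r.atoms:
                atoms.append(
                    AtomRecord(a.serial, a.name, a.element, coords[i],
                               a.occupancy, a.bfactor)
                )
                i += 1
            out.append(Residue(r.key, atoms))
        return StructureModel(out, dict(self.metadata))

    def same_topology(self, other: "StructureModel") -> bool:
        if len(self) != len(other):
            return False
        for a, b in zip(self.residues, other.residues):
            if a.key != b.key or [x.name for x in a.atoms] != [x.name for x in b.atoms]:
                return False
        return True


@dataclass
class Ensemble:
    """Ordered conformations sharing one topology (an exported trajectory).

    ``frames`` is (n_frames, n_atoms, 3) in Å; ``frame_times`` (ps) is
    optional metadata and must be strictly increasing when present.
    """

    topology: StructureModel
    frames: np.ndarray
    frame_times: list[float] | None = None
    temperature_label: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if self.frame_times is not None:
            t = list(self.frame_times)
            if len(t) != self.n_frames:
                raise ValueError("frame_times length must equal frame count")
            if any(b <= a for a, b in zip(t, t[1:])):
                raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, index: int) -> StructureModel:
        return self.topology.with_coords(self.frames[index])


@dataclass(frozen=True)
class ResidueRange:
    """Inclusive residue range on one chain, e.g. residues 238–245."""

    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"range start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def sites(self) -> list[int]:
        return list(range(self.start, self.end + 1))

    def __contains__(self, resnum: int) -> bool:
        return self.start <= resnum <= self.end

    @classmethod
    def parse(cls, text: str, default_chain: str = "A") -> "ResidueRange":
        """Parse ``"A:2-6"`` (or ``"2-6"``, or a single ``"124"``)."""
        chain, _, span = text.strip().rpartition(":")
        chain = chain or default_chain
        if "-" in span.lstrip("-"):
            lo, hi = span.rsplit("-", 1)
            return cls(chain, int(lo), int(hi))
        return cls(chain, int(span), int(span))

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.start}-{self.end}"


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def _prescan_atom_lines(path: Path) -> int:
    """Count ATOM records and fail fast on duplicate residue keys.

    The permissive parser would silently merge a residue that appears
    twice; here a key that re-appears after a different key, or under a
    different residue name, is an error naming the key.
    """
    n_atom = 0
    last: tuple[str, int, str] | None = None
    seen: dict[tuple[str, int, str], str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("ENDMDL"):
                break  # duplicate keys across models are expected
            if not line.startswith("ATOM"):
                continue
            n_atom += 1
            chain = line[21].strip()
            resnum = int(line[22:26])
            icode = line[26].strip()
            resname = line[17:20].strip()
            pos = (chain, resnum, icode)
            if pos in seen:
                if pos != last or seen[pos] != resname:
                    raise PDBFormatError(
                        f"duplicate residue key {chain}:{resnum}{icode} "
                        f"({seen[pos]} vs {resname}) in {path}"
                    )
            seen[pos] = resname
            last = pos
    return n_atom


def _convert_biopdb_model(model, metadata: dict) -> StructureModel:
    """Translate one Bio.PDB model into our StructureModel."""
    residues: list[Residue] = []
    het: list[str] = []
    for chain in model:
        for res in chain:
            hetflag, resnum, icode = res.id
            if hetflag.strip():
                het.append(f"{res.resname.strip()} {chain.id}:{resnum}{icode.strip()}")
                continue
            key = ResidueKey(chain.id, resnum, icode.strip(), res.resname.strip())
            atoms: list[AtomRecord] = []
            for atom in res:
                if atom.is_disordered():
                    ids = atom.disordered_get_id_list()
                    pick = "A" if "A" in ids else ids[0]
                    logger.warning(
                        "residue %s atom %s: keeping altloc %r, dropping %s",
                        key, atom.get_id(), pick, [i for i in ids if i != pick],
                    )
                    atom = atom.disordered_get(pick)
                elif atom.get_altloc() not in (" ", "", "A"):
                    continue
                atoms.append(
                    AtomRecord(
                        serial=atom.serial_number or len(atoms) + 1,
                        name=atom.get_name(),
                        element=(atom.element or "").strip() or atom.get_name()[0],
                        coords=np.asarray(atom.coord, dtype=float),
                        occupancy=float(atom.get_occupancy() or 1.0),
                        bfactor=float(atom.get_bfactor() or 0.0),
                    )
                )
            residues.append(Residue(key, atoms))
    if het:
        metadata["hetatm"] = het
    return StructureModel(residues, metadata)


def _parse_pdb(path: str | Path):
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    if _prescan_atom_lines(path) == 0:
        raise PDBFormatError(f"no ATOM records in {path}")
    parser = PDBParser(QUIET=True)
    return parser.get_structure(path.stem, str(path))


def read_pdb(path: str | Path) -> StructureModel:
    """Read a single-model PDB file (MODEL 1 of a multi-model file).

    HETATM records are noted in ``metadata["hetatm"]`` and excluded from
    the residue list.  Alternate locations keep altloc 'A' or blank.
    """
    bio = _parse_pdb(path)
    model = next(iter(bio))
    return _convert_biopdb_model(model, {"source": str(path)})


def read_ensemble(path: str | Path, temperature_label: float | None = None) -> Ensemble:
    """Read a multi-model PDB file as a conformational ensemble.

    Frames follow MODEL order; the topology is taken from the first
    model.  Every model must contain the same number of atoms.
    """
    bio = _parse_pdb(path)
    models = list(bio)
    topology = _convert_biopdb_model(models[0], {"source": str(path)})
    n_ref = topology.n_atoms
    frames = np.empty((len(models), n_ref, 3), dtype=float)
    frames[0] = topology.all_coords()
    for i, model in enumerate(models[1:], start=1):
        struct = _convert_biopdb_model(model, {})
        if struct.n_atoms != n_ref:
            raise PDBFormatError(
                f"model {model.id + 1} has {struct.n_atoms} atoms but model "
                f"{models[0].id + 1} has {n_ref} ({path})"
            )
        frames[i] = struct.all_coords()
    return Ensemble(topology, frames, temperature_label=temperature_label)


def _format_atom_line(serial: int, atom: AtomRecord, key: ResidueKey) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3}"
    x, y, z = atom.coords
    return (
        f"ATOM  {serial % 100000:>5} {name:<4} {key.resname:<3} {key.chain_id:1}"
        f"{key.resnum:>4}{key.icode or ' ':1}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
        f"          {atom.element:>2}"
    )


def _model_lines(structure: StructureModel, start_serial: int = 1) -> list[str]:
    lines: list[str] = []
    serial = start_serial
    prev_chain: str | None = None
    for res in structure.residues:
        if prev_chain is not None and res.key.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = res.key.chain_id
        for atom in res.atoms:
            lines.append(_format_atom_line(serial, atom, res.key))
            serial += 1
    lines.append("TER")
    return lines


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write fixed-column PDB; coordinates round to 3 decimals.

    Serial numbers above 99999 wrap, per the fixed-width convention.
    """
    if len(structure) == 0 or structure.n_atoms == 0:
        raise ValueError("refusing to write an empty structure")
    lines = _model_lines(structure)
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL blocks)."""
    if ensemble.n_frames == 0:
        raise ValueError("refusing to write an empty ensemble")
    lines: list[str] = []
    for i in range(ensemble.n_frames):
        lines.append(f"MODEL     {i + 1:>4}")
        lines.extend(_model_lines(ensemble.frame_structure(i)))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
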