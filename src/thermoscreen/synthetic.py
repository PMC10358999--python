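"""Synthetic structures, ensembles and energy tables with known truth.

These generators make every analysis in the package testable without
external downloads: an ideal-geometry helix built from internal
coordinates (so its dihedrals are known exactly), Gaussian-perturbed
ensembles (whose per-residue RMSF has the analytic limit σ·√3), and
mutation-energy tables with neutral background noise and planted
stabilizing entries.

Everything is a pure function of its arguments including the seed.
The Gaussian ensembles are deliberately naive — noise is independent
across atoms and frames, with none of the covariance structure of a
real trajectory — which is exactly what makes their RMSF analytically
checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .energy import MutationEnergyTable, TableKind, canonical_aa
from .model import AtomRecord, Ensemble, Residue, ResidueKey, StructureModel
from .model import ONE_TO_THREE

# ideal backbone internal coordinates (Å, degrees): Engh–Huber-style values
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.5
OMEGA_TRANS = 180.0
#: improper torsion C–N–CA–CB placing the β carbon with L chirality
TORSION_CB = -122.5


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom d from a–b–c."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def make_helix(
    n_residues: int,
    phi: float = -57.0,
    psi: float = -47.0,
    sequence: str | None = None,
    chain_id: str = "A",
) -> StructureModel:
    """Build an ideal poly-alanine backbone with the requested dihedrals.

    Atoms per residue: N, CA, C, O and CB (no CB for glycine).  The
    default (φ, ψ) = (−57°, −47°) is the canonical right-handed α
    helix; any (φ, ψ) pair builds, e.g. φ = +60° for a left-handed
    turn exercising the positive-φ branch of the glycine rule.

    ``sequence`` (1-letter codes) lets callers plant glycines or other
    residue names; geometry stays poly-alanine-like regardless.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues to define interior dihedrals")
    if sequence is None:
        sequence = "A" * n_residues
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    try:
        resnames = [ONE_TO_THREE[c.upper()] for c in sequence]
    except KeyError as exc:
        raise ValueError(f"unknown amino-acid code {exc.args[0]!r} in sequence") from None

    # seed atoms of residue 1
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])

    backbone: list[dict[str, np.ndarray]] = [{"N": n0, "CA": ca0, "C": c0}]
    for i in range(1, n_residues):
        prev = backbone[-1]
        n_i = _place(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi)
        ca_i = _place(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        c_i = _place(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        backbone.append({"N": n_i, "CA": ca_i, "C": c_i})

    residues: list[Residue] = []
    serial = 1
    for i, atoms_i in enumerate(backbone):
        resname = resnames[i]
        key = ResidueKey(chain_id, i + 1, "", resname)
        atoms: list[AtomRecord] = []

        def add(name: str, element: str, xyz: np.ndarray) -> None:
            nonlocal serial
            atoms.append(AtomRecord(serial, name, element, xyz))
            serial += 1

        add("N", "N", atoms_i["N"])
        add("CA", "C", atoms_i["CA"])
        add("C", "C", atoms_i["C"])
        # carbonyl O: torsion N–CA–C–O = psi + 180 (anti to the next N)
        add("O", "O", _place(atoms_i["N"], atoms_i["CA"], atoms_i["C"],
                             BOND_C_O, ANGLE_CA_C_O, psi + 180.0))
        if resname != "GLY":
            add("CB", "C", _place(atoms_i["C"], atoms_i["N"], atoms_i["CA"],
                                  BOND_CA_CB, ANGLE_N_CA_CB, TORSION_CB))
        residues.append(Residue(key, atoms))
    return StructureModel(residues, {"source": "synthetic ideal helix"})


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSpec:
    """Recipe for a Gaussian-perturbed synthetic ensemble.

    ``per_residue_sigma`` maps residue number → per-coordinate noise σ
    (Å); unlisted residues use ``default_sigma``.  The analytic RMSF of
    a residue whose only motion is this noise is σ·√3.
    """

    n_frames: int
    per_residue_sigma: Mapping[int, float] = field(default_factory=dict)
    default_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.default_sigma < 0 or any(s < 0 for s in self.per_residue_sigma.values()):
            raise ValueError("sigmas must be non-negative")


def make_ensemble(
    structure: StructureModel,
    spec: EnsembleSpec,
    temperature_label: float | None = None,
) -> Ensemble:
    """Frames = base coordinates + iid Gaussian noise, residue-wise σ.

    Deterministic for a given spec (seed included); frame times are
    spaced 50 ps apart as trajectory-export convention.
    """
    rng = np.random.default_rng(spec.seed)
    base = structure.all_coords()
    sigma_per_atom = np.empty(structure.n_atoms)
    for i, (key, _) in enumerate(structure.iter_atoms()):
        sigma_per_atom[i] = spec.per_residue_sigma.get(key.resnum, spec.default_sigma)
    noise = rng.standard_normal((spec.n_frames, structure.n_atoms, 3))
    frames = base[None, :, :] + noise * sigma_per_atom[None, :, None]
    times = [50.0 * (i + 1) for i in range(spec.n_frames)]
    return Ensemble(structure, frames, frame_times=times,
                    temperature_label=temperature_label)


# ---------------------------------------------------------------------------
# energy tables
# ---------------------------------------------------------------------------

#: background energies stay inside the neutral band by construction
_BACKGROUND_RANGE = (-0.4, 0.4)

_AA20 = sorted(ONE_TO_THREE.values())


def make_energy_table(
    seed: int,
    n_sites: int,
    planted: Sequence[tuple[int, str, float]] = (),
    kind: TableKind = "saturation",
    from_aa: str = "GLY",
) -> MutationEnergyTable:
    """Synthetic mutation-energy table with planted stabilizing entries.

    Background entries are drawn uniform in [−0.4, +0.4] kcal/mol — the
    neutral band — so default-threshold screens return exactly the
    planted sites.  ``planted`` entries (site, to_aa, energy) replace
    the background value verbatim; a site/substitution collision among
    the planted entries raises.
    """
    rng = np.random.default_rng(seed)
    frm = canonical_aa(from_aa)
    entries: dict[tuple, float] = {}
    lo, hi = _BACKGROUND_RANGE
    for site in range(1, n_sites + 1):
        if kind == "alanine_scan":
            if frm != "ALA":
                entries[((site, frm, "ALA"),)] = float(rng.uniform(lo, hi))
        else:
            for to in _AA20:
                if to == frm:
                    entries[((site, frm, to),)] = 0.0  # self row, by convention
                else:
                    entries[((site, frm, to),)] = float(rng.uniform(lo, hi))

    seen: set[tuple[int, str]] = set()
    for site, to_aa, e in planted:
        to3 = canonical_aa(to_aa)
        if (site, to3) in seen:
            raise ValueError(f"planted collision at site {site} -> {to3}")
        seen.add((site, to3))
        if not (1 <= site <= n_sites):
            raise ValueError(f"planted site {site} outside 1..{n_sites}")
        entries[((site, frm, to3),)] = float(e)

    return MutationEnergyTable(entries, engine_tag="synthetic", kind=kind)
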