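"""Trajectory-style analytics over a conformational ensemble.

Per-frame RMSD against a reference, the ensemble-average structure,
the representative frame (closest to the average), per-residue RMSF,
and hydrogen-bond counts per frame.

Windows are frame-index based (``frame_times`` is metadata only).  A
window of ``None`` means the last 75 % of frames — the convention of
discarding the equilibration phase of a production run — except for
per-frame RMSD, which always covers every frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import HBondCriteria, detect_hbonds, kabsch_superpose
from .model import Ensemble, ResidueKey, StructureModel

#: fraction of frames, counted from the end, used when no window is given
DEFAULT_WINDOW_FRACTION = 0.75


def last_fraction_window(n_frames: int, fraction: float = DEFAULT_WINDOW_FRACTION) -> list[int]:
    """Frame indices of the trailing ``fraction`` of an ``n_frames`` run."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    start = int(np.floor(n_frames * (1.0 - fraction)))
    return list(range(start, n_frames))


def _resolve_window(ensemble: Ensemble, window: Sequence[int] | None) -> list[int]:
    if window is None:
        return last_fraction_window(ensemble.n_frames)
    idx = [int(i) for i in window]
    if not idx:
        raise ValueError("empty analysis window")
    if any(i < 0 or i >= ensemble.n_frames for i in idx):
        raise IndexError(f"window index out of range 0..{ensemble.n_frames - 1}")
    return idx


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class RmsdSeries:
    """Per-frame RMSD (Å) of an ensemble against one reference."""

    values: np.ndarray
    reference_tag: str = ""
    selection: tuple[str, ...] = ("CA",)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < -1e-12).any():
            raise ValueError("RMSD values must be non-negative")


@dataclass
class FlexibilityProfile:
    """Per-residue RMSF (Å) at one simulated temperature."""

    values: dict[ResidueKey, float]
    temperature_label: float | None = None
    window: tuple[int, int] | None = None

    @property
    def residues(self) -> list[ResidueKey]:
        return list(self.values.keys())

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["chain\tresnum\ticode\tresname\trmsf"]
        for k, v in self.values.items():
            lines.append(f"{k.chain_id}\t{k.resnum}\t{k.icode}\t{k.resname}\t{v:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, temperature_label: float | None = None
                 ) -> "FlexibilityProfile":
        values: dict[ResidueKey, float] = {}
        lines = Path(path).read_text().splitlines()
        for line in lines[1:]:
            chain, resnum, icode, resname, rmsf = line.split("\t")
            values[ResidueKey(chain, int(resnum), icode, resname)] = float(rmsf)
        return cls(values, temperature_label=temperature_label)


@dataclass
class HBondSeries:
    """Hydrogen-bond count per frame and its arithmetic mean."""

    counts: np.ndarray
    criteria: HBondCriteria = field(default_factory=HBondCriteria)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("hydrogen-bond counts must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.counts.mean())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _selection_indices(structure: StructureModel, selection: Sequence[str]) -> np.ndarray:
    idx = structure.atom_indices(selection)
    if idx.size < 3:
        raise ValueError(
            f"selection {tuple(selection)} resolves to {idx.size} atoms; need >= 3"
        )
    return idx


def per_frame_rmsd(
    ensemble: Ensemble,
    reference: StructureModel,
    selection: Sequence[str] = ("CA",),
) -> RmsdSeries:
    """RMSD of every frame to ``reference`` after superposition on ``selection``."""
    idx_e = _selection_indices(ensemble.topology, selection)
    idx_r = _selection_indices(reference, selection)
    if idx_e.size != idx_r.size:
        raise ValueError("selection sizes differ between ensemble and reference")
    ref = reference.all_coords()[idx_r]
    out = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        out[f] = kabsch_superpose(ensemble.frames[f][idx_e], ref).rmsd
    tag = reference.metadata.get("source", "reference")
    return RmsdSeries(out, reference_tag=str(tag), selection=tuple(selection))


def _aligned_window_coords(
    ensemble: Ensemble, window: list[int], ca_idx: np.ndarray
) -> np.ndarray:
    """Window frames aligned to their average with one re-averaging pass.

    Align to the first window frame, average; re-align to that average,
    re-average; final alignment to the second-pass mean.  Returns the
    aligned full-atom coordinates (n_window, n_atoms, 3).
    """
    frames = ensemble.frames[window]

    def align_all(target_ca: np.ndarray) -> np.ndarray:
        out = np.empty_like(frames)
        for i, fr in enumerate(frames):
            out[i] = kabsch_superpose(fr[ca_idx], target_ca).apply(fr)
        return out

    aligned = align_all(frames[0][ca_idx])
    mean1 = aligned.mean(axis=0)
    aligned = align_all(mean1[ca_idx])
    mean2 = aligned.mean(axis=0)
    return align_all(mean2[ca_idx])


def average_structure(ensemble: Ensemble, window: Sequence[int] | None = None
                      ) -> StructureModel:
    """Atom-wise mean conformation over the window, after superposition."""
    idx = _resolve_window(ensemble, window)
    ca_idx = _selection_indices(ensemble.topology, ("CA",))
    aligned = _aligned_window_coords(ensemble, idx, ca_idx)
    return ensemble.topology.with_coords(aligned.mean(axis=0))


def representative_frame(ensemble: Ensemble, window: Sequence[int] | None = None) -> int:
    """Window frame index closest (Cα RMSD) to the average structure.

    Ties break toward the lowest frame index.
    """
    idx = _resolve_window(ensemble, window)
    ca_idx = _selection_indices(ensemble.topology, ("CA",))
    avg_ca = average_structure(ensemble, idx).all_coords()[ca_idx]
    best, best_rmsd = idx[0], np.inf
    for f in idx:
        r = kabsch_superpose(ensemble.frames[f][ca_idx], avg_ca).rmsd
        if r < best_rmsd - 1e-15:
            best, best_rmsd = f, r
    return best


def per_residue_rmsf(ensemble: Ensemble, window: Sequence[int] | None = None
                     ) -> FlexibilityProfile:
    """Root-mean-square fluctuation of each residue's Cα over the window.

    Frames are superposed (Cα) onto the window-average structure;
    RMSF(residue) = sqrt(mean over frames of |x − ⟨x⟩|²).
    """
    idx = _resolve_window(ensemble, window)
    if len(idx) < 2:
        raise ValueError("RMSF needs at least 2 frames")
    ca_idx = _selection_indices(ensemble.topology, ("CA",))
    aligned = _aligned_window_coords(ensemble, idx, ca_idx)[:, ca_idx, :]
    mean_pos = aligned.mean(axis=0)
    rmsf = np.sqrt(((aligned - mean_pos) ** 2).sum(axis=2).mean(axis=0))
    flat_atoms = list(ensemble.topology.iter_atoms())
    keys = [flat_atoms[i][0] for i in ca_idx]
    return FlexibilityProfile(
        dict(zip(keys, rmsf.tolist())),
        temperature_label=ensemble.temperature_label,
        window=(min(idx), max(idx)),
    )


def per_residue_rmsd(
    ensemble_a: Ensemble,
    ensemble_b: Ensemble,
    window: Sequence[int] | None = None,
) -> dict[ResidueKey, float]:
    """Per-residue Cα deviation between two ensembles' average structures.

    Both averages are computed over the same window spec; B's average is
    globally superposed (Cα) onto A's before the per-residue distances.
    Typical use: the same system simulated at two temperatures.
    """
    if not ensemble_a.topology.same_topology(ensemble_b.topology):
        raise ValueError("ensembles have different topologies")
    avg_a = average_structure(ensemble_a, window)
    avg_b = average_structure(ensemble_b, window)
    ca_idx = _selection_indices(ensemble_a.topology, ("CA",))
    a_ca = avg_a.all_coords()[ca_idx]
    b_ca = avg_b.all_coords()[ca_idx]
    b_on_a = kabsch_superpose(b_ca, a_ca).apply(b_ca)
    d = np.linalg.norm(a_ca - b_on_a, axis=1)
    flat_atoms = list(ensemble_a.topology.iter_atoms())
    keys = [flat_atoms[i][0] for i in ca_idx]
    return dict(zip(keys, d.tolist()))


def hbond_series(ensemble: Ensemble, criteria: HBondCriteria = HBondCriteria()
                 ) -> HBondSeries:
    """Hydrogen-bond count of every frame (intra-protein, geometric)."""
    counts = [
        len(detect_hbonds(ensemble.frame_structure(f), criteria))
        for f in range(ensemble.n_frames)
    ]
    return HBondSeries(np.asarray(counts), criteria=criteria)
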