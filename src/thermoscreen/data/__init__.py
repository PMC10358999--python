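"""Loaders for the packaged tyrosinase reference data.

The package ships the published screening inputs for the
*Streptomyces cyaneofuscatus* tyrosinase case study as plain-text
files: the glycine φ table, the alanine-scanning and saturation
mutation-energy tables, the double-mutant energies, two FoldX single
ΔΔG values, and the region annotations (secondary structure, RMSD/RMSF
regions, low-contact regions, active-site exclusions).

These are worked-example inputs, not things the package computes — the
energy values come from external calculators, the region lists from
published trajectory analysis.
"""

from __future__ import annotations

import json
from importlib import resources

from ..energy import MutationEnergyTable, parse_energy_table
from ..model import ResidueRange
from ..screen import GlycinePhiTable


def _path(name: str):
    return resources.files(__name__) / name


def glycine_phi_table() -> GlycinePhiTable:
    """The 22-glycine backbone-φ table (degrees)."""
    import pandas as pd

    with resources.as_file(_path("glycine_phi.csv")) as p:
        df = pd.read_csv(p)
    return GlycinePhiTable(dict(zip(df["residue"].astype(int), df["phi"].astype(float))))


def alanine_scan_table() -> MutationEnergyTable:
    """12-site alanine-scanning mutation energies (kcal/mol)."""
    with resources.as_file(_path("alanine_scan.csv")) as p:
        return parse_energy_table(p, dialect="csv")


def saturation_table() -> MutationEnergyTable:
    """Saturation mutation energies at G124 and G137 (19 rows per site,
    including the 0-energy glycine self-rows)."""
    with resources.as_file(_path("saturation.csv")) as p:
        return parse_energy_table(p, dialect="csv")


def double_mutant_table() -> MutationEnergyTable:
    """Energies of the 15 reported G124/G137 double mutants."""
    with resources.as_file(_path("double_mutants.csv")) as p:
        return parse_energy_table(p, dialect="csv")


def foldx_singles_table() -> MutationEnergyTable:
    """FoldX ΔΔG of the two single mutants G124W and G137W."""
    with resources.as_file(_path("foldx_singles.txt")) as p:
        return parse_energy_table(p, dialect="foldx_positionscan")


def region_annotations() -> dict:
    """Published region annotations with range strings parsed.

    Returns a dict with ``total_residues``, per-class
    ``secondary_structure`` ranges, the RMSD/RMSF/low-contact region
    lists, and the exclusion lists (site, reason).
    """
    raw = json.loads(_path("tyrosinase_regions.json").read_text())

    def ranges(texts):
        return [ResidueRange.parse(t) for t in texts]

    return {
        "total_residues": raw["total_residues"],
        "secondary_structure": {
            cls: ranges(v) for cls, v in raw["secondary_structure"].items()
        },
        "rmsd_shift_regions": ranges(raw["rmsd_shift_regions"]),
        "rmsf_increase_regions": ranges(raw["rmsf_increase_regions"]),
        "low_contact_regions": ranges(raw["low_contact_regions"]),
        "low_contact_regions_selected": ranges(raw["low_contact_regions_selected"]),
        "exclusions": {
            factor: [(int(site), reason) for site, reason in pairs]
            for factor, pairs in raw["exclusions"].items()
        },
    }
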