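"""The multi-factor candidate-site screen.

Six factors nominate residue sites for rigidifying mutation:

1. regions with an RMSD shift / conformational change at the high
   simulated temperature (supplied as residue ranges);
2. regions whose RMSF increases significantly with temperature;
3. regions with few residue contacts (β-carbon distance rule);
4. glycines with a negative backbone φ (tolerant of bulkier residues);
5. sites passing the alanine-scanning mutation-energy filter;
6. user-supplied exclusions (active site, metal-binding residues,
   substrate pocket) that remove sites from any factor.

The aggregation keeps per-factor provenance so a report can say *why*
each site was nominated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .ensemble import FlexibilityProfile
from .geometry import ContactRule, contact_counts, phi_of_residue
from .model import ResidueKey, ResidueRange, StructureModel

logger = logging.getLogger(__name__)

#: canonical factor order; fixed so provenance tags compare across runs
FACTORS = ("rmsd_region", "rmsf_region", "low_contact", "gly_phi", "ala_scan")


# ---------------------------------------------------------------------------
# glycine phi table
# ---------------------------------------------------------------------------

@dataclass
class GlycinePhiTable:
    """Backbone φ (degrees) of every glycine, keyed by residue number."""

    values: dict[int, float]

    def __post_init__(self) -> None:
        for site, phi in self.values.items():
            if not (-180.0 < phi <= 180.0):
                raise ValueError(f"site {site}: phi {phi} outside (-180, 180]")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_structure(cls, structure: StructureModel) -> "GlycinePhiTable":
        """Compute φ for every glycine (chain-start glycines are skipped)."""
        values: dict[int, float] = {}
        for res in structure.residues:
            if res.key.resname != "GLY":
                continue
            try:
                values[res.key.resnum] = phi_of_residue(structure, res.key)
            except ValueError as exc:
                logger.warning("glycine %s skipped: %s", res.key, exc)
        return cls(values)

    def validate_against(self, structure: StructureModel) -> None:
        """Every listed residue must be a glycine in ``structure``."""
        by_num = {r.key.resnum: r.key.resname for r in structure.residues}
        bad = [s for s in self.values if by_num.get(s) != "GLY"]
        if bad:
            raise ValueError(f"table lists non-glycine residues: {sorted(bad)}")


def glycine_phi_candidates(
    table: GlycinePhiTable, exclusions: Iterable[int] = ()
) -> list[int]:
    """Glycine sites with φ < 0, minus exclusions, ascending.

    A glycine with negative φ occupies right-handed backbone territory
    and tolerates substitution by a bulkier, rigidifying residue; one
    with positive φ does not.  Exclusions absent from the table warn
    rather than fail.
    """
    if not table.values:
        raise ValueError("empty glycine phi table")
    excl = set(exclusions)
    for site in excl - set(table.values):
        logger.warning("exclusion site %s not in the glycine table", site)
    return sorted(s for s, phi in table.values.items() if phi < 0 and s not in excl)


# ---------------------------------------------------------------------------
# region factors
# ---------------------------------------------------------------------------

def _maximal_runs(
    items: Sequence[tuple[ResidueKey, bool]], min_len: int
) -> list[ResidueRange]:
    """Maximal runs of consecutively numbered flagged residues per chain."""
    ranges: list[ResidueRange] = []
    run: list[ResidueKey] = []

    def flush() -> None:
        if len(run) >= min_len:
            ranges.append(ResidueRange(run[0].chain_id, run[0].resnum, run[-1].resnum))
        run.clear()

    for key, flag in items:
        contiguous = (
            run
            and key.chain_id == run[-1].chain_id
            and key.resnum == run[-1].resnum + 1
        )
        if flag and (not run or contiguous):
            run.append(key)
        elif flag:
            flush()
            run.append(key)
        else:
            flush()
    flush()
    return ranges


def rmsf_increase_regions(
    low: FlexibilityProfile,
    high: FlexibilityProfile,
    delta_min: float = 0.5,
    min_len: int = 3,
) -> list[ResidueRange]:
    """Regions whose RMSF grows by at least ``delta_min`` Å at the
    higher temperature, as maximal runs of ≥ ``min_len`` residues.
    """
    if low.residues != high.residues:
        raise ValueError("profiles cover different residue sets")
    flags = [
        (key, (high.values[key] - low.values[key]) >= delta_min)
        for key in low.residues
    ]
    return _maximal_runs(flags, min_len)


def low_contact_regions(
    structure: StructureModel,
    rule: ContactRule = ContactRule(),
    max_contacts: int = 2,
    min_len: int = 3,
) -> list[ResidueRange]:
    """Maximal runs of ≥ ``min_len`` residues with ≤ ``max_contacts``
    contact partners under ``rule``.
    """
    counts = contact_counts(structure, rule)
    flags = [
        (res.key, counts.get(res.key, 0) <= max_contacts)
        for res in structure.residues
    ]
    return _maximal_runs(flags, min_len)


def region_total(ranges: Iterable[ResidueRange], merge_overlaps: bool = True) -> int:
    """Total residue count of a range collection.

    With ``merge_overlaps`` the count is the cardinality of the covered
    residue set; without it, overlapping ranges count twice.
    """
    ranges = list(ranges)
    if merge_overlaps:
        covered = {(r.chain_id, s) for r in ranges for s in r.sites()}
        return len(covered)
    return sum(r.length for r in ranges)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    """Candidate sites with per-factor provenance and applied exclusions."""

    provenance: dict[int, set[str]]
    exclusions_applied: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for site, tags in self.provenance.items():
            if not tags:
                raise ValueError(f"site {site} has no provenance tag")
        excluded = {s for s, _ in self.exclusions_applied}
        if excluded & set(self.provenance):
            raise ValueError("excluded sites must not remain in the set")

    @property
    def sites(self) -> list[int]:
        return sorted(self.provenance)

    def __len__(self) -> int:
        return len(self.provenance)

    def to_rows(self) -> list[dict]:
        rows = [
            {"site": s, "factors": ",".join(sorted(self.provenance[s])), "excluded": ""}
            for s in self.sites
        ]
        rows += [
            {"site": s, "factors": "", "excluded": reason}
            for s, reason in sorted(self.exclusions_applied)
        ]
        return rows


def _expand_sites(output: Iterable) -> set[int]:
    sites: set[int] = set()
    for item in output:
        if isinstance(item, ResidueRange):
            sites.update(item.sites())
        else:
            sites.add(int(item))
    return sites


def aggregate_candidates(
    factor_outputs: Mapping[str, Iterable],
    exclusions: Iterable[tuple[int, str]] = (),
) -> CandidateSet:
    """Union the per-factor outputs (sites or ranges) with provenance.

    Order-independent and idempotent: a site nominated by several
    factors carries every tag but counts once.  Exclusions are removed
    from the union and logged with their reason.
    """
    if not factor_outputs:
        raise ValueError("at least one factor output is required")
    provenance: dict[int, set[str]] = {}
    for factor, output in factor_outputs.items():
        for site in _expand_sites(output):
            provenance.setdefault(site, set()).add(factor)
    applied: list[tuple[int, str]] = []
    for site, reason in exclusions:
        if site in provenance:
            logger.info("excluding site %s: %s", site, reason)
            del provenance[site]
            applied.append((site, reason))
    return CandidateSet(provenance, applied)


# ---------------------------------------------------------------------------
# secondary-structure accounting
# ---------------------------------------------------------------------------

def _round_half_up(x: float, digits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -digits, ROUND_HALF_UP))


@dataclass
class SecondaryStructureSummary:
    """Residue counts and percentages per secondary-structure class."""

    counts: dict[str, int]
    percentages: dict[str, float]
    total_residues: int


def secstruct_summary(
    regions: Mapping[str, Sequence[ResidueRange]], total_residues: int
) -> SecondaryStructureSummary:
    """Count residues per class from inclusive ranges.

    Ranges within one class are merged before counting; percentages are
    100·count/total rounded half-up to 2 decimals.  Class assignments
    come from external annotation (no secondary-structure detector is
    implemented here).
    """
    if total_residues <= 0:
        raise ValueError("total_residues must be positive")
    counts: dict[str, int] = {}
    for cls_name, ranges in regions.items():
        for r in ranges:
            if r.end > total_residues:
                raise ValueError(
                    f"range {r} exceeds total residue count {total_residues}"
                )
        counts[cls_name] = region_total(ranges, merge_overlaps=True)
    percentages = {
        c: _round_half_up(100.0 * n / total_residues) for c, n in counts.items()
    }
    return SecondaryStructureSummary(counts, percentages, total_residues)
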