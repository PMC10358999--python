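"""End-to-end screening pipeline driven by a JSON config.

``run_screen`` executes the candidate-site factors in a fixed order —
RMSD regions → RMSF regions → contacts → glycine φ → alanine scan —
aggregates them with provenance, then runs the energy screens
(saturation candidates, best substitutions, combinatorial ranking) and
names a selected design.  Factors whose inputs are missing are skipped
with a log line; a config with no runnable factor is an error.

The report is canonical JSON (plus TSV summaries and a plain-text
narrative); two runs with the same config and seed produce identical
reports apart from the timestamp field.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .energy import (
    MutationEnergyTable,
    StabilityBands,
    alanine_scan_filter,
    candidate_sites,
    combine_additive,
    mutation_label,
    parse_energy_table,
    rank_mutants,
    saturation_best,
)
from .ensemble import FlexibilityProfile, per_residue_rmsf
from .geometry import ContactRule, HBondCriteria
from .model import ResidueRange, StructureModel, read_ensemble, read_pdb
from .screen import (
    CandidateSet,
    GlycinePhiTable,
    aggregate_candidates,
    glycine_phi_candidates,
    low_contact_regions,
    rmsf_increase_regions,
)

logger = logging.getLogger(__name__)


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ContactRuleConfig(_Model):
    distance_threshold: float = 3.0


class HBondConfig(_Model):
    max_donor_acceptor_dist: float = 3.5
    min_dha_angle: float = 150.0


class BandsConfig(_Model):
    neutral_low: float = -0.5
    neutral_high: float = 0.5
    candidate_cutoff: float = -1.5

    @model_validator(mode="after")
    def _check(self) -> "BandsConfig":
        StabilityBands(self.neutral_low, self.neutral_high, self.candidate_cutoff)
        return self

    def to_bands(self) -> StabilityBands:
        return StabilityBands(self.neutral_low, self.neutral_high, self.candidate_cutoff)


class EnergyTableRef(_Model):
    path: Path
    dialect: Literal["csv", "foldx_positionscan"] = "csv"


class ExclusionEntry(_Model):
    site: int
    reason: str = ""


class ScreenConfig(_Model):
    """Validated screening configuration.

    Every threshold the screen uses is an explicit field with its
    default echoed into the report, so a report is self-describing.
    """

    structure: Optional[Path] = None
    ensembles: dict[str, Path] = Field(default_factory=dict)
    profiles: dict[str, Path] = Field(default_factory=dict)
    rmsd_regions: list[str] = Field(default_factory=list)
    glycine_phi_csv: Optional[Path] = None
    alanine_scan_table: Optional[EnergyTableRef] = None
    saturation_table: Optional[EnergyTableRef] = None
    combinatorial_table: Optional[EnergyTableRef] = None
    contact_rule: ContactRuleConfig = Field(default_factory=ContactRuleConfig)
    hbond_criteria: HBondConfig = Field(default_factory=HBondConfig)
    stability_bands: BandsConfig = Field(default_factory=BandsConfig)
    rmsf_delta_min: float = 0.5
    rmsf_min_len: int = 3
    max_contacts: int = 2
    low_contact_min_len: int = 3
    glycine_exclusions: list[ExclusionEntry] = Field(default_factory=list)
    alanine_scan_exclusions: list[ExclusionEntry] = Field(default_factory=list)
    low_contact_exclusions: list[ExclusionEntry] = Field(default_factory=list)
    aggregate_exclusions: list[ExclusionEntry] = Field(default_factory=list)
    out_dir: Path = Path("screen_out")
    seed: int = 0

    @model_validator(mode="after")
    def _at_least_one_factor(self) -> "ScreenConfig":
        runnable = (
            self.rmsd_regions
            or len(self.ensembles) >= 2
            or len(self.profiles) >= 2
            or self.structure is not None
            or self.glycine_phi_csv is not None
            or self.alanine_scan_table is not None
        )
        if not runnable:
            raise ValueError("config enables no screening factor")
        return self

    def referenced_paths(self) -> list[Path]:
        paths = [p for p in (self.structure, self.glycine_phi_csv) if p]
        paths += list(self.ensembles.values()) + list(self.profiles.values())
        for ref in (self.alanine_scan_table, self.saturation_table,
                    self.combinatorial_table):
            if ref:
                paths.append(ref.path)
        return paths


def validate_config(path: str | Path) -> ScreenConfig:
    """Parse, default and range-check a JSON config file.

    Unknown keys are errors (no silent typos); every referenced input
    path must exist at validation time.
    """
    raw = json.loads(Path(path).read_text())
    config = ScreenConfig.model_validate(raw)
    missing = [str(p) for p in config.referenced_paths() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"config references missing files: {missing}")
    return config


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

class ScreenReport:
    """Outcome of one screening run; serializable and self-describing."""

    def __init__(self, config: ScreenConfig) -> None:
        self.config = config
        self.factors: dict[str, list] = {}
        self.skipped: list[str] = []
        self.candidates: CandidateSet | None = None
        self.saturation_candidates: list[tuple[int, str]] = []
        self.best_substitutions: dict[int, tuple[str, float]] = {}
        self.ranking = None
        self.ranking_source: str | None = None
        self.selected_design: str | None = None
        self.timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat()

    def to_dict(self, include_timestamp: bool = True) -> dict:
        d = {
            "tool": {"name": "thermoscreen", "version": __version__},
            "config": json.loads(self.config.model_dump_json()),
            "factors": {k: [str(x) for x in v] for k, v in self.factors.items()},
            "skipped_factors": self.skipped,
            "candidates": self.candidates.to_rows() if self.candidates else [],
            "saturation_candidates": [
                {"site": s, "to_aa": a} for s, a in self.saturation_candidates
            ],
            "best_substitutions": {
                str(site): {"to_aa": aa, "energy": e}
                for site, (aa, e) in self.best_substitutions.items()
            },
            "ranking": self.ranking.to_rows() if self.ranking else [],
            "ranking_source": self.ranking_source,
            "selected_design": self.selected_design,
        }
        if include_timestamp:
            d["timestamp"] = self.timestamp
        return d

    def to_json(self, include_timestamp: bool = True) -> str:
        return json.dumps(self.to_dict(include_timestamp), indent=2, sort_keys=True)

    def narrative(self) -> str:
        """Plain-text account of the decision sequence, for human review."""
        cfg = self.config
        lines = [
            "thermoscreen candidate report",
            "=============================",
            f"thresholds: contact < {cfg.contact_rule.distance_threshold} "
            f"(max {cfg.max_contacts} partners), "
            f"RMSF increase >= {cfg.rmsf_delta_min} A over >= {cfg.rmsf_min_len} residues, "
            f"stability bands [{cfg.stability_bands.neutral_low}, "
            f"{cfg.stability_bands.neutral_high}] kcal/mol, "
            f"candidate cutoff {cfg.stability_bands.candidate_cutoff} kcal/mol, "
            f"glycine rule phi < 0",
            "",
        ]
        for factor in ("rmsd_region", "rmsf_region", "low_contact", "gly_phi", "ala_scan"):
            if factor in self.factors:
                items = ", ".join(str(x) for x in self.factors[factor])
                lines.append(f"{factor}: {items if items else '(none)'}")
            else:
                lines.append(f"{factor}: skipped (inputs not provided)")
        if self.candidates:
            lines.append(
                f"aggregated candidate sites ({len(self.candidates)}): "
                + ", ".join(str(s) for s in self.candidates.sites)
            )
            for site, reason in self.candidates.exclusions_applied:
                lines.append(f"  excluded {site}: {reason}")
        if self.saturation_candidates:
            lines.append(
                "saturation candidates (< "
                f"{cfg.stability_bands.candidate_cutoff} kcal/mol): "
                + ", ".join(f"{s}->{a}" for s, a in self.saturation_candidates)
            )
        for site, (aa, e) in self.best_substitutions.items():
            lines.append(f"best substitution at {site}: {aa} ({e:+.2f} kcal/mol)")
        if self.selected_design:
            lines.append(
                f"selected design: {self.selected_design} (ranking from "
                f"{self.ranking_source})"
            )
        return "\n".join(lines) + "\n"

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        (out / "narrative.txt").write_text(self.narrative())
        if self.candidates:
            rows = self.candidates.to_rows()
            lines = ["site\tfactors\texcluded"]
            lines += [f"{r['site']}\t{r['factors']}\t{r['excluded']}" for r in rows]
            (out / "candidates.tsv").write_text("\n".join(lines) + "\n")
        if self.ranking:
            lines = ["mutation\tenergy"]
            lines += [
                f"{r['mutation']}\t{r['energy']}" for r in self.ranking.to_rows()
            ]
            (out / "ranking.tsv").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def _load_profiles(config: ScreenConfig) -> tuple[FlexibilityProfile, FlexibilityProfile] | None:
    """Low/high-temperature RMSF profiles from TSVs or from ensembles."""
    if len(config.profiles) >= 2:
        labels = sorted(config.profiles, key=float)
        low = FlexibilityProfile.from_tsv(config.profiles[labels[0]], float(labels[0]))
        high = FlexibilityProfile.from_tsv(config.profiles[labels[-1]], float(labels[-1]))
        return low, high
    if len(config.ensembles) >= 2:
        labels = sorted(config.ensembles, key=float)
        low_e = read_ensemble(config.ensembles[labels[0]], float(labels[0]))
        high_e = read_ensemble(config.ensembles[labels[-1]], float(labels[-1]))
        return per_residue_rmsf(low_e), per_residue_rmsf(high_e)
    return None


def _check_site_consistency(structure: StructureModel, table: MutationEnergyTable
                            ) -> None:
    """Sites and from-residues in a table must match the structure."""
    by_num = {r.key.resnum: r.key.resname for r in structure.residues}
    bad: list[str] = []
    for mutset in table.entries:
        for site, frm, _ in mutset:
            resname = by_num.get(site)
            if resname is None or (resname != frm):
                bad.append(f"{site}({frm} vs {resname})")
    if bad:
        raise ValueError(
            "energy table disagrees with structure numbering at sites: "
            + ", ".join(sorted(set(bad)))
        )


def run_screen(config: ScreenConfig, check_structure_consistency: bool = True
               ) -> ScreenReport:
    """Execute the full multi-factor screen described by ``config``."""
    report = ScreenReport(config)
    structure = read_pdb(config.structure) if config.structure else None
    factor_outputs: dict[str, list] = {}

    # 1. RMSD-shift regions (supplied ranges; the conformational-change
    #    call is made upstream by the analyst)
    if config.rmsd_regions:
        factor_outputs["rmsd_region"] = [
            ResidueRange.parse(t) for t in config.rmsd_regions
        ]
    else:
        report.skipped.append("rmsd_region")

    # 2. RMSF-increase regions
    profiles = _load_profiles(config)
    if profiles is not None:
        low, high = profiles
        factor_outputs["rmsf_region"] = rmsf_increase_regions(
            low, high, config.rmsf_delta_min, config.rmsf_min_len
        )
    else:
        report.skipped.append("rmsf_region")

    # 3. low-contact regions
    if structure is not None:
        rule = ContactRule(config.contact_rule.distance_threshold)
        regions = low_contact_regions(
            structure, rule, config.max_contacts, config.low_contact_min_len
        )
        drop = {e.site for e in config.low_contact_exclusions}
        sites = [s for r in regions for s in r.sites() if s not in drop]
        factor_outputs["low_contact"] = sites
    else:
        report.skipped.append("low_contact")

    # 4. glycine phi rule
    gly_table: GlycinePhiTable | None = None
    if config.glycine_phi_csv is not None:
        import pandas as pd

        df = pd.read_csv(config.glycine_phi_csv)
        df.columns = [c.strip().lower() for c in df.columns]
        gly_table = GlycinePhiTable(
            dict(zip(df["residue"].astype(int), df["phi"].astype(float)))
        )
        if structure is not None:
            gly_table.validate_against(structure)
    elif structure is not None:
        gly_table = GlycinePhiTable.from_structure(structure)
    if gly_table is not None and gly_table.values:
        factor_outputs["gly_phi"] = glycine_phi_candidates(
            gly_table, [e.site for e in config.glycine_exclusions]
        )
    else:
        report.skipped.append("gly_phi")

    # 5. alanine scan
    ala_table = None
    if config.alanine_scan_table is not None:
        ala_table = parse_energy_table(
            config.alanine_scan_table.path, config.alanine_scan_table.dialect
        )
        if structure is not None and check_structure_consistency:
            _check_site_consistency(structure, ala_table)
        factor_outputs["ala_scan"] = alanine_scan_filter(
            ala_table,
            config.stability_bands.to_bands(),
            [e.site for e in config.alanine_scan_exclusions],
        )
    else:
        report.skipped.append("ala_scan")

    if not factor_outputs:
        raise ValueError("no screening factor could run with the given inputs")
    for name in report.skipped:
        logger.info("factor %s skipped: inputs not provided", name)

    report.factors = factor_outputs
    report.candidates = aggregate_candidates(
        factor_outputs,
        [(e.site, e.reason) for e in config.aggregate_exclusions],
    )

    # energy screening
    bands = config.stability_bands.to_bands()
    sat_table = None
    if config.saturation_table is not None:
        sat_table = parse_energy_table(
            config.saturation_table.path, config.saturation_table.dialect
        )
        if structure is not None and check_structure_consistency:
            _check_site_consistency(structure, sat_table)
        report.saturation_candidates = candidate_sites(sat_table, bands)
        for site in sat_table.sites:
            report.best_substitutions[site] = saturation_best(sat_table, site)

    if config.combinatorial_table is not None:
        combo = parse_energy_table(
            config.combinatorial_table.path, config.combinatorial_table.dialect
        )
        report.ranking = rank_mutants(combo)
        report.ranking_source = "combinatorial table"
    elif sat_table is not None:
        # combine only the sites that survived the candidate screen; if
        # more than 4 remain, keep those with the most stabilizing best
        # substitution so the cross-product stays reviewable
        combo_sites = sorted({s for s, _ in report.saturation_candidates})
        if len(combo_sites) > 4:
            combo_sites = sorted(
                sorted(combo_sites, key=lambda s: report.best_substitutions[s][1])[:4]
            )
        if len(combo_sites) >= 2:
            combo = combine_additive(sat_table, combo_sites)
            report.ranking = rank_mutants(combo)
            report.ranking_source = "additive combination of saturation singles"
    if report.ranking is not None:
        report.selected_design = report.ranking.best_label

    return report
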