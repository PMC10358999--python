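"""Mutation-energy tables and the energy-based screening steps.

The table type holds per-mutation stability estimates from an external
calculator — an alanine scan, a per-site saturation scan, or a
combinatorial (multi-site) scan — tagged by the engine that produced
them.  Engines use different scales (a CHARMm-based "mutation energy"
and a FoldX ΔΔG are not comparable numbers), so tables are never mixed
across engine tags within one screen.

All energies are kcal/mol; negative means stabilizing.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .model import ONE_TO_THREE, THREE_TO_ONE

TableKind = Literal["alanine_scan", "saturation", "combinatorial"]

#: one single-site mutation: (site, from 3-letter, to 3-letter)
Mutation = tuple[int, str, str]
#: a mutation set (single mutants are 1-tuples), sorted by site
MutationSet = tuple[Mutation, ...]


def canonical_aa(code: str) -> str:
    """Normalize a 1- or 3-letter amino-acid code to 3-letter upper case."""
    c = code.strip().upper()
    if len(c) == 1 and c in ONE_TO_THREE:
        return ONE_TO_THREE[c]
    if c in THREE_TO_ONE:
        return c
    raise ValueError(f"unknown amino-acid code {code!r}")


def mutation_label(mutations: MutationSet) -> str:
    """Slash-joined compact label, e.g. ``G124W/G137W``."""
    return "/".join(
        f"{THREE_TO_ONE[frm]}{site}{THREE_TO_ONE[to]}" for site, frm, to in mutations
    )


def parse_mutation_label(label: str) -> MutationSet:
    """Parse ``G124W`` or ``G124W/G137W`` into a mutation set."""
    out = []
    for part in label.strip().split("/"):
        m = re.fullmatch(r"([A-Za-z])(\d+)([A-Za-z])", part.strip())
        if not m:
            raise ValueError(f"cannot parse mutation label {part!r}")
        frm, site, to = m.groups()
        out.append((int(site), canonical_aa(frm), canonical_aa(to)))
    return tuple(sorted(out))


# ---------------------------------------------------------------------------
# table type
# ---------------------------------------------------------------------------

@dataclass
class MutationEnergyTable:
    """(mutation set) → energy (kcal/mol) with an engine tag and a kind.

    Self-mutations (from == to) are retained on parse — scans often
    print them as explicit 0 rows — but are excluded from minima and
    destabilizing counts.
    """

    entries: dict[MutationSet, float]
    engine_tag: str = ""
    kind: TableKind = "saturation"

    def __post_init__(self) -> None:
        for mutset, e in self.entries.items():
            if not math.isfinite(e):
                raise ValueError(f"non-finite energy for {mutation_label(mutset)}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def sites(self) -> list[int]:
        return sorted({site for mutset in self.entries for site, _, _ in mutset})

    def singles_at(self, site: int, include_self: bool = False
                   ) -> dict[str, float]:
        """to-AA → energy for single mutations at one site."""
        out: dict[str, float] = {}
        for mutset, e in self.entries.items():
            if len(mutset) == 1 and mutset[0][0] == site:
                _, frm, to = mutset[0]
                if include_self or frm != to:
                    out[to] = e
        return out

    def single_energy(self, site: int, to_aa: str) -> float:
        to3 = canonical_aa(to_aa)
        for mutset, e in self.entries.items():
            if len(mutset) == 1 and mutset[0][0] == site and mutset[0][2] == to3:
                return e
        raise KeyError(f"no entry for site {site} -> {to3}")


def _build_entries(rows: Iterable[tuple[MutationSet, float]], source: str
                   ) -> dict[MutationSet, float]:
    entries: dict[MutationSet, float] = {}
    for i, (mutset, energy) in enumerate(rows, start=1):
        if mutset in entries:
            raise ValueError(
                f"duplicate entry {mutation_label(mutset)} (row {i} of {source})"
            )
        entries[mutset] = energy
    return entries


def _infer_kind(entries: dict[MutationSet, float]) -> TableKind:
    if any(len(m) > 1 for m in entries):
        return "combinatorial"
    by_site: dict[int, set[str]] = {}
    to_codes: set[str] = set()
    for mutset in entries:
        site, _, to = mutset[0]
        by_site.setdefault(site, set()).add(to)
        to_codes.add(to)
    if to_codes <= {"ALA"} and all(len(v) == 1 for v in by_site.values()):
        return "alanine_scan"
    return "saturation"


def parse_energy_table(
    path: str | Path,
    dialect: Literal["csv", "foldx_positionscan"] = "csv",
    engine_tag: str | None = None,
    kind: TableKind | None = None,
) -> MutationEnergyTable:
    """Read a mutation-energy table from delimited text.

    ``csv`` expects columns ``site, from_aa, to_aa, energy`` (any
    delimiter pandas can sniff; an optional ``engine`` column sets the
    tag), or ``mutation, energy`` with slash-joined labels for
    combinatorial tables.  ``foldx_positionscan`` expects lines of
    ``<fromAA><chain><site><toAA> <energy>``.

    The kind is inferred from the column shape unless given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"energy table not found: {path}")

    rows: list[tuple[MutationSet, float]] = []
    tag = engine_tag or ""
    if dialect == "foldx_positionscan":
        pat = re.compile(r"([A-Za-z])([A-Za-z])(\d+)([A-Za-z])\s+(\S+)")
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m = pat.fullmatch(line)
            if not m:
                raise ValueError(f"{path}:{ln}: cannot parse PositionScan line {line!r}")
            frm, _chain, site, to, energy = m.groups()
            try:
                e = float(energy)
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-numeric energy {energy!r}") from None
            rows.append((((int(site), canonical_aa(frm), canonical_aa(to)),), e))
        tag = engine_tag or "foldx"
    elif dialect == "csv":
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        df.columns = [c.strip().lower() for c in df.columns]
        if "mutation" in df.columns:
            for i, rec in df.iterrows():
                rows.append((parse_mutation_label(str(rec["mutation"])),
                             _numeric(rec["energy"], path, i)))
        else:
            missing = {"site", "from_aa", "to_aa", "energy"} - set(df.columns)
            if missing:
                raise ValueError(f"{path}: missing columns {sorted(missing)}")
            for i, rec in df.iterrows():
                mut = (int(rec["site"]), canonical_aa(str(rec["from_aa"])),
                       canonical_aa(str(rec["to_aa"])))
                rows.append(((mut,), _numeric(rec["energy"], path, i)))
        if "engine" in df.columns and not engine_tag:
            tags = set(df["engine"].astype(str))
            if len(tags) > 1:
                raise ValueError(f"{path}: mixed engine tags {sorted(tags)}")
            tag = tags.pop()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    entries = _build_entries(rows, str(path))
    return MutationEnergyTable(entries, engine_tag=tag, kind=kind or _infer_kind(entries))


def _numeric(value, path, row) -> float:
    try:
        e = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"{path}: row {row}: non-numeric energy {value!r}") from None
    if not math.isfinite(e):
        raise ValueError(f"{path}: row {row}: non-finite energy")
    return e


# ---------------------------------------------------------------------------
# classification and screens
# ---------------------------------------------------------------------------

@dataclass
class StabilityBands:
    """Energy bands (kcal/mol) for classifying a mutation.

    Below ``neutral_low`` the mutation is called stabilizing, above
    ``neutral_high`` destabilizing, in between (boundaries included)
    neutral.  ``candidate_cutoff`` is the stricter threshold a
    saturation substitution must beat to become a candidate design.
    """

    neutral_low: float = -0.5
    neutral_high: float = 0.5
    candidate_cutoff: float = -1.5

    def __post_init__(self) -> None:
        if self.neutral_low >= self.neutral_high:
            raise ValueError(
                f"neutral band inverted: [{self.neutral_low}, {self.neutral_high}]"
            )
        if self.candidate_cutoff > self.neutral_low:
            raise ValueError("candidate_cutoff must be <= neutral_low")


def classify_stability(energy: float, bands: StabilityBands = StabilityBands()
                       ) -> Literal["stabilizing", "neutral", "destabilizing"]:
    """Partition the energy axis; band boundaries classify as neutral."""
    if not math.isfinite(energy):
        raise ValueError("energy must be finite")
    if energy < bands.neutral_low:
        return "stabilizing"
    if energy > bands.neutral_high:
        return "destabilizing"
    return "neutral"


def alanine_scan_filter(
    table: MutationEnergyTable,
    bands: StabilityBands = StabilityBands(),
    exclusions: Iterable[int] = (),
) -> list[int]:
    """Sites whose X→Ala energy is below ``neutral_low``, minus exclusions.

    Typical exclusions are catalytic or metal-binding residues whose
    substitution would cost activity regardless of stability.
    """
    if table.kind != "alanine_scan":
        raise ValueError(f"expected an alanine_scan table, got {table.kind!r}")
    excl = set(exclusions)
    return sorted(
        mutset[0][0]
        for mutset, e in table.entries.items()
        if e < bands.neutral_low and mutset[0][0] not in excl
    )


def saturation_best(table: MutationEnergyTable, site: int) -> tuple[str, float]:
    """Minimum-energy substitution at ``site`` (self-rows excluded).

    Ties break to the alphabetically first 3-letter code.
    """
    column = table.singles_at(site, include_self=False)
    if not column:
        raise KeyError(f"no non-self substitutions for site {site}")
    best_to = min(sorted(column), key=column.get)
    return best_to, column[best_to]


def count_destabilizing(table: MutationEnergyTable, site: int) -> int:
    """Number of non-self substitutions at ``site`` with energy > 0."""
    column = table.singles_at(site, include_self=False)
    if not column:
        raise KeyError(f"site {site} not in table")
    return sum(1 for e in column.values() if e > 0)


def candidate_sites(
    table: MutationEnergyTable, bands: StabilityBands = StabilityBands()
) -> list[tuple[int, str]]:
    """All (site, substitution) pairs with energy below ``candidate_cutoff``."""
    if table.kind != "saturation":
        raise ValueError(f"expected a saturation table, got {table.kind!r}")
    out = [
        (mutset[0][0], mutset[0][2])
        for mutset, e in table.entries.items()
        if mutset[0][1] != mutset[0][2] and e < bands.candidate_cutoff
    ]
    return sorted(out)


# ---------------------------------------------------------------------------
# ranking and combination
# ---------------------------------------------------------------------------

@dataclass
class MutantRanking:
    """Mutation sets ordered by ascending energy (most stabilizing first).

    Ties break by the lexicographic mutation label, so the ranking is
    a deterministic permutation of the input.
    """

    ranked: list[tuple[MutationSet, float]]

    def __post_init__(self) -> None:
        energies = [e for _, e in self.ranked]
        if any(b < a for a, b in zip(energies, energies[1:])):
            raise ValueError("ranking energies must be non-decreasing")

    @property
    def best(self) -> tuple[MutationSet, float]:
        return self.ranked[0]

    @property
    def best_label(self) -> str:
        return mutation_label(self.best[0])

    def to_rows(self) -> list[dict]:
        return [
            {"mutation": mutation_label(m), "energy": e} for m, e in self.ranked
        ]


def rank_mutants(table: MutationEnergyTable) -> MutantRanking:
    """Rank every entry by energy; the top element is the selected design."""
    if not table.entries:
        raise ValueError("cannot rank an empty table")
    ranked = sorted(
        table.entries.items(), key=lambda kv: (kv[1], mutation_label(kv[0]))
    )
    return MutantRanking(ranked)


def additive_ddg(singles: Sequence[tuple[Mutation | str, float]]) -> float:
    """Additive ΔΔG of a multi-mutant: the sum of its single-mutant ΔΔGs.

    The additivity approximation requires pairwise-distinct sites; a
    duplicated site raises.
    """
    if not singles:
        raise ValueError("need at least one single mutant")
    sites = []
    total = 0.0
    for mut, e in singles:
        if isinstance(mut, str):
            (mut,) = parse_mutation_label(mut)
        sites.append(mut[0])
        total += e
    if len(set(sites)) != len(sites):
        raise ValueError(f"duplicated site in {sites}: additivity assumption violated")
    return total


def combine_additive(
    table: MutationEnergyTable, sites: Sequence[int]
) -> MutationEnergyTable:
    """Synthesize a combinatorial table from a saturation table by additivity.

    Every cross-combination of non-self substitutions at the given
    sites gets the sum of its single-mutant energies.  The engine tag
    is suffixed ``+additive`` so reports can state which path produced
    a ranking.
    """
    if table.kind != "saturation":
        raise ValueError(f"expected a saturation table, got {table.kind!r}")
    if len(set(sites)) != len(sites):
        raise ValueError("sites must be pairwise distinct")
    columns = []
    froms = {}
    for site in sites:
        col = table.singles_at(site, include_self=False)
        if not col:
            raise KeyError(f"no substitutions for site {site}")
        for mutset in table.entries:
            if len(mutset) == 1 and mutset[0][0] == site:
                froms[site] = mutset[0][1]
                break
        columns.append((site, col))

    combos: dict[MutationSet, float] = {}

    def build(i: int, acc: list[Mutation], energy: float) -> None:
        if i == len(columns):
            combos[tuple(sorted(acc))] = energy
            return
        site, col = columns[i]
        for to, e in col.items():
            build(i + 1, acc + [(site, froms[site], to)], energy + e)

    build(0, [], 0.0)
    tag = (table.engine_tag + "+additive") if table.engine_tag else "additive"
    return MutationEnergyTable(combos, engine_tag=tag, kind="combinatorial")
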