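"""Gland- and labor-selective protein calling and Venn partitioning.

Two routes lead to a selectivity call for a protein in a comparison of
sample groups (glands, or nurse vs forager within one gland):

* ``unique_detection`` — the protein is detected in exactly one group
  (aggregated count >= ``unique_min``, default 2) and has zero counts in
  every other group.
* ``fold_excess`` — the protein's normalized count in its group strictly
  exceeds ``fold_min`` (default 5) times the normalized count in EACH other
  group, i.e. 5x the strongest competitor.

The two routes are disjoint: a protein with any competitor signal must pass
the fold test, and a protein detected in one group only but below
``unique_min`` is called nowhere.  With ``fold_min > 1`` a protein can be
selective for at most one group per comparison.

Group normalization divides each group's aggregated count by the group's
total spectral count (sum of member-column totals), or treats all totals as
equal when requested — appropriate for curated table excerpts where the
true per-sample totals (all near 40,000 in this study) are unavailable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CriteriaConfig, ProteinEntry, SpectralCountTable
from .samples import Gland, atomic_names

__all__ = [
    "SelectivityCall",
    "gland_groups",
    "specific_proteins",
    "selective_proteins",
    "labor_selective_proteins",
    "venn_partition",
]

UNIQUE_DETECTION = "unique_detection"
FOLD_EXCESS = "fold_excess"


@dataclass(frozen=True)
class SelectivityCall:
    """One selective protein in one group, with the evidence behind the call.

    ``own_value`` and ``max_other`` are normalized (relative) counts; for a
    ``unique_detection`` call ``max_other`` is exactly 0.
    """

    entry: ProteinEntry
    group: str
    basis: str  # UNIQUE_DETECTION or FOLD_EXCESS
    own_value: float
    max_other: float

    @property
    def fold(self) -> float:
        if self.max_other == 0:
            return np.inf if self.own_value > 0 else np.nan
        return self.own_value / self.max_other


def gland_groups(glands: Sequence[Gland] = tuple(Gland)) -> dict[str, list[str]]:
    """The standard three-gland partition: each gland's nurse+forager columns."""
    return {g.value: list(atomic_names(g)) for g in glands}


def _group_counts_and_totals(
    table: SpectralCountTable,
    groups: Mapping[str, Sequence[str]],
    criteria: CriteriaConfig,
    totals_override: Mapping[str, float] | None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Aggregate raw counts and totals per group; validate the partition."""
    seen: set[str] = set()
    for name, cols in groups.items():
        missing = [c for c in cols if c not in table.samples]
        if missing:
            raise ValueError(f"group {name!r} names missing sample column(s): {missing}")
        overlap = seen.intersection(cols)
        if overlap:
            raise ValueError(f"groups overlap on sample column(s): {sorted(overlap)}")
        seen.update(cols)
    counts = pd.DataFrame(
        {name: table.counts[list(cols)].sum(axis=1) for name, cols in groups.items()}
    )
    if criteria.assume_equal_totals:
        totals = pd.Series(1.0, index=list(groups))
    else:
        col_totals = table.column_totals().astype(float)
        if totals_override is not None:
            for s, t in totals_override.items():
                if s in col_totals.index:
                    col_totals[s] = float(t)
        totals = pd.Series(
            {name: col_totals[list(cols)].sum() for name, cols in groups.items()}
        )
        zero = [g for g, t in totals.items() if t <= 0]
        if zero:
            raise ValueError(
                f"zero total spectral count for group(s) {zero}; "
                "supply totals_override or assume_equal_totals"
            )
    return counts, totals


def specific_proteins(
    table: SpectralCountTable,
    groups: Mapping[str, Sequence[str]],
    unique_min: int = 2,
) -> dict[str, set[str]]:
    """Proteins detected in exactly one group: count >= unique_min there, 0 elsewhere."""
    counts, _ = _group_counts_and_totals(table, groups, CriteriaConfig(assume_equal_totals=True), None)
    out: dict[str, set[str]] = {g: set() for g in groups}
    arr = counts.to_numpy()
    for i, acc in enumerate(counts.index):
        nz = np.flatnonzero(arr[i])
        if len(nz) == 1 and arr[i, nz[0]] >= unique_min:
            out[counts.columns[nz[0]]].add(acc)
    return out


def selective_proteins(
    table: SpectralCountTable,
    groups: Mapping[str, Sequence[str]],
    criteria: CriteriaConfig = CriteriaConfig(),
    totals_override: Mapping[str, float] | None = None,
) -> dict[str, list[SelectivityCall]]:
    """Union of unique-detection and fold-excess calls per group.

    Calls within a group are ordered by accession (deterministic output).
    """
    counts, totals = _group_counts_and_totals(table, groups, criteria, totals_override)
    norm = counts / totals
    out: dict[str, list[SelectivityCall]] = {g: [] for g in groups}
    names = list(counts.columns)
    raw = counts.to_numpy()
    rel = norm.to_numpy(dtype=float)
    desc = table.df["description"]
    for i, acc in enumerate(counts.index):
        entry = ProteinEntry(acc, str(desc.loc[acc]))
        for j, g in enumerate(names):
            others = [k for k in range(len(names)) if k != j]
            other_raw = raw[i, others]
            max_other = float(rel[i, others].max()) if others else 0.0
            own = float(rel[i, j])
            if (other_raw == 0).all():
                if raw[i, j] >= criteria.unique_min:
                    out[g].append(SelectivityCall(entry, g, UNIQUE_DETECTION, own, 0.0))
            elif max_other > 0 and own > criteria.fold_min * max_other:
                out[g].append(SelectivityCall(entry, g, FOLD_EXCESS, own, max_other))
    for g in out:
        out[g].sort(key=lambda c: c.entry.accession)
    return out


def labor_selective_proteins(
    table: SpectralCountTable,
    gland: Gland,
    criteria: CriteriaConfig = CriteriaConfig(),
    totals_override: Mapping[str, float] | None = None,
) -> dict[str, list[SelectivityCall]]:
    """Nurse- vs forager-selective proteins within one gland.

    A two-group comparison between the gland's nurse and forager columns
    using the same unique-detection/fold-excess rules; group labels are the
    sample names (e.g. ``nTG``, ``fTG``).
    """
    n, f = atomic_names(gland)
    missing = [c for c in (n, f) if c not in table.samples]
    if missing:
        raise ValueError(f"labor columns {missing} absent for gland {gland.value}")
    return selective_proteins(table, {n: [n], f: [f]}, criteria, totals_override)


def venn_partition(sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Inclusion/exclusion region counts for 2 or 3 named sets.

    Keys are frozensets of set names; the count for key R is the number of
    elements belonging to exactly the sets in R.  Region counts sum to the
    size of the union.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError(f"venn_partition supports 2 or 3 sets, got {len(sets)}")
    names = list(sets)
    regions: dict[frozenset, int] = {
        frozenset(c): 0
        for r in range(1, len(names) + 1)
        for c in itertools.combinations(names, r)
    }
    universe = set().union(*sets.values())
    for x in universe:
        member = frozenset(n for n in names if x in sets[n])
        regions[member] += 1
    return regions
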