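"""Labor merging, normalization, frequent-protein calling, ranking, folds.

The semiquantitative unit throughout is the spectral count (SC): the number
of MS/MS spectra assigned to a protein in one sample.  Counts are compared
either raw (rankings, the >100 "frequently detected" rule on pooled
nurse+forager counts) or normalized by each sample's total spectral count
(selectivity folds).  Counts are deliberately NOT normalized by predicted
molecular mass, which is why the abundance proxy is called "frequently
detected" rather than "most abundant".

Fold sentinels: a/0 with a > 0 is ``+inf``; 0/0 is ``nan``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DegenerateInputError, NormalizedCountTable, ProteinEntry, SpectralCountTable
from .samples import Gland, atomic_names, merged_name

__all__ = [
    "FrequentCall",
    "merge_labor",
    "normalize",
    "find_frequent",
    "rank_proteins",
    "fold_change",
    "relative_to_reference",
]


@dataclass(frozen=True)
class FrequentCall:
    """Frequent-protein predicate for one protein in one gland.

    ``is_frequent`` is True iff the pooled nurse+forager spectral count
    strictly exceeds the threshold (default 100).
    """

    entry: ProteinEntry
    gland: Gland
    merged_count: int
    is_frequent: bool


def merge_labor(table: SpectralCountTable, glands: Sequence[Gland] = tuple(Gland)) -> SpectralCountTable:
    """Add pooled ``(n+f)X`` columns (nurse + forager) for each gland.

    Atomic columns are preserved; the merged column for gland X is the
    elementwise sum of nX and fX.  Requires both labor columns per gland.
    """
    new: dict[str, pd.Series] = {}
    for g in glands:
        n, f = atomic_names(g)
        missing = [c for c in (n, f) if c not in table.samples]
        if missing:
            raise ValueError(f"merge_labor: missing labor column(s) {missing} for gland {g.value}")
        new[merged_name(g)] = table.df[n] + table.df[f]
    return table.with_columns(new)


def normalize(
    table: SpectralCountTable,
    totals_override: Mapping[str, float] | None = None,
) -> NormalizedCountTable:
    """Divide each sample column by its total spectral count.

    *totals_override* supplies denominators when the table is an excerpt
    whose own column sums are not the real per-sample totals (e.g. a
    curated benchmark slice of a full proteome table).
    """
    totals = table.column_totals().astype(float)
    if totals_override is not None:
        for s, t in totals_override.items():
            if s in totals.index:
                totals[s] = float(t)
    zero = [s for s in table.samples if totals[s] <= 0]
    if zero:
        raise DegenerateInputError(f"zero column total for sample(s) {zero}; supply totals_override")
    df = table.df.copy()
    for s in table.samples:
        df[s] = df[s] / totals[s]
    return NormalizedCountTable(df, totals)


def find_frequent(
    merged: SpectralCountTable,
    frequent_min: int = 100,
    glands: Sequence[Gland] = tuple(Gland),
) -> dict[Gland, list[FrequentCall]]:
    """Apply the strict >threshold rule to the pooled (n+f) column per gland."""
    out: dict[Gland, list[FrequentCall]] = {}
    for g in glands:
        col = merged_name(g)
        if col not in merged.samples:
            raise ValueError(f"find_frequent: merged column {col!r} absent; run merge_labor first")
        calls = []
        for entry in merged.entries:
            c = merged.count(entry.accession, col)
            calls.append(FrequentCall(entry, g, c, c > frequent_min))
        out[g] = calls
    return out


def rank_proteins(merged: SpectralCountTable, gland: Gland) -> pd.DataFrame:
    """Rank proteins by pooled (n+f) count, descending; ties keep input order.

    Returns a frame with columns description, nurse, forager, merged count
    and a 1-based ``rank`` column (ties share their order by table order,
    which makes rankings deterministic).
    """
    col = merged_name(gland)
    if col not in merged.samples:
        raise ValueError(f"rank_proteins: merged column {col!r} absent; run merge_labor first")
    n, f = atomic_names(gland)
    cols = [c for c in ("description", n, f, col) if c in merged.df.columns]
    out = merged.df[cols].sort_values(col, ascending=False, kind="stable")
    out = out.copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _ratio(a: float, b: float) -> float:
    if b == 0:
        return np.nan if a == 0 else np.inf
    return a / b


def fold_change(
    table: SpectralCountTable | NormalizedCountTable,
    accession: str,
    sample_a: str,
    sample_b: str,
) -> float:
    """Ratio of *accession*'s value in *sample_a* over *sample_b*.

    On a raw table this is a raw-count ratio, which equals the
    normalized-count ratio exactly when the two samples' totals are equal
    (the equal-totals assumption for benchmark excerpts).
    """
    df = table.df
    if accession not in df.index:
        raise KeyError(f"accession {accession!r} not in table")
    for s in (sample_a, sample_b):
        if s not in df.columns:
            raise KeyError(f"sample {s!r} not in table")
    return _ratio(float(df.at[accession, sample_a]), float(df.at[accession, sample_b]))


def relative_to_reference(
    table: SpectralCountTable,
    target_accession: str,
    reference_accession: str,
) -> pd.Series:
    """Per-sample ratio target/reference, e.g. a protein's count over beta-actin's.

    Dividing by an internal-control protein makes one protein's counts
    comparable across samples.  The reference must be detected (count > 0)
    in every sample.
    """
    for acc in (target_accession, reference_accession):
        if acc not in table.df.index:
            raise KeyError(f"accession {acc!r} not in table")
    ref = table.counts.loc[reference_accession]
    zero = [s for s, v in ref.items() if v == 0]
    if zero:
        raise DegenerateInputError(
            f"reference {reference_accession!r} has zero count in sample(s) {zero}"
        )
    series = table.counts.loc[target_accession] / ref
    series.name = f"{target_accession}/{reference_accession}"
    return series.astype(float)
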