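"""Pathway mapping, spectral-count-weighted composition, and hypergeometric enrichment.

Proteins are mapped to pathway categories through an annotation table (as
exported from a pathway-mapping tool such as the KEGG Mapper).  Two
complementary summaries are computed:

* **Composition** — each (protein, category) assignment contributes the
  protein's full spectral count; a protein annotated to two categories is
  counted redundantly in both, and the denominator is the sum over
  assignments at the chosen level.  Percentages therefore describe where
  the spectra fall, not where the proteins fall.
* **Enrichment** — membership-only hypergeometric upper tails
  P(X >= k) for drawing k category members in a selection of n mapped
  proteins from a background of N containing K members.  Spectral counts
  play no role here; permuting them never changes a p-value.

Benjamini-Hochberg adjusted q-values are available but off by default
(raw p-values are the primary report).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import AnnotationTable, DegenerateInputError

__all__ = [
    "EnrichmentInput",
    "CompositionRow",
    "map_proteins",
    "category_composition",
    "hypergeom_pvalue",
    "enrich_categories",
]

LEVELS = ("category", "subcategory", "pathway_name")


@dataclass(frozen=True)
class EnrichmentInput:
    """Contingency for one category: background N/K, selection n/k."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        ok = 0 <= self.k <= min(self.n, self.K) and self.n <= self.N and self.K <= self.N and self.N > 0
        if not ok:
            raise ValueError(f"invalid hypergeometric contingency N={self.N} K={self.K} n={self.n} k={self.k}")


@dataclass(frozen=True)
class CompositionRow:
    """Spectral-count share of one category at the reported level."""

    name: str
    assigned_spectral_count: float
    percentage: float


def map_proteins(
    proteins: Iterable[str],
    annotation: AnnotationTable,
) -> tuple[set[str], list[str], pd.DataFrame]:
    """Split *proteins* into mapped/unmapped and return their annotation records.

    A protein is mapped iff at least one annotation record exists for it.
    Multi-category proteins appear once in the mapped set but once per
    record in the returned assignment frame.
    """
    prots = set(proteins)
    ann = annotation.df
    assignments = ann[ann["accession"].isin(prots)].reset_index(drop=True)
    mapped = set(assignments["accession"])
    unmapped = sorted(prots - mapped)
    return mapped, unmapped, assignments


def category_composition(
    proteins: Iterable[str],
    counts: Mapping[str, int] | pd.Series,
    annotation: AnnotationTable,
    level: str = "category",
    fractional: bool = False,
) -> list[CompositionRow]:
    """Spectral-count-weighted category shares for the mapped subset of *proteins*.

    Each assignment of a protein to a category at *level* contributes the
    protein's full count (redundant counting across categories); rows are
    sorted by percentage descending.  With ``fractional=True`` a protein's
    count is instead split evenly across its labels, so multi-category
    proteins are not overweighted (non-default).
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    mapped, _, assignments = map_proteins(proteins, annotation)
    if not mapped:
        raise DegenerateInputError("no protein in the selection is annotated")
    counts = pd.Series(counts)
    missing = mapped - set(counts.index)
    if missing:
        raise KeyError(f"no counts supplied for mapped protein(s): {sorted(missing)}")
    # one assignment per distinct (protein, level-label) pair
    per_label = assignments[["accession", level]].drop_duplicates()
    weighted = per_label.assign(count=per_label["accession"].map(counts).astype(float))
    if fractional:
        weighted["count"] /= weighted.groupby("accession")["accession"].transform("size")
    sums = weighted.groupby(level)["count"].sum().sort_values(ascending=False)
    denom = float(sums.sum())
    return [
        CompositionRow(str(name), float(v), 100.0 * float(v) / denom)
        for name, v in sums.items()
    ]


def hypergeom_pvalue(inp: EnrichmentInput) -> float:
    """Upper-tail P(X >= k) of the hypergeometric(N, K, n) distribution."""
    # sf(k-1) = P(X >= k); k = 0 gives exactly 1
    return float(hypergeom.sf(inp.k - 1, inp.N, inp.K, inp.n))


def enrich_categories(
    selected: Iterable[str],
    background: Iterable[str],
    annotation: AnnotationTable,
    level: str = "category",
    adjust: bool = False,
) -> pd.DataFrame:
    """Hypergeometric enrichment of *selected* within *background*, per category.

    Both sets are first restricted to mapped proteins; the background
    universe is the mapped background (configurable by the caller through
    what it passes as *background*).  Returns one row per category present
    in the background with columns N, K, n, k, p (and q when *adjust*).
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    selected, background = set(selected), set(background)
    if not selected <= background:
        raise ValueError("selected proteins must be a subset of the background")
    bg_mapped, _, bg_assign = map_proteins(background, annotation)
    sel_mapped = selected & bg_mapped
    N, n = len(bg_mapped), len(sel_mapped)
    per_label = bg_assign[["accession", level]].drop_duplicates()
    rows = []
    for label, members in per_label.groupby(level)["accession"]:
        mem = set(members)
        K, k = len(mem), len(mem & sel_mapped)
        p = hypergeom_pvalue(EnrichmentInput(N, K, n, k))
        rows.append((str(label), N, K, n, k, p))
    out = pd.DataFrame(rows, columns=[level, "N", "K", "n", "k", "p"]).sort_values(
        ["p", level], kind="stable"
    ).reset_index(drop=True)
    if adjust and len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
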