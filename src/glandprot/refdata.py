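"""Curated benchmark tables for the worker honeybee exocrine-gland proteomes.

Four small reference tables ship with the package and anchor the test
suite; all are excerpts of the published six-gland spectral-count data for
*Apis mellifera* workers (postcerebral, thoracic, and mandibular glands of
nurse bees and foragers):

* ``top30_<gland>`` — the 30 most frequently detected proteins per gland
  with nurse/forager counts, the printed pooled (n+f) count, and (head
  glands only) the rank in an earlier, smaller shotgun study;
* ``vatpase`` — all 17 identified V-ATPase subunit proteins across the six
  samples (11 of which are frequently detected in the thoracic gland);
* ``cyp`` — the 14 identified cytochrome P450 enzymes with six-sample
  counts plus the curated mandibular-gland selectivity (S) and abundance
  (A) flags;
* ``lipid_metabolism`` — frequently detected proteins of the "Lipid
  metabolism" subcategory with pooled per-gland counts and their pathway
  assignments.

Because these are excerpts, the column sums are NOT the per-sample total
spectral counts (those are all close to 40,000 in the full data); analyses
on them use the equal-totals assumption.
"""

from __future__ import annotations

import csv
from importlib import resources

import pandas as pd

from .core import AnnotationTable, SpectralCountTable
from .samples import ATOMIC_SAMPLE_NAMES, Gland, atomic_names

__all__ = [
    "top30_table",
    "top30_frame",
    "vatpase_table",
    "cyp_table",
    "cyp_frame",
    "lipid_metabolism_table",
    "lipid_metabolism_annotation",
]

_FILES = {
    Gland.PcG: "top30_pcg.tsv",
    Gland.TG: "top30_tg.tsv",
    Gland.MG: "top30_mg.tsv",
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("glandprot.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", quoting=csv.QUOTE_MINIMAL, dtype={"accession": str}, keep_default_na=False)


def _as_count_table(df: pd.DataFrame, samples: list[str]) -> SpectralCountTable:
    out = df[["accession", "description"] + samples].set_index("accession")
    return SpectralCountTable(out)


def top30_frame(gland: Gland | str) -> pd.DataFrame:
    """Raw frame of the top-30 benchmark for *gland*, incl. ``merged_printed``."""
    return _read(_FILES[Gland(gland)])


def top30_table(gland: Gland | str) -> SpectralCountTable:
    """Top-30 benchmark as a two-sample (nurse, forager) count table."""
    g = Gland(gland)
    return _as_count_table(top30_frame(g), list(atomic_names(g)))


def vatpase_table() -> SpectralCountTable:
    """All 17 identified V-ATPase subunit proteins, six-sample counts."""
    return _as_count_table(_read("vatpase.tsv"), list(ATOMIC_SAMPLE_NAMES))


def cyp_frame() -> pd.DataFrame:
    """Raw CYP benchmark incl. gene names and curated S/A flags."""
    return _read("cyp.tsv")


def cyp_table() -> SpectralCountTable:
    """The 14 identified cytochrome P450s as a six-sample count table.

    Rows whose printed count block covers several accessions are kept as a
    single entry under the first accession (the count is per printed row,
    not per accession); the gene name is carried in the description.
    """
    df = cyp_frame()
    df = df.assign(description=df["gene_name"])
    return _as_count_table(df, list(ATOMIC_SAMPLE_NAMES))


def lipid_metabolism_table() -> SpectralCountTable:
    """Pooled per-gland counts of the lipid-metabolism benchmark, deduplicated.

    Proteins listed under several pathways appear once; their counts are
    identical across listings.  Sample columns are the pooled ``(n+f)X``
    glands.
    """
    df = _read("lipid_metabolism.tsv")
    merged_cols = [c for c in df.columns if c.startswith("(n+f)")]
    dedup = df.drop_duplicates(subset="accession")
    return _as_count_table(dedup, merged_cols)


def lipid_metabolism_annotation() -> AnnotationTable:
    """Pathway assignments of the lipid-metabolism benchmark proteins."""
    df = _read("lipid_metabolism.tsv")
    recs = df[["accession", "pathway_id", "pathway_name"]].copy()
    recs["subcategory"] = "Lipid metabolism"
    recs["category"] = "Metabolism"
    return AnnotationTable(recs)
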