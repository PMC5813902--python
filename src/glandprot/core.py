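"""Core containers and TSV I/O for spectral-count proteomics tables.

Everything downstream works on three tables:

* :class:`SpectralCountTable` — protein-by-sample matrix of non-negative
  integer spectral counts (number of MS/MS spectra assigned to a protein in
  one sample), with an accession and free-text description per row.
* :class:`AnnotationTable` — many-to-many map from protein accession to
  pathway (id, name, subcategory, category), as produced by pathway-mapping
  tools such as the KEGG Mapper.
* scored PSM lists (:class:`PSMRecord`) with target/decoy flags.

File dialect: UTF-8 tab-separated values with a mandatory header row.
Absent proteins are explicit zeros, never blanks or ``.``.  Fields that
contain tabs/quotes are quoted per RFC-4180 so round-trips are exact.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "DegenerateInputError",
    "ProteinEntry",
    "SpectralCountTable",
    "NormalizedCountTable",
    "AnnotationTable",
    "PSMRecord",
    "CriteriaConfig",
    "read_count_table",
    "write_count_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_psms",
    "write_psms",
]

ANNOTATION_COLUMNS = ("accession", "pathway_id", "pathway_name", "subcategory", "category")
PSM_COLUMNS = ("spectrum_id", "accession", "score", "is_decoy")


class FormatError(ValueError):
    """A file does not conform to the expected TSV dialect/columns."""


class ValidationError(ValueError):
    """Table contents violate an invariant (negative counts, duplicates...)."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but degenerate for the requested operation."""


@dataclass(frozen=True)
class ProteinEntry:
    """One protein row: opaque accession plus free-text description.

    Accessions are treated as opaque identifiers; distinct accessions may
    legitimately share identical descriptions and counts (isoform rows).
    """

    accession: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("accession must be non-empty")


class SpectralCountTable:
    """Protein-by-sample matrix of non-negative integer spectral counts.

    Thin wrapper around a :class:`pandas.DataFrame` indexed by accession with
    a ``description`` column followed by one integer column per sample.
    Sample column names are arbitrary strings; the canonical six-sample
    honeybee design uses the names in :data:`glandprot.samples.ATOMIC_SAMPLE_NAMES`.
    """

    def __init__(self, df: pd.DataFrame, *, validate: bool = True):
        if "description" not in df.columns:
            df = df.copy()
            df.insert(0, "description", "")
        # sample columns keep their input order
        self._df = df.loc[:, ["description"] + [c for c in df.columns if c != "description"]]
        if validate:
            self.validate()

    # -- construction ---------------------------------------------------
    @classmethod
    def from_records(
        cls,
        entries: Sequence[ProteinEntry | str],
        counts: Mapping[str, Sequence[int]] | pd.DataFrame,
    ) -> "SpectralCountTable":
        """Build a table from entries plus a sample-name -> counts mapping."""
        ents = [e if isinstance(e, ProteinEntry) else ProteinEntry(e) for e in entries]
        df = pd.DataFrame(counts, index=pd.Index([e.accession for e in ents], name="accession"))
        df.insert(0, "description", [e.description for e in ents])
        return cls(df)

    # -- basic accessors ------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def samples(self) -> list[str]:
        return [c for c in self._df.columns if c != "description"]

    @property
    def accessions(self) -> list[str]:
        return list(self._df.index)

    @property
    def entries(self) -> list[ProteinEntry]:
        return [ProteinEntry(a, d) for a, d in self._df["description"].items()]

    @property
    def counts(self) -> pd.DataFrame:
        """The numeric sample block (view, accession-indexed)."""
        return self._df[self.samples]

    def count(self, accession: str, sample: str) -> int:
        return int(self._df.at[accession, sample])

    def description(self, accession: str) -> str:
        return str(self._df.at[accession, "description"])

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, accession: str) -> bool:
        return accession in self._df.index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralCountTable):
            return NotImplemented
        return self._df.equals(other._df) and list(self._df.columns) == list(other._df.columns)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<SpectralCountTable {len(self)} proteins x {len(self.samples)} samples>"

    # -- manipulation ---------------------------------------------------
    def subset(self, accessions: Iterable[str]) -> "SpectralCountTable":
        return SpectralCountTable(self._df.loc[list(accessions)].copy())

    def with_columns(self, new: Mapping[str, pd.Series | Sequence[int]]) -> "SpectralCountTable":
        df = self._df.copy()
        for name, col in new.items():
            df[name] = np.asarray(col, dtype=np.int64)
        return SpectralCountTable(df)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        idx = self._df.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate accessions: {dups}")
        if (idx.astype(str) == "").any():
            raise ValidationError("empty accession")
        block = self._df[self.samples]
        for col in self.samples:
            vals = block[col]
            if not np.issubdtype(vals.dtype, np.integer):
                arr = vals.to_numpy()
                if not np.all(np.equal(np.mod(arr, 1), 0)):
                    raise ValidationError(f"non-integer counts in column {col!r}")
                self._df[col] = vals.astype(np.int64)
            if (self._df[col] < 0).any():
                raise ValidationError(f"negative counts in column {col!r}")
            self._df[col] = self._df[col].astype(np.int64)


class NormalizedCountTable:
    """Relative spectral counts: each sample column divided by its total.

    Same shape as the source :class:`SpectralCountTable`; values are
    dimensionless fractions.  When the totals come from the table itself,
    every non-empty column sums to 1.
    """

    def __init__(self, df: pd.DataFrame, totals: pd.Series):
        self._df = df
        self.totals = totals

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def samples(self) -> list[str]:
        return [c for c in self._df.columns if c != "description"]

    @property
    def values(self) -> pd.DataFrame:
        return self._df[self.samples]

    def value(self, accession: str, sample: str) -> float:
        return float(self._df.at[accession, sample])

    def __len__(self) -> int:
        return len(self._df)


class AnnotationTable:
    """Many-to-many accession -> pathway map (pathway id/name, subcategory, category).

    An accession may carry zero, one, or several pathway records; redundant
    categorization is expected (e.g. V-ATPase subunits appear under both
    "Metabolism" and "Cellular processes").  (accession, pathway_id) pairs
    are unique.
    """

    def __init__(self, df: pd.DataFrame, *, validate: bool = True):
        missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"annotation table missing column(s): {missing}")
        self._df = df.loc[:, list(ANNOTATION_COLUMNS)].reset_index(drop=True)
        if validate:
            self.validate()

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str, str, str]]) -> "AnnotationTable":
        return cls(pd.DataFrame(list(records), columns=list(ANNOTATION_COLUMNS)))

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def validate(self) -> None:
        pairs = self._df[["accession", "pathway_id"]]
        if pairs.duplicated().any():
            dup = pairs[pairs.duplicated()].to_records(index=False).tolist()
            raise ValidationError(f"duplicate (accession, pathway_id) pairs: {dup}")
        if (self._df["accession"].astype(str) == "").any():
            raise ValidationError("empty accession in annotation table")

    def records_for(self, accession: str) -> pd.DataFrame:
        return self._df[self._df["accession"] == accession]

    def annotated_accessions(self) -> set[str]:
        return set(self._df["accession"])

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return self._df.equals(other._df)


@dataclass(frozen=True)
class PSMRecord:
    """One scored peptide-spectrum match with a target/decoy flag."""

    spectrum_id: str
    accession: str
    score: float
    is_decoy: bool

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValidationError(f"non-finite PSM score for {self.spectrum_id!r}")


@dataclass(frozen=True)
class CriteriaConfig:
    """All thresholds of the selection procedure, with the study defaults.

    frequent_min
        A protein is "frequently detected" when its pooled (nurse+forager)
        spectral count strictly exceeds this (default 100).
    unique_min
        Minimum aggregated count (inclusive, default 2) for a protein detected
        in exactly one group to be called specific/selective.
    fold_min
        Normalized-count fold excess (strict, default 5) over every comparison
        group required for a fold-based selectivity call.
    fdr_max
        Target-decoy false-positive-rate bound for PSM filtering (default 1%).
    min_spectra_per_protein
        Minimum retained spectra (inclusive, default 2) for a protein to enter
        the identified list.
    assume_equal_totals
        Treat all per-sample totals as equal (appropriate for table excerpts
        where the full-column totals, all near 40,000, are unavailable).
    """

    frequent_min: int = 100
    unique_min: int = 2
    fold_min: float = 5.0
    fdr_max: float = 0.01
    min_spectra_per_protein: int = 2
    assume_equal_totals: bool = False

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "assume_equal_totals":
                continue
            v = getattr(self, f.name)
            if not v > 0:
                raise ValidationError(f"{f.name} must be > 0, got {v}")
        if not (0.0 < self.fdr_max < 1.0):
            raise ValidationError(f"fdr_max must be in (0, 1), got {self.fdr_max}")

    def replace(self, **kw) -> "CriteriaConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_READ_KW = dict(
    sep="\t",
    quoting=csv.QUOTE_MINIMAL,
    dtype={"accession": str, "description": str},
    keep_default_na=False,
)


def read_count_table(path: str | Path, sample_columns: Sequence[str] | None = None) -> SpectralCountTable:
    """Read a spectral-count TSV: columns ``accession``, ``description``, then samples.

    If *sample_columns* is given, exactly those columns (in that order) are
    used as samples and must all be present; otherwise every column after
    ``description`` is a sample.  Merged ``(n+f)X`` columns are rejected on
    input — they are derived quantities and are always recomputed.
    """
    df = pd.read_csv(path, **_READ_KW)
    for col in ("accession", "description"):
        if col not in df.columns:
            raise FormatError(f"count table {path} missing column {col!r}")
    present = [c for c in df.columns if c not in ("accession", "description")]
    if sample_columns is not None:
        missing = [c for c in sample_columns if c not in present]
        if missing:
            raise FormatError(f"count table {path} missing sample column(s): {missing}")
        present = list(sample_columns)
    for c in present:
        if c.startswith("(n+f)"):
            raise FormatError(
                f"merged sample column {c!r} not accepted on input; merged counts are always recomputed"
            )
    df = df[["accession", "description"] + present]
    for c in present:
        try:
            numeric = pd.to_numeric(df[c])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric counts in column {c!r}: {exc}") from None
        df[c] = numeric
    df = df.set_index("accession")
    df.index.name = "accession"
    return SpectralCountTable(df)


def write_count_table(table: SpectralCountTable, path: str | Path) -> None:
    """Write a table as TSV; ``read_count_table(write(t)) == t`` bit-exactly."""
    table.df.to_csv(path, sep="\t", quoting=csv.QUOTE_MINIMAL, index=True, index_label="accession")


def read_annotation_table(path: str | Path) -> AnnotationTable:
    df = pd.read_csv(path, **_READ_KW)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation table {path} missing column(s): {missing}")
    return AnnotationTable(df.astype(str))


def write_annotation_table(table: AnnotationTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", quoting=csv.QUOTE_MINIMAL, index=False)


def read_psms(path: str | Path) -> list[PSMRecord]:
    df = pd.read_csv(path, **_READ_KW)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"PSM table {path} missing column(s): {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PSMRecord(
                spectrum_id=str(row.spectrum_id),
                accession=str(row.accession),
                score=float(row.score),
                is_decoy=bool(int(row.is_decoy)),
            )
        )
    return out


def write_psms(psms: Iterable[PSMRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(p.spectrum_id, p.accession, p.score, int(p.is_decoy)) for p in psms],
        columns=list(PSM_COLUMNS),
    )
    df.to_csv(path, sep="\t", quoting=csv.QUOTE_MINIMAL, index=False)
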