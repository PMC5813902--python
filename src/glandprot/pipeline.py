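"""End-to-end orchestration: counts in, selectivity/enrichment report out.

A run is fully described by a :class:`RunConfig` (input paths, thresholds,
toggles); identical config and inputs give byte-identical outputs, with
timestamps confined to the run log.  Stage errors are re-raised with the
stage name attached so a failing record is attributable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from .core import (
    CriteriaConfig,
    DegenerateInputError,
    NormalizedCountTable,
    SpectralCountTable,
    read_annotation_table,
    read_count_table,
)
from .enrichment import category_composition, enrich_categories
from .quantify import find_frequent, merge_labor, normalize, rank_proteins
from .samples import Gland, merged_name
from .selectivity import (
    SelectivityCall,
    gland_groups,
    labor_selective_proteins,
    selective_proteins,
    specific_proteins,
    venn_partition,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "report_tables"]

log = logging.getLogger("glandprot")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run (plus the input files)."""

    counts_path: str
    annotation_path: str | None = None
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    enrichment_level: str = "category"
    top_n: int = 30
    out_dir: str | None = None

    def to_flat(self) -> dict[str, str]:
        d: dict[str, str] = {
            "counts_path": self.counts_path,
            "annotation_path": self.annotation_path or "",
            "enrichment_level": self.enrichment_level,
            "top_n": str(self.top_n),
            "out_dir": self.out_dir or "",
        }
        for f in dataclasses.fields(CriteriaConfig):
            d[f.name] = str(getattr(self.criteria, f.name))
        return d

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in self.to_flat().items()]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kv: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            kv[k.strip()] = v.strip()
        crit_kw: dict[str, Any] = {}
        for f in dataclasses.fields(CriteriaConfig):
            if f.name in kv:
                raw = kv.pop(f.name)
                crit_kw[f.name] = raw.lower() == "true" if f.type == "bool" else type(f.default)(raw)
        return cls(
            counts_path=kv["counts_path"],
            annotation_path=kv.get("annotation_path") or None,
            criteria=CriteriaConfig(**crit_kw),
            enrichment_level=kv.get("enrichment_level", "category"),
            top_n=int(kv.get("top_n", "30")),
            out_dir=kv.get("out_dir") or None,
        )


@dataclass
class PipelineResult:
    """All stage outputs of one run plus a machine-readable summary."""

    config: RunConfig
    merged: SpectralCountTable
    normalized: NormalizedCountTable
    frequent: dict[Gland, pd.DataFrame]
    rankings: dict[Gland, pd.DataFrame]
    gland_specific: dict[str, set[str]]
    gland_selective: dict[str, list[SelectivityCall]]
    labor_selective: dict[Gland, dict[str, list[SelectivityCall]]]
    venn_regions: dict[frozenset, int]
    composition: dict[str, list] = field(default_factory=dict)
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict[str, Any] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def _calls_frame(calls: list[SelectivityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.entry.accession, c.entry.description, c.group, c.basis, c.own_value, c.max_other, c.fold)
            for c in calls
        ],
        columns=["accession", "description", "group", "basis", "own_value", "max_other", "fold"],
    )


class StageError(RuntimeError):
    """Wraps a stage failure with the stage name for attribution."""


def _stage(name: str):
    def deco(fn):
        def run(*a, **kw):
            try:
                return fn(*a, **kw)
            except DegenerateInputError:
                raise
            except Exception as exc:  # noqa: BLE001 - attribution wrapper
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return run

    return deco


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Read counts, merge labors, normalize, call frequent/selective proteins.

    When an annotation table is configured, spectral-count composition and
    hypergeometric enrichment (background = all identified proteins of the
    run) are added per gland.  With ``out_dir`` set, all stage tables are
    written as TSV together with ``summary.json`` and ``run.log``.
    """
    crit = config.criteria
    log.info("thresholds: %s", ", ".join(f"{k}={v}" for k, v in sorted(dataclasses.asdict(crit).items())))

    table = _stage("read_counts")(read_count_table)(config.counts_path)
    merged = _stage("merge_labor")(merge_labor)(table)
    normalized = _stage("normalize")(normalize)(
        table if not crit.assume_equal_totals else merged,
        {s: 1.0 for s in merged.samples} if crit.assume_equal_totals else None,
    )
    freq_calls = _stage("find_frequent")(find_frequent)(merged, crit.frequent_min)
    frequent = {
        g: pd.DataFrame(
            [(c.entry.accession, c.entry.description, c.merged_count) for c in calls if c.is_frequent],
            columns=["accession", "description", "merged_count"],
        )
        for g, calls in freq_calls.items()
    }
    rankings = {g: rank_proteins(merged, g) for g in Gland}
    groups = gland_groups()
    gland_specific = _stage("specific_proteins")(specific_proteins)(table, groups, crit.unique_min)
    gland_selective = _stage("selective_proteins")(selective_proteins)(table, groups, crit)
    labor_selective = {
        g: _stage("labor_selective")(labor_selective_proteins)(table, g, crit) for g in Gland
    }
    venn_regions = venn_partition(gland_specific)

    result = PipelineResult(
        config=config,
        merged=merged,
        normalized=normalized,
        frequent=frequent,
        rankings=rankings,
        gland_specific=gland_specific,
        gland_selective=gland_selective,
        labor_selective=labor_selective,
        venn_regions=venn_regions,
    )

    if config.annotation_path:
        annotation = _stage("read_annotation")(read_annotation_table)(config.annotation_path)
        background = set(table.accessions)
        for g in Gland:
            sel = {c.entry.accession for c in gland_selective[g.value]}
            counts = merged.df[merged_name(g)]
            try:
                result.composition[g.value] = category_composition(
                    sel, counts, annotation, config.enrichment_level
                )
                result.enrichment[g.value] = enrich_categories(
                    sel, background, annotation, config.enrichment_level
                )
            except DegenerateInputError as exc:
                result.notes.append(f"enrichment skipped for {g.value}: {exc}")

    result.summary = {
        "n_proteins": len(table),
        "column_totals": {s: int(t) for s, t in table.column_totals().items()},
        "n_frequent": {g.value: int(len(f)) for g, f in frequent.items()},
        "n_gland_specific": {g: len(s) for g, s in gland_specific.items()},
        "n_gland_selective": {g: len(c) for g, c in gland_selective.items()},
        "n_labor_selective": {
            g.value: {lab: len(c) for lab, c in d.items()} for g, d in labor_selective.items()
        },
        "venn_regions": {"+".join(sorted(k)): v for k, v in venn_regions.items()},
        "criteria": dataclasses.asdict(crit),
        "notes": result.notes,
    }

    if config.out_dir:
        _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.merged.df.to_csv(out / "merged.tsv", sep="\t")
    result.normalized.df.to_csv(out / "normalized.tsv", sep="\t")
    for g in Gland:
        result.frequent[g].to_csv(out / f"frequent_{g.value}.tsv", sep="\t", index=False)
        result.rankings[g].to_csv(out / f"ranking_{g.value}.tsv", sep="\t")
        _calls_frame(result.gland_selective[g.value]).to_csv(
            out / f"selective_{g.value}.tsv", sep="\t", index=False
        )
        for lab, calls in result.labor_selective[g].items():
            _calls_frame(calls).to_csv(out / f"labor_selective_{lab}.tsv", sep="\t", index=False)
    for g, table in result.enrichment.items():
        table.to_csv(out / f"enrichment_{g}.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2, sort_keys=True) + "\n")
    (out / "run.log").write_text(
        "\n".join(
            [f"{k} = {v}" for k, v in sorted(result.config.to_flat().items())]
            + [f"note: {n}" for n in result.notes]
        )
        + "\n",
        encoding="utf-8",
    )


def report_tables(result: PipelineResult) -> dict[str, pd.DataFrame]:
    """Human-readable tables: top-N rankings, selectivity flags, composition."""
    out: dict[str, pd.DataFrame] = {}
    for g in Gland:
        out[f"top{result.config.top_n}_{g.value}"] = result.rankings[g].head(result.config.top_n)

    flag_rows = []
    freq_acc = {g: set(result.frequent[g]["accession"]) for g in Gland}
    for g in Gland:
        for c in result.gland_selective[g.value]:
            flag_rows.append(
                (
                    c.entry.accession,
                    c.entry.description,
                    c.group,
                    "S",
                    "A" if c.entry.accession in freq_acc[g] else "-",
                )
            )
    out["selectivity_flags"] = pd.DataFrame(
        flag_rows, columns=["accession", "description", "gland", "selectivity", "abundance"]
    )
    for g, rows in result.composition.items():
        out[f"composition_{g}"] = pd.DataFrame(
            [(r.name, r.assigned_spectral_count, round(r.percentage)) for r in rows],
            columns=["category", "assigned_spectral_count", "percent"],
        )
    return out
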