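"""Target-decoy FDR filtering of PSMs and spectral-count protein inference.

The false-positive rate at a score threshold t is estimated as
``decoys(score >= t) / targets(score >= t)`` — the plain decoy/target ratio,
not the (2D)/(T+D) variant.  :func:`filter_psms` picks the lowest (most
permissive) threshold whose estimate stays below the bound, which maximizes
the number of retained target PSMs.  Ties at the threshold score are
inclusive for targets and decoys alike, so a tied decoy is never silently
dropped in favor of its target twin.

Protein inference is deliberately simple spectral counting: every retained
PSM contributes one count to its accession, with no grouping or parsimony
across shared peptides; proteins below ``min_spectra`` retained spectra are
excluded from the identified list but keep their raw counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import PSMRecord, SpectralCountTable, ValidationError
from .samples import SampleKey

__all__ = ["FdrCurvePoint", "FilterResult", "InferenceResult", "fdr_curve", "filter_psms", "infer_proteins"]


def _ratio_estimator(n_targets: int, n_decoys: int) -> float:
    if n_targets == 0:
        return 0.0 if n_decoys == 0 else math.inf
    return n_decoys / n_targets


@dataclass(frozen=True)
class FdrCurvePoint:
    """Cumulative target/decoy tallies at (and above) one score threshold."""

    score_threshold: float
    n_targets: int
    n_decoys: int
    fdr_estimate: float


@dataclass(frozen=True)
class FilterResult:
    """Outcome of FDR filtering: retained target PSMs plus the chosen threshold.

    ``threshold`` is None (and ``warning`` set) when no score threshold
    satisfies the bound; the retained set is then empty.
    """

    retained: tuple[PSMRecord, ...]
    threshold: float | None
    fdr_estimate: float | None
    warning: str | None = None


def fdr_curve(
    psms: Sequence[PSMRecord],
    estimator: Callable[[int, int], float] = _ratio_estimator,
) -> list[FdrCurvePoint]:
    """One point per distinct score, sorted by descending threshold.

    Counts are cumulative at-or-above the threshold, so ``n_targets`` and
    ``n_decoys`` are non-decreasing down the returned list.
    """
    if not psms:
        raise ValueError("fdr_curve requires at least one PSM")
    scores = np.array([p.score for p in psms])
    decoy = np.array([p.is_decoy for p in psms], dtype=bool)
    order = np.argsort(-scores, kind="stable")
    scores, decoy = scores[order], decoy[order]
    cum_decoys = np.cumsum(decoy)
    cum_targets = np.cumsum(~decoy)
    points: list[FdrCurvePoint] = []
    n = len(scores)
    for i in range(n):
        if i + 1 < n and scores[i + 1] == scores[i]:
            continue  # last index of this distinct score carries the tally
        t, d = int(cum_targets[i]), int(cum_decoys[i])
        points.append(FdrCurvePoint(float(scores[i]), t, d, estimator(t, d)))
    return points


def filter_psms(
    psms: Sequence[PSMRecord],
    fdr_max: float,
    estimator: Callable[[int, int], float] = _ratio_estimator,
) -> FilterResult:
    """Retain target PSMs at the most permissive threshold with FDR below *fdr_max*."""
    if not psms:
        raise ValueError("filter_psms requires at least one PSM")
    if not (0.0 < fdr_max < 1.0):
        raise ValueError(f"fdr_max must be in (0, 1), got {fdr_max}")
    ok = [p for p in fdr_curve(psms, estimator) if p.fdr_estimate < fdr_max]
    if not ok:
        return FilterResult(
            retained=(),
            threshold=None,
            fdr_estimate=None,
            warning=f"no score threshold achieves FDR < {fdr_max:g}; retaining nothing",
        )
    best = min(ok, key=lambda p: p.score_threshold)  # lowest threshold = most targets
    retained = tuple(p for p in psms if not p.is_decoy and p.score >= best.score_threshold)
    return FilterResult(retained=retained, threshold=best.score_threshold, fdr_estimate=best.fdr_estimate)


@dataclass(frozen=True)
class InferenceResult:
    """Per-sample spectral counts from retained PSMs.

    ``raw`` holds every accession's retained-spectrum tally; ``identified``
    is the subset meeting the minimum-spectra criterion for the identified
    list.  Both are accession-indexed count Series for one sample.
    """

    sample: SampleKey
    raw: pd.Series
    identified: pd.Series

    def as_table(self) -> SpectralCountTable:
        df = self.raw.to_frame(self.sample.name)
        df.index.name = "accession"
        return SpectralCountTable(df)


def infer_proteins(
    retained_psms: Sequence[PSMRecord],
    sample: SampleKey,
    min_spectra: int = 2,
    inclusive: bool = True,
) -> InferenceResult:
    """Tally retained PSMs per accession into one sample column.

    ``inclusive=True`` keeps proteins with count >= *min_spectra* in the
    identified list; ``inclusive=False`` applies a strict > reading.
    """
    if any(p.is_decoy for p in retained_psms):
        raise ValidationError("decoy PSMs must not reach protein inference")
    tally: dict[str, int] = {}
    for p in retained_psms:
        tally[p.accession] = tally.get(p.accession, 0) + 1
    raw = pd.Series(tally, dtype=np.int64, name=sample.name).sort_index()
    raw.index.name = "accession"
    if inclusive:
        identified = raw[raw >= min_spectra]
    else:
        identified = raw[raw > min_spectra]
    return InferenceResult(sample=sample, raw=raw, identified=identified)
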