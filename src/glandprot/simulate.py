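"""Seeded generators for six-sample count tables, PSM lists, and annotations.

The count generator emulates the scale of the honeybee gland shotgun
measurements: ~2,500 proteins per table, per-sample total spectral counts
near 40,000, and roughly 2,000 proteins detected (count > 0) per sample.
Counts are drawn from a gamma-Poisson (negative-binomial) model around
protein-specific expected rates, because spectral counts are overdispersed
integers; planted effects act multiplicatively on the expected rates
*before* sampling, so realized fold-changes fluctuate around the planted
fold.  Three kinds of ground truth are planted:

* **frequent** proteins — expected pooled (n+f) count in their gland well
  above twice the 100-count frequent threshold;
* **gland-selective** proteins — expected rate ``planted_fold`` times
  higher in their gland than in the other two;
* **labor-selective** proteins — expected rate ``planted_fold`` times
  higher in one (gland, labor) sample than in the same gland's other labor.

Every planted membership is recorded in a tidy truth table, so recovery
sensitivity/specificity of each downstream stage is computable without
manual labeling.  All randomness flows through one
:class:`numpy.random.Generator` seeded from the config, so a fixed seed
gives identical output on every run and platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AnnotationTable, PSMRecord, SpectralCountTable
from .samples import ATOMIC_SAMPLE_NAMES, Gland, Labor

__all__ = [
    "SimulationConfig",
    "DEFAULT_CATEGORIES",
    "simulate_counts",
    "simulate_psms",
    "simulate_annotation",
]

#: A small KEGG-style category palette: (pathway_id, pathway_name, subcategory, category).
DEFAULT_CATEGORIES: tuple[tuple[str, str, str, str], ...] = (
    ("ame00010", "Glycolysis / Gluconeogenesis", "Carbohydrate metabolism", "Metabolism"),
    ("ame00030", "Pentose phosphate pathway", "Carbohydrate metabolism", "Metabolism"),
    ("ame00061", "Fatty acid biosynthesis", "Lipid metabolism", "Metabolism"),
    ("ame00071", "Fatty acid degradation", "Lipid metabolism", "Metabolism"),
    ("ame00190", "Oxidative phosphorylation", "Energy metabolism", "Metabolism"),
    ("ame00250", "Alanine, aspartate and glutamate metabolism", "Amino acid metabolism", "Metabolism"),
    ("ame03010", "Ribosome", "Translation", "Genetic information processing"),
    ("ame04142", "Lysosome", "Transport and catabolism", "Cellular processes"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale conditions for the count generator.

    Defaults mirror the measured scale of the six-gland study: ~2,500
    proteins with ~40,000 spectra per sample.  ``planted_fold`` (default 10)
    is deliberately twice the 5-fold selectivity threshold so planted truths
    are recoverable with margin despite count noise.
    """

    n_proteins: int = 2500
    target_column_total: int = 40000
    n_frequent: int = 50           # planted frequent proteins per gland
    n_gland_selective: int = 30    # planted per gland
    n_labor_selective: int = 30    # planted per (gland, labor) sample
    planted_fold: float = 10.0
    baseline_dispersion: float = 0.01  # extra-Poisson CV^2 of the count model
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or self.target_column_total <= 0:
            raise ValueError("n_proteins and target_column_total must be positive")
        if min(self.n_frequent, self.n_gland_selective, self.n_labor_selective) < 0:
            raise ValueError("planted set sizes must be non-negative")
        if self.planted_fold <= 1:
            raise ValueError("planted_fold must exceed 1")
        if self.baseline_dispersion < 0:
            raise ValueError("baseline_dispersion must be non-negative")
        if self.n_planted > self.n_proteins:
            raise ValueError(
                f"planted sets need {self.n_planted} proteins but only "
                f"{self.n_proteins} are simulated"
            )

    @property
    def n_planted(self) -> int:
        return 3 * (self.n_frequent + self.n_gland_selective) + 6 * self.n_labor_selective


def _nb_counts(rng: np.random.Generator, lam: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with mean lam and variance lam + dispersion * lam^2."""
    if dispersion == 0:
        return rng.poisson(lam)
    shape = 1.0 / dispersion
    rates = rng.gamma(shape, lam * dispersion)
    return rng.poisson(rates)


def simulate_counts(config: SimulationConfig) -> tuple[SpectralCountTable, pd.DataFrame]:
    """Draw a six-sample count table with planted ground truth.

    Returns the table and a truth frame with one row per planted membership
    (columns ``accession``, ``role`` in {frequent, gland_selective,
    labor_selective}, ``group``: the gland, or the sample for labor
    selectivity).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    accessions = np.array([f"sim|{i:05d}" for i in range(n)])

    # background expected rates: lognormal, heavy-tailed like real SC tables
    lam = np.tile(rng.lognormal(mean=np.log(8.0), sigma=1.3, size=n)[:, None], (1, 6))

    perm = rng.permutation(n)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = perm[cursor : cursor + k]
        cursor += k
        return out

    glands = list(Gland)
    col = {name: j for j, name in enumerate(ATOMIC_SAMPLE_NAMES)}
    truth_rows: list[tuple[str, str, str]] = []

    def loguniform(lo: float, hi: float, size: int) -> np.ndarray:
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))

    for g in glands:
        own = [col[f"n{g.value}"], col[f"f{g.value}"]]
        idx = take(config.n_frequent)
        # expected merged count >> 2x the 100-count frequent threshold,
        # with headroom for the column rescaling below
        lam[idx[:, None], own] = loguniform(160.0, 450.0, config.n_frequent)[:, None]
        truth_rows += [(accessions[i], "frequent", g.value) for i in idx]

        idx = take(config.n_gland_selective)
        base = loguniform(8.0, 25.0, config.n_gland_selective)
        lam[idx, :] = base[:, None]
        lam[idx[:, None], own] = (config.planted_fold * base)[:, None]
        truth_rows += [(accessions[i], "gland_selective", g.value) for i in idx]

        for labor in (Labor.NURSE, Labor.FORAGER):
            sample = f"{labor.value}{g.value}"
            idx = take(config.n_labor_selective)
            base = loguniform(8.0, 25.0, config.n_labor_selective)
            lam[idx, :] = base[:, None]
            lam[idx, col[sample]] = config.planted_fold * base
            truth_rows += [(accessions[i], "labor_selective", sample) for i in idx]

    # scale each column's expectation to the target total; column-wise
    # scaling preserves every within-column (normalized) fold ratio
    lam *= config.target_column_total / lam.sum(axis=0, keepdims=True)

    counts = _nb_counts(rng, lam, config.baseline_dispersion)
    df = pd.DataFrame(counts, index=pd.Index(accessions, name="accession"), columns=list(ATOMIC_SAMPLE_NAMES))
    df.insert(0, "description", [f"simulated protein {i}" for i in range(n)])
    truth = pd.DataFrame(truth_rows, columns=["accession", "role", "group"])
    return SpectralCountTable(df), truth


def simulate_psms(
    n_targets: int,
    n_decoys: int,
    true_fdr_at_full: float = 0.3,
    seed: int = 0,
    n_proteins: int = 200,
    correct_loc: float = 10.0,
    incorrect_loc: float = 0.0,
    scale: float = 2.0,
) -> tuple[list[PSMRecord], np.ndarray]:
    """Scored PSM mixture with decoys drawn from the incorrect component.

    Target scores come from a two-component Gaussian mixture: a fraction
    ``true_fdr_at_full`` of targets are incorrect matches scoring like
    decoys (mean *incorrect_loc*), the rest are correct matches (mean
    *correct_loc*).  Returns the PSM list plus a boolean array marking
    which target PSMs are planted-incorrect (index-aligned with the
    returned targets-first ordering).
    """
    if n_targets <= 0 or n_decoys < 0:
        raise ValueError("n_targets must be positive and n_decoys non-negative")
    if not 0.0 <= true_fdr_at_full <= 1.0:
        raise ValueError("true_fdr_at_full must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_incorrect = int(round(true_fdr_at_full * n_targets))
    incorrect = np.zeros(n_targets, dtype=bool)
    incorrect[rng.choice(n_targets, size=n_incorrect, replace=False)] = True
    scores = np.where(
        incorrect,
        rng.normal(incorrect_loc, scale, size=n_targets),
        rng.normal(correct_loc, scale, size=n_targets),
    )
    prot = rng.integers(0, n_proteins, size=n_targets + n_decoys)
    psms = [
        PSMRecord(f"spec{i:06d}", f"sim|{prot[i]:05d}", float(scores[i]), False)
        for i in range(n_targets)
    ]
    decoy_scores = rng.normal(incorrect_loc, scale, size=n_decoys)
    psms += [
        PSMRecord(
            f"spec{n_targets + i:06d}",
            f"decoy|{prot[n_targets + i]:05d}",
            float(decoy_scores[i]),
            True,
        )
        for i in range(n_decoys)
    ]
    return psms, incorrect


def simulate_annotation(
    proteins: Sequence[str],
    categories: Sequence[tuple[str, str, str, str]] = DEFAULT_CATEGORIES,
    probabilities: Sequence[float] | None = None,
    mapping_probability: float = 0.6,
    multi_category_rate: float = 0.2,
    seed: int = 0,
) -> AnnotationTable:
    """Random accession -> pathway table over a fixed category palette.

    Each protein is mapped with probability *mapping_probability*; mapped
    proteins draw one pathway according to *probabilities* (uniform by
    default) and, at *multi_category_rate*, a second distinct pathway —
    producing the redundant categorization real pathway maps exhibit.
    """
    if probabilities is None:
        probs = np.full(len(categories), 1.0 / len(categories))
    else:
        probs = np.asarray(probabilities, dtype=float)
        if len(probs) != len(categories) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("probabilities must match categories and sum to 1")
    if not 0.0 <= mapping_probability <= 1.0 or not 0.0 <= multi_category_rate <= 1.0:
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    k = len(categories)
    for acc in proteins:
        if rng.random() >= mapping_probability:
            continue
        first = int(rng.choice(k, p=probs))
        chosen = [first]
        if k > 1 and rng.random() < multi_category_rate:
            others = [i for i in range(k) if i != first]
            p = probs[others] / probs[others].sum()
            chosen.append(int(rng.choice(others, p=p)))
        for i in chosen:
            pid, pname, sub, cat = categories[i]
            records.append((acc, pid, pname, sub, cat))
    return AnnotationTable.from_records(records)
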