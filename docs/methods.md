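# Methods

## The measurement and its unit

Each of the six samples — nurse and forager postcerebral (PcG), thoracic
(TG), and mandibular (MG) glands of worker honeybees — is one pooled
shotgun LC-MS/MS measurement.  The quantity carried through every stage is
the spectral count SC(p, s): the number of MS/MS spectra assigned to
protein p in sample s.  Spectral counts are a semiquantitative abundance
proxy; they scale with both abundance and protein length, and the pipeline
deliberately does **not** normalize by predicted molecular mass (hence
"frequently detected", not "most abundant").  Cross-sample comparisons use
the relative count r(p, s) = SC(p, s) / total(s), where total(s) is the
sample's total spectral count (all six totals are close to 40,000 in the
reference data).

## PSM filtering and protein inference

PSMs carry a search-engine score (higher = better) and a target/decoy
flag.  The false-positive rate at an inclusive score threshold t is
estimated as decoys(≥ t) / targets(≥ t) — the plain ratio, not the
(2D)/(T+D) variant; the estimator is an injectable function for users who
prefer another convention.  `filter_psms` retains targets at the lowest
(most permissive) distinct score whose estimate is strictly below the
bound (default 1%); because the target count is non-increasing in the
threshold, this simultaneously maximizes retained PSMs.  Ties at the
threshold are inclusive for targets and decoys alike, so a tied decoy can
veto a threshold but is never silently dropped.  If no threshold meets the
bound the result is an empty set with a warning record, not an exception.
The filter is applied per input PSM file (per measurement).

Protein inference is plain spectral counting per accession with no
grouping or parsimony across shared peptides, matching the
row-per-accession structure of the reference tables.  The identified list
keeps proteins with **≥ 2** retained spectra.  The inclusive reading is
used even though the rule is often phrased as "more than two spectra":
the curated CYP benchmark lists identified enzymes with a total count of
exactly 2, which only the inclusive reading admits.  A strict `> `
reading is selectable (`infer_proteins(..., inclusive=False)`).

## Selection rules and their thresholds

| parameter | default | comparison | meaning |
|---|---|---|---|
| `frequent_min` | 100 counts | strict > | pooled (n+f) count for "frequently detected" |
| `unique_min` | 2 counts | inclusive ≥ | aggregated count for unique-detection selectivity |
| `fold_min` | 5 | strict > | relative-count excess over every comparison group |
| `fdr_max` | 0.01 | strict < | target-decoy false-positive bound |
| `min_spectra_per_protein` | 2 spectra | inclusive ≥ | identified-protein criterion |

A protein is **group-selective** (gland-selective across the three pooled
glands, or labor-selective between nurse and forager within one gland)
through exactly one of two disjoint routes:

* **unique detection** — aggregated count ≥ `unique_min` in one group and
  exactly 0 in every other group;
* **fold excess** — relative count strictly greater than `fold_min` times
  the relative count of each other group (equivalently, of the strongest
  competitor), requiring at least one competitor to be non-zero.

Design choices made where the procedure was genuinely open:

* The fold comparison is against the **maximum** over the other groups,
  the conservative reading of "5-fold more than the other glands"; it
  reproduces every curated selectivity flag, including the boundary cases
  (pooled count 2, unique detection) and the non-calls (e.g. CYP6AS7 with
  pooled counts 9/16/9).
* `unique_min` is inclusive ≥ 2 for the same boundary-case reason as the
  identified-protein rule; both readings are one config field away.
* "Far greater than 5-fold" is operationalized as a plain strict > 5.0
  with no extra margin.
* A protein detected in only one group but below `unique_min` is called
  nowhere: zero-competitor cases belong to the unique-detection route
  only, never to fold excess.
* Rankings sort by pooled count descending with stable tie-breaking by
  input order, making report tables deterministic.

**Equal-totals mode.**  The shipped benchmark tables are excerpts; their
column sums are not the true measurement totals.  Since the six true
totals are all close to 40,000, `assume_equal_totals` treats the totals
as equal, under which relative-count folds coincide with raw-count folds.
All benchmark reproduction runs use this mode; full-table analyses use the
actual column totals.

**Fold sentinels.**  a/0 with a > 0 is +inf, 0/0 is NaN; both propagate
to reports rather than raising.

## Pathway composition and enrichment

Proteins map to pathway categories through a supplied annotation table
(accession → pathway id/name, subcategory, category); merging several
annotation sources into one table is the caller's responsibility.
Composition at a chosen level assigns each (protein, label) pair the
protein's full spectral count — **redundant counting**, because proteins
genuinely belong to several categories (V-ATPase subunits sit in both
"Metabolism" and "Cellular processes") — and divides by the sum over all
assignments, so percentages sum to 100 at the reported level.

Enrichment is membership-only: with N mapped background proteins, K of
them in a category, and n mapped selected proteins of which k are in the
category, the p-value is the hypergeometric upper tail P(X ≥ k), computed
with `scipy.stats.hypergeom.sf` (the test suite checks it against
exhaustive enumeration of draws for every universe N ≤ 12 and against
Monte-Carlo tails for N ≤ 30).  The background is whatever protein set the
caller passes — typically all identified proteins of the relevant
gland/sample set, the most defensible default universe; the pipeline uses
all identified proteins of the run.  Benjamini–Hochberg q-values are
available but off by default; raw p-values are the primary report.

## The synthetic-data generator

`simulate_counts` emulates the study's scale and structure: 2,500
proteins, six samples, expected column totals of exactly 40,000, ~2,200
proteins detected per sample.  Protein baseline rates are lognormal
(median 8 spectra/sample before rescaling, σ = 1.3 on the log scale),
giving the heavy-tailed count distribution real SC tables show.  Counts
are gamma-Poisson (negative-binomial) with variance λ + φλ²; the default
dispersion φ = 0.01 reflects near-Poisson sampling noise of a single
pooled measurement, not biological replicate variance (which the source
material bounds at roughly three-fold — see limitations).

Planted effects multiply expected rates before sampling:

* **frequent** (50/gland): own-gland per-sample rate log-uniform in
  160–450, so the pooled expectation stays above twice the 100-count
  threshold even after column rescaling;
* **gland-selective** (30/gland): baseline log-uniform 8–25 per sample in
  all glands, ×10 (`planted_fold`) in the own gland — twice the 5-fold
  calling threshold, so recovery has margin against count noise;
* **labor-selective** (30/sample): same construction within one
  (gland, labor) cell.

Columns are rescaled to the target total after planting; per-column
scaling leaves every relative-count ratio untouched, so planted folds
survive exactly in expectation.  All randomness flows through one
`numpy.random.Generator` per call, so a fixed seed reproduces tables
byte-identically across platforms.

What the generator does **not** emulate: shared peptides and protein
grouping ambiguity, correlated abundances between functionally related
proteins, protein-length bias of spectral counts, biological replicate
variability, and missingness that depends on abundance rather than
sampling.  Recovery results on synthetic data therefore demonstrate that
the calling rules are implemented correctly and are well-conditioned at
study scale — not that 5-fold thresholds have any particular sensitivity
on real glands.

`simulate_psms` draws target scores from a two-component Gaussian mixture
(correct matches at mean 10, incorrect at 0, σ = 2) with decoys from the
incorrect component, so the decoy/target ratio is a consistent estimate of
the incorrect fraction; `simulate_annotation` maps proteins onto a small
fixed palette of KEGG-style categories with a configurable multi-category
rate.

## Problem sizes and tolerances in the test suite

Benchmark reproduction runs on the shipped tables (30 + 30 + 30, 17, 14,
and 19 rows) and completes in well under a second.  Property suites use:
exhaustive hypergeometric enumeration for all N ≤ 12; 10⁵ Monte-Carlo
draws (agreement within 3 standard errors) for N ≤ 30; 1,000 random PSM
lists of 5–40 PSMs against a brute-force threshold scan; 20 simulated
studies at full scale (2,500 × 6 counts each) for planted recovery
(sensitivity ≥ 95%, background false-positive rate ≤ 5%); and 100 random
tables for the conservation invariants (merge totals, normalized column
sums, Venn region sums, composition percentages).  Normalized column sums
are checked to 1e-9; all count comparisons are exact.

## Known limitations

* Threshold-based calling only; no count-model significance testing of
  differential abundance (a deliberate non-goal).
* PSM-level FDR only, applied per measurement; no peptide- or
  protein-level FDR and no rescoring.
* Each accession is tallied independently, so isoform rows sharing all
  peptides carry duplicated counts, exactly as in the reference tables.
* The enrichment background is configurable but its "correct" choice is
  analysis-dependent; composition percentages with redundant counting sum
  to 100 by construction but overweight multi-category proteins (an
  even-split `fractional=True` mode exists and is not the default).
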