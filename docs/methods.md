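# Methods

## Screen normalization and per-pool statistics

A dual-luciferase well yields firefly (F, pathway-responsive) and Renilla
(R, constitutive) luminescence. The analysis never uses either channel
alone: the ratio F/R cancels any multiplicative factor common to both
channels of a well, which is the assay's mechanism for controlling cell
number and transfection efficiency. Wells with R = 0 are flagged and
excluded at parse time; they are never divided.

Per pool, the effect estimate is the median replicate ratio expressed as a
percentage of the same-plate negative-control median ("percent of
control"). Plate matching is the default and deliberate: plate-to-plate
drift in reagent age, read timing and cell seeding dominates HTS noise, so
controls only ever calibrate the plate they sit on. A config flag permits
cross-plate pooling of controls for instruments known to be drift-free.
When a pool's replicates span plates, each well's ratio is first divided
by its own plate's control median and the median of those normalized
ratios is taken; on a single plate this reduces to the plain
median-over-control-median.

Significance is a two-sample test of the pool's log₂ ratios against the
same-plate negative-control log₂ ratios. Log₂ is used throughout, so
"two-fold" is |log₂ effect| ≥ 1. The default test is Student's unpaired
two-tailed t-test. With the typical 3 replicate wells per pool the pooled
test draws its degrees of freedom mostly from the (larger) control group
and retains power; Welch's correction, by contrast, collapses to ~2
degrees of freedom in this design and its α=0.01 critical value (≈7–10)
destroys sensitivity at realistic effect sizes, so Welch is offered as an
option rather than the default. A permutation test (exhaustive up to 10⁵
reassignments, Monte Carlo beyond) is also available; its p-values are
exact for the reassignment null and are the reference the t-approximation
is checked against.

Degenerate inputs follow two conventions, shared by every test in the
package: both groups constant and equal → p = 1.0; both groups constant
but unequal → p equals the smallest positive normal float. This keeps
downstream threshold filters free of NaNs without ever manufacturing
significance from noise-free ties.

The volcano table (one row per pool: percent of control, p-value, log₂
effect) is sorted by ascending p with ties broken lexicographically by
pool id, and round-trips through TSV at 6 significant digits.

## Hit calling

A pool is a hit when percent of control is at or beyond 2-fold in either
direction (inclusive boundary) **and** p < 0.01 (strict). A gene is a
consensus hit only when every pool targeting it is a pool hit — an
intentionally stringent rule that uses the redundancy of multiple
independent siRNA pools per gene as an off-target filter. Direction
agreement across pools is *not* required by default, because the consensus
rule as defined constrains only magnitude and significance; mixed-direction
genes are reported via `direction_mix` and a `require_direction_consensus`
flag restricts the call when desired (the restricted hit set is provably a
subset of the default). Raw p-values are thresholded by default, matching
the historical criterion; Benjamini–Hochberg adjustment is available via
config for prospective reuse.

Both thresholds are monotone by construction: lowering α or raising the
fold threshold can only remove hits.

## Evidence integration

Gene symbols are the join key across evidence sets. Harmonization trims,
uppercases, applies a caller-supplied alias map (itself case-normalized)
and deduplicates; unmapped entries are kept verbatim-uppercased and
logged rather than dropped, since most symbols legitimately have no alias
entry.

The disease-association list is produced by querying a serialized
gene-record dump (JSON lines) for a keyword in the description or summary
fields — case-insensitive and whole-word by default, so a query for
"melanoma" does not match "melanomagenesis". The dump-based design is
offline-first on purpose: keyword hits against a live database are a
function of its snapshot date and cannot be reproduced later. A live
Entrez helper exists for building fresh dumps but nothing in the analysis
or tests depends on it.

The 3-set overlap report carries both the seven exclusive Venn regions and
the three pairwise totals, because published overlap figures are
ambiguous between the two readings; the identity pairwise = exclusive +
triple makes either checkable. Nomination returns all genes supported by
at least two sets, triple-overlap genes first, alphabetically within
rank — a deterministic function of the sets.

## AP-MS background subtraction

Subtraction is presence/absence on protein labels: a prey is removed if it
appears in the control-purification prey list or on a common-contaminant
list, with the control taking precedence in the recorded reason. No
count-ratio scoring is applied by default because the filter being modeled
is pure subtraction; a minimum spectral-count option (default 1 = off)
exists for noisier runs. Every input row is preserved in the output with
its retention flag and reason — no silent drops — which makes the
operation idempotent and auditable. The bait appearing as its own prey is
retained and tagged `bait_self` (bait recovery is a positive control),
but is not counted as an interactor by `retained_preys` unless requested.
Networks export as SIF or TSV in deterministic lexicographic order.

## Validation assays

* **Reporter comparisons** — per-replicate F/R ratios, group means and
  SEMs, unpaired two-tailed Student t-test by default (Welch via flag),
  requiring ≥2 replicates per group.
* **ΔΔCt** — ΔCt = target − reference per sample; ΔΔCt subtracts the mean
  calibrator ΔCt; RQ = E^(−ΔΔCt) with amplification efficiency E = 2 by
  default (SYBR assays without standard-curve calibration), exposed as a
  parameter. Because ΔCt is a within-sample difference, any global Ct
  shift (RNA input) cancels exactly. Ct values outside (0, 45) are
  rejected; rows missing the reference Ct are excluded with a warning.
* **TUNEL** — percent positive = 100 · Σ TUNEL / Σ DAPI with counts summed
  across fields *before* division. Summing weights nuclei, not fields; a
  mean of per-field percentages would let a sparse field dominate, and the
  two aggregations demonstrably differ on unbalanced fields.
* **Densitometry** — signal density / loading-control density per
  condition, scaled to the maximum ratio = 100%. Invariant to rescaling
  all loading densities by a common factor; at least one condition always
  reads exactly 100.

## Synthetic data

The screen generator models a well's two channels as

```
F = F₀ · 2^e · c · εF      R = R₀ · c · εR
```

with planted log₂ effect *e* (0 for non-regulators and negative
controls), a shared log-normal cell-number factor *c* (CV 0.2 by default)
and independent log-normal channel noise εF, εR (CV 0.2). Because *c*
multiplies both channels, the simulated F/R ratio cancels it — the
simulator reproduces exactly the nuisance structure the dual-luciferase
normalization exists to remove, and `cell_number_cv` can be raised
arbitrarily without affecting ratio-based analysis. All log-normal
factors are unit-mean.

Desk-scale defaults: 500 genes, 1 pool per gene, 3 replicate wells per
pool laid out contiguously on 384-well plates carrying 16 negative and 4
positive control wells each; 10% true regulators with |log₂ effect| = 2
(sign random). A `paper_scale()` preset generates 28,044 pools over
19,490 genes on 1536-well plates for soak testing. Every generator is a
pure function of (config, seed) via a named per-stage generator, so
stages can be re-run independently and identical calls are byte-identical.

Evidence simulation plants exactly `n_triple` regulators in both the
phosphoproteomic and disease sets and keeps every other gene out of at
least one of the two, making the planted triple overlap exact with
respect to the regulator set; disease membership is realized as record
text containing the query keyword, with one in five non-members carrying
a compound-word decoy that whole-word matching must reject. The AP-MS
simulator draws shifted-Poisson spectral counts (≥1) and duplicates a
configurable fraction of preys into the control list. Assay simulators
plant per-condition folds/rates with the same shared-factor noise
structure (reporter), per-sample global Ct shifts that ΔΔCt must cancel
(qPCR), and binomial field counts with Poisson cellularity (TUNEL).

What the simulators do **not** model: spatial plate artifacts (edge
effects, gradients), siRNA off-target seed effects, count overdispersion
beyond Poisson in AP-MS, and qPCR efficiency drift. Passing tests
therefore demonstrate correctness of the computations under clean
multiplicative noise, not robustness to those real-world artifacts; a
B-score-style spatial corrector is explicitly out of scope.

## Numerical and design choices

* p-value conventions for degenerate variance as above; Monte-Carlo
  permutation p uses the add-one estimator and a per-pool seed derived
  from the pool id (never the row position), so results are invariant to
  input row order.
* Permutation enumeration is exhaustive whenever C(n, k) ≤ 10⁵.
* Volcano and gene tables sort with stable keys; all set operations are
  order-free; the pipeline report is JSON with sorted keys — repeated
  seeded runs are byte-identical.
* Plates need ≥2 usable negative controls to participate; pools lacking
  usable wells yield flagged summaries with NaN statistics rather than
  errors, and NaN p-values classify as non-hits with a warning.
* Problem sizes in the test suite (500-gene screens, 12-observation
  permutation comparisons, 200-replicate uniformity checks) were chosen
  as the smallest scales at which each property is statistically
  meaningful.

## Known limitations

The consensus "all pools must hit" rule has no tolerance parameter (e.g.
"all but one"); genes with many pools are penalized under noise. The
keyword query is intentionally simple (no stemming, no synonym
expansion) — it reproduces a text-match procedure, not a curated disease
ontology. AP-MS filtering is binary; quantitative enrichment scoring
(SAINT/CompPASS style) is out of scope. EC50/dose–response fitting is not
included; dose metadata passes through untouched.
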