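# Methods

## The activity score

The package quantifies disulfidptosis — disulfide-stress-driven cell
death — from transcriptomes using two curated regulator gene sets: 9
positive regulators (the cystine importer *SLC7A11*/*SLC3A2* and the WAVE
regulatory complex genes whose products are crosslinked under disulfide
stress) and 12 negative regulators (NADPH-producing pentose-phosphate
enzymes, glucose transporters and mitochondrial genes that buffer the
stress).  A sample's activity score is the enrichment of the positive set
minus the enrichment of the negative set, so it rises when the
death-promoting program dominates the death-suppressing one.

### Single-sample enrichment (bulk)

For sample *j*, genes are ranked ascending by expression with average
ranks at ties, then traversed in decreasing rank order.  The score is the
sum over all positions of the difference between the rank-weighted
in-set cumulative fraction (weight `rank**alpha`) and the uniform
out-of-set cumulative fraction — the *sum-of-deviations* single-sample
statistic, not the max-deviation statistic of two-class GSEA.

Model assumptions worth knowing:

* **Scale freedom.** Only within-sample ranks enter, so the score is
  invariant under any strictly increasing per-sample transform; linear
  and log2 input give identical results, and the `log2` flag is recorded
  metadata only.
* **Weight exponent `alpha`** (default 0.25, unitless): the conventional
  single-sample weight.  Larger values concentrate weight on the most
  highly expressed set members; 0 makes the in-set walk uniform.
* **Normalization** (default on): all scores in one call are divided by
  the joint max−min range over every set and sample.  This makes scores
  comparable within a call but **not across calls**; the positive and
  negative sets are therefore always scored together, so the shared range
  cancels in the difference.  Cohorts are scored independently
  (cohort-local range), matching per-dataset analysis practice.
* **Determinism.** Rank ties in the traversal are broken
  lexicographically by gene id, so results are bit-reproducible across
  platforms.  Zero-variance and all-zero genes are kept — they still
  carry within-sample rank information; filtering is the caller's choice.
* **No re-standardization.** Scores are not z-scaled per cohort before
  differencing by default (`zscale` exists for users who want it); the
  difference of jointly normalized enrichments is the primary statistic.

### Module score (single cell)

Sparse single-cell matrices use the binned-control-gene module score:
genes are ordered by mean expression across cells (lexicographic
tie-break) and cut into `nbin` equal-frequency bins (default 24); for
each module gene, `n_ctrl` control genes (default 100) are drawn without
replacement from its bin, excluding module genes and capping at the bin's
size; the score is the mean expression of module genes minus the mean of
the pooled control draws (pooled as a multiset — a gene drawn for two
module genes counts twice, keeping the estimator an unweighted mean of
per-gene bin controls).  Subtracting expression-matched controls removes
the abundance/depth component a raw module mean would carry; a constant
added to every gene cancels exactly.

Input is expected log-normalized; `normalize_counts` applies
counts-per-10k + log1p for raw counts.  Control draws are seeded; the two
regulator sets draw from independent streams (`seed`, `seed + 1`)
assigned in lexicographic set-name order, which makes the draw of each
set independent of its direction tag — swapping the tags negates every
cell's score exactly.  Malignant (or other) subsets are split at the
median activity; ties at the median go to "suppressive" so "activated"
is strictly above the median.

## Survival dichotomization

`maxstat_cutpoint` implements the maximally selected rank statistic.
Subjects receive log-rank (Nelson–Aalen) scores
`a_i = event_i − H(t_i)`, with `H` the Nelson–Aalen cumulative hazard at
the subject's observed time.  For a candidate cutpoint μ the statistic is
the standardized sum of `a_i` over the low group (score ≤ μ), using the
permutational mean and variance

```
E = m·ā,   Var = m(n−m)/(n(n−1)) · Σ(a_i − ā)²
```

where m is the low-group size.  Candidates are observed score values
keeping at least `ceil(minprop·n)` subjects per arm (`minprop` default
0.1, the cited convention); the selected cutpoint maximizes the absolute
statistic, ties resolved toward the smaller score.  This
rank-score formulation is the standard maximally-selected-statistics
construction; it orders splits the same way as per-split log-rank tests
while making the exhaustive scan an O(n) cumulative sum.

Because the maximum over many correlated candidates is far from
chi-square distributed, significance uses a **seeded permutation test**
(scores permuted against survival, default 1000 permutations; the p-value
is the fraction of permuted maxima reaching the observed one) rather than
an asymptotic improved approximation — exact in distribution at cohort
scale and free of special functions.  Kaplan–Meier curves, the two-group
log-rank test and univariate Cox fits (HR, asymptotic 95% CI, Wald p)
delegate to lifelines; their contracts are pinned by hand-computed
product-limit and O−E/V examples and by parameter-recovery tests.  A
median split is available alongside maxstat, as both conventions appear
in practice.

## Association layer

Fold change is the ratio of group means on linear-scale values (log2
input is unlogged first); a zero denominator is flagged infinite rather
than silently dropped.  Two-group comparisons use the two-sided Wilcoxon
rank-sum test — exact enumeration when the pooled sample is tie-free and
≤ 10 observations (`exact_threshold`), tie-corrected normal approximation
without continuity correction otherwise, so the p-value is symmetric in
the labels.  Three or more groups use tie-corrected Kruskal–Wallis.
Correlation is Spearman's rho with the t-approximation p-value.  BH
adjustment is the step-up `min_{j≥i}(m·p_(j)/j)` clipped at 1, applied
within each profile invocation; significance conventions are reporting
flags, never data filters.  `hallmark_correlation_profile` wires these
into a sorted rho/p/FDR table of any feature-by-sample matrix (hallmark
ssGSEA scores, immune deconvolution outputs) against the activity score.

## Synthetic study conditions

The generators define the conditions every statistical claim is tested
under; their defaults are fixed once:

* **Bulk contrast** — 2000 genes, 20 samples per condition, gene
  baselines log2 ~ Normal(5, 2), noise SD 1.0 log2 units, and a +1 log2
  shift of the 9 positive regulators in condition B.  One log2 unit on a
  between-sample SD of 1 is a strong but realistic treatment effect for a
  starvation contrast; 20 per arm is a typical validation-series size.
* **Survival** — standard-normal score; exponential event times with
  hazard `h0·exp(beta·score)` (h0 = 0.05 per time unit, planted log-HR
  0.7) or a step hazard at a score threshold; independent exponential
  censoring whose rate is solved by Brent's method so the expected
  censored fraction equals `censor_rate` (default 0.3, a common cohort
  censoring level).  The step-recovery experiment uses a step log-HR of
  1.0 at the score median with n = 200 — a strong prognostic dichotomy.
* **Single cell** — log-normal gene means, negative-binomial counts
  drawn as a Gamma–Poisson mixture (shape 2), optional Bernoulli
  dropout; malignant cells (40% of 500) have their negative-regulator
  means multiplied by `module_shift` (default 2), planting a *lower*
  activity score in malignant cells.

All generators route randomness through numpy's PCG64 (`default_rng`)
with a mandatory seed, so fixtures are bit-reproducible across platforms.
What they deliberately do **not** emulate: gene–gene correlation
structure, batch effects, probe-level artifacts, library-size gradients,
doublets, or the empirical distributions of any public dataset.  Passing
tests therefore demonstrate correctness of the algorithms and their
calibration under clean planted-effect conditions, not performance on any
particular cohort.

## Numerical choices and edge cases

* Gene symbols match case-sensitively by default (an optional case-fold
  flag exists) — silent case-folding can merge distinct symbols.
* A set covering no gene, or every gene, of a matrix is an error naming
  the set; missing set genes are dropped with a logged warning listing
  them.
* Joint normalization with a zero global range (a fully degenerate score
  table) is an error, not a silent division.
* Constant-matrix module scores are zero to the last floating-point bit
  (module and control means are sums of identical values in different
  group sizes).
* All-identical inputs to the rank tests return p = 1 (no rank
  information) instead of propagating a 0/0 from the tie correction.
* Cox non-convergence is surfaced as an error with the solver diagnostic;
  zero-variance covariates are rejected before fitting.
* The permutation p-value is the plain fraction of permuted maxima ≥
  observed; with `n_perm = 0` no p-value is computed and the cutpoint is
  unchanged.

## Problem sizes

The test suite and the acceptance script run the study conditions at
desk scale: 100 replicates for power-type claims, 200–500 for null
calibration, cohorts of n = 40–500 for survival properties, and random
fixtures of ≤ 50 genes × 5 samples for oracle equivalence.  These sizes
give binomial 99% bands tight enough to detect miscalibration of a few
percentage points while keeping a full run in minutes on one CPU.

## Known limitations

* The bulk normalization couples scores within a call; comparing absolute
  activity scores across separately scored cohorts is not meaningful.
* The module score inherits the usual binned-control caveats: very small
  bins (few genes, or modules dominating a bin) cap the control draw and
  increase sampling noise.
* The maxstat permutation test permutes the score vector, which assumes
  exchangeability of subjects under the null; covariate-adjusted
  cutpoints are out of scope.
* No imputation: matrices with missing values are rejected.
* The CLI exposes the analysis path end to end but not plotting beyond
  tabular outputs.
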