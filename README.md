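# disulfiscore

Disulfidptosis activity scoring for bulk and single-cell transcriptomes.

Disulfidptosis is a form of regulated cell death in which intracellular
disulfide accumulation (typically under glucose starvation in
SLC7A11-high cells) collapses the actin cytoskeleton.  A CRISPR
loss-of-function screen identified 21 regulator genes: 9 **positive**
regulators that promote the phenotype (*SLC7A11, SLC3A2, RPN1, NCKAP1,
CYFIP1, ABI2, WASF2, BRK1, RAC1*) and 12 **negative** regulators that
suppress it (*GYS1, NDUFS1, OXSM, LRPPRC, NDUFA11, NUBPL, G6PD, PGD,
TALDO1, TKT, SLC2A1, SLC2A3*).  `disulfiscore` turns those lists into a
per-sample (or per-cell) **disulfidptosis activity score** and provides
the downstream survival and association machinery built around it.  It is
aimed at computational biologists who want the scoring pipeline as a
tested, reproducible library rather than a collection of R one-liners.

## The method

For a bulk sample *j*, each regulator set *S* receives a single-sample
GSEA (ssGSEA) enrichment score.  With genes ranked ascending by
expression (rank *r<sub>g</sub>*, average at ties) and traversed in
decreasing rank order:

```
ES(S, j) = Σ_i [ P_in(i) − P_out(i) ]
P_in(i)  = Σ_{g∈S, pos(g)≤i} r_g^α / Σ_{g∈S} r_g^α        (α = 0.25)
P_out(i) = #{g∉S : pos(g)≤i} / (N − |S|)
```

Both sets are scored in one call and normalized jointly by the global
max–min score range; the **activity score** is

```
activity(j) = ES(positive, j) − ES(negative, j)
```

For single cells the ssGSEA score is replaced by the binned-control-gene
module score: mean expression of the module genes minus the mean of
expression-matched control genes drawn from mean-expression bins
(nbin = 24, 100 controls per module gene, seeded draws), and the activity
score is again the positive-module score minus the negative-module score.
Cells are split into *activated* (above the median activity) and
*suppressive* (at or below) subsets.

Downstream, the package dichotomizes cohorts by the **maximally selected
rank statistic** (the cutpoint of the score that maximizes the absolute
standardized log-rank statistic over all splits keeping ≥ `minprop` of
samples per arm, with a seeded permutation p-value), provides
Kaplan–Meier / log-rank / univariate Cox summaries (via lifelines), and
profiles the score against arbitrary feature tables (hallmark pathway
scores, immune features) with Spearman correlation and
Benjamini–Hochberg FDR.

A synthetic-data layer generates the study conditions end to end: bulk
two-condition contrasts with a planted regulator shift (the
glucose-starvation analogue), survival cohorts with score-dependent
hazard, and sparse negative-binomial single-cell counts with a malignant
subpopulation carrying a module shift.

## Worked example

```python
import disulfiscore as ds

# a two-condition cohort: 2000 genes, 20 samples per condition,
# +1 log2 shift on the 9 positive regulators in condition B
matrix = ds.simulate_bulk_contrast(ds.SimulationConfig(seed=1))

scores = ds.disulfidptosis_scores(matrix, ds.bundled_regulators())
report = ds.compare_score_by_condition(scores)
print(report["levels"], report["test"], f"p={report['p']:.2e}")
```

prints

```
{'A': {'n': 20, 'median': 0.327207646442539},
 'B': {'n': 20, 'median': 0.5451730399875057}} wilcoxon_rank_sum p=5.51e-06
```

i.e. the starved condition B carries a visibly higher median activity
score (0.545 vs 0.327 on the joint-range-normalized ssGSEA scale) and the
two-sided Wilcoxon rank-sum test detects the planted shift at
p ≈ 5.5 × 10⁻⁶.

The same pipeline is available from the shell:

```bash
disulfiscore simulate bulk --out-dir sim/ --seed 1
disulfiscore bulk --expr sim/expr.tsv --annotations sim/annotations.csv \
    --out scores.tsv --compare-condition condition
disulfiscore survival --scores scores.tsv --clinical clinical.csv \
    --out groups.tsv --split maxstat --n-perm 1000 --seed 1
```

Every command writes a `run_manifest.json` with input/output hashes and
seeds so deterministic runs can be replayed and verified.

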