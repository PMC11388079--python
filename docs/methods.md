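# Methods

This note documents the models and procedures implemented in `oncofetal`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not
demonstrate.

## Preprocessing convention

All expression-based operations consume a single normalization: counts per
10,000 per cell, then `log(1 + x)` with the natural log. Every downstream
statistic is rank- or contrast-based, so the choice of scale matters less
than its consistency; fixing one convention keeps signatures, scores and
CNV profiles comparable across stages. Cells with zero total counts are
retained as all-zero rows but excluded from scoring denominators — dropping
them silently would change per-sample proportions.

## Module detection and signature

Pseudobulks are arithmetic means of member cells' normalized rows, one per
sample × cell-type group with at least `min_cells` (default 10) cells.
Correlation runs on epithelial pseudobulks over the 2,000 most variable
genes (variance across pseudobulks); hierarchical clustering uses average
linkage on 1 − Pearson. The module-selection rule — maximize the fetal
fraction of a cluster, gated on the cluster containing at least one tumor
pseudobulk, ties broken to the larger cluster then the lowest label — makes
the visual "fetal + tumor co-cluster" selection algorithmic and
deterministic.

`n_clusters` is exposed (default 4). On the default synthetic cohort the
epithelium has exactly two macro-states (program-bearing vs
differentiated), so pipeline runs on synthetic data cut at 2; real cohorts
with more heterogeneity warrant deeper cuts.

The signature test is a per-gene two-sided Wilcoxon rank-sum
(normal approximation) with Benjamini–Hochberg control at α = 0.05. The
ranking statistic is the log2 ratio of group means on the expm1/CP10K
scale with pseudocount 1; only positive-fold-change genes are kept, top
`n_top` = 200 by default (150 in the synthetic tests, matching the planted
program size). Rank-sum + BH is the robust default for single-cell
contrasts; the ranking statistic is pinned so results are reproducible.

## Per-cell scoring

The raw score is a control-matched module score: genes with nonzero total
expression are ranked by mean expression and split into `n_bins` = 25
near-equal bins; each signature gene contributes its value minus the mean
of `n_ctrl` = 50 control genes drawn uniformly from its bin (without
replacement, excluding the gene itself; with replacement when the bin is
smaller). This cancels depth and mean-expression composition effects. The
draw is seeded and recorded in `ScoreVector.params`.

The zeroing rule sets scores at or below the 95th percentile
(linear interpolation) of normal-cell raw scores to zero; ties at the
threshold are zeroed (strict inequality). Fetal-like = positive adjusted
score restricted to epithelial cells; non-epithelial cells are scored but
never classified. By construction about 5% of truly program-free
epithelial cells exceed the threshold, so per-sample proportions carry a
false-positive floor of that order — visible in the calibration test.

The differentiation-potential surrogate is the per-cell detected-gene
count, averaged over each cell's `smooth_k` = 30 nearest neighbors
(Euclidean in the top 2,000 variable genes) and min-max rescaled to [0, 1].
It is a deliberate simplification of gene-count-based potency scoring —
counts plus smoothing, without the full signature-correlation/diffusion
machinery — and is used only to check the direction of the
score-vs-potential relationship.

## CNV profiles and malignancy

Genes with positions are ordered by (chromosome, start) with natural
numeric chromosome order. Per gene: subtract the reference-cell mean
(reference = normal epithelial + all endothelial cells), clip to
±`clip` × reference SD (`clip` = 3, SD floored at 1e−6), moving-average
over `window` = 101 genes within each chromosome with shrinking edge
windows, subtract each cell's median residual, then re-center so the
reference mean per gene is exactly 0. The per-cell median step removes
library-complexity shifts — cells that detect more genes are otherwise
uniformly offset and mimic genome-wide gains; it can be disabled
(`center_cells=False`), in which case residuals at `window=1, clip=∞`
equal the centered values exactly. Residual magnitudes are bounded by the
per-gene clip at the clipping stage; smoothing and centering keep them of
that order but the bound is per-gene (clip × SD), not a single constant.

The CNV score defaults to the mean absolute residual: a literal mean of
residuals is ≈ constant for every cell under centering, so deviation in
either direction is what carries malignancy information. The literal mean
is retained as `mode="raw-mean"` for comparison.

Malignancy calls need both gates: median score difference above
`min_effect` and BH-adjusted two-sided rank-sum p ≤ α (default 0.01)
against the pooled reference — with hundreds of cells, trivial differences
are significant, so significance alone would over-call. Candidate clusters
are the tumor-sample clusters (semi-supervised design); fetal epithelium,
for instance, is never a candidate.

## Regulator prioritization

Per-line oncofetal score: mean z-score across lines of log2(TPM + 1) over
signature genes. Per gene: Pearson r between log2(TPM + 1) and the line
score (zero-variance genes get r = 0 and can never pass), and the mean
CRISPR gene effect over lines with data (lower = more essential — the sign
convention is easy to trip over). Defaults r ≥ 0.3 and mean gene effect
≤ −0.4 (the latter reusing the printed essentiality bound); passing genes
are ranked by z(r) + z(|gene effect|), standardized over rankable genes.
Lineage specificity of a gene counts lineages among its top-k (default 10)
most-dependent lines with TPM > 1.

## Cohort analysis

Bulk scoring standardizes each signature gene within its source dataset
before averaging, guarding against batch shifts at the scoring stage in
addition to the dataset covariate in the regressions. Clinical
associations are OLS of score on one covariate plus dataset indicators;
coefficients come with normal-theory 95% CIs and BH adjustment across the
covariates tested. Covariates constant within every dataset are flagged
inestimable rather than silently absorbed.

The survival split scans every distinct score value as a cutoff
(high group = score > cutoff) subject to both groups holding ≥ `min_prop`
(default 0.1) of samples, and maximizes |standardized log-rank Z| (ties →
lower cutoff). Because the maximum over cutoffs is selection-biased, the
p-value is computed by permuting score–sample assignments
(default ≥ 1,000, seeded) and comparing max |Z|; the scan is vectorized via
cumulative at-risk/death tables so permutations cost O(n·K) each. The
log-rank variance uses the hypergeometric tie correction
d(y−d)/(y−1)·(y₁/y)(1−y₁/y); event times with one subject at risk
contribute nothing; zero total variance yields Z = 0. Kaplan–Meier curves
and the reported two-group chi-square come from lifelines; the internal Z
is cross-checked against it in the tests.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, at
sizes chosen to exercise every stage in seconds.

**Single-cell cohort** (600 cells × 2,000 genes on two equal synthetic
chromosomes): 11 samples — two fetal, two normal, two adjacent, three HCC,
one HB, one ICC — each with epithelial and endothelial cells. Counts are
gamma-Poisson (negative binomial, shape 2) around lognormal gene means
(log-mean log 0.3, log-SD 1.2) with lognormal size factors (SD 0.25) and
5% independent extra dropout. A 150-gene program at log2 fold change 2 is
planted in fetal epithelium and in a per-sample fraction of tumor
epithelium (0.60–0.70 for HCC/HB, 0 for ICC by default; a uniform 30% in
the recovery tests). A 150-gene adult-hepatocyte program (×4) marks
differentiated epithelium and is absent from fetal/fetal-like cells; a
200-gene endothelial marker program (×4) separates cell types. Program
genes are scattered genome-wide with a fixed layout permutation — 
contiguous up-only programs would be indistinguishable from CNV gains
after window smoothing. 75% of tumor epithelial cells (a superset of the
fetal-like ones) are malignant and carry three CNV segments (×2.0 and ×0.5
on chr1, ×1.5 on chr2; 120–150 genes each). Fetal and fetal-like cells get
a ×2 library-size boost so they detect more genes, the premise of the
differentiation-potential surrogate.

The per-sample fetal-like heterogeneity is deliberate: with a uniform low
fraction, tumor pseudobulks sit closer to normal liver than to fetal
liver, and no fetal + tumor module exists to find — only program-rich
tumors co-cluster with fetal tissue, which is also the observed biology.

**Cell-line panel**: 50 lines (15 liver, 12 lung, 12 breast, 11 colon),
500 genes. Latent line scores are standard normal with liver shifted +1.
Fifty signature genes and 3 driver genes track the score in log2(TPM + 1)
space (driver noise SD 0.3); drivers have gene effect ~N(−1.0, 0.1) in
above-median-score lines and ~N(0, 0.1) elsewhere (−1 is where common
essentials calibrate on the gene-effect scale), non-drivers ~N(0, 0.15).

**Bulk cohort**: two sources of 360 and 98 samples (mirroring the two
survival cohorts the method is used on), latent per-sample scores standard
normal with a source shift, 150 signature genes = shift + score + N(0, 0.5),
ordinal grade/stage/fibrosis and binary HBV tied to the score through a
binomial/logistic link. Survival is exponential with log-hazard
0.7 × score around a median of 50 months, with exponential censoring
(mean 120 months) and administrative censoring at 120 months.

**What passing tests do and do not show.** The generators are pure
functions of (config, seed) and every planted effect is checked by a
self-check test before the recovery tests use it. They do not model
ambient RNA, doublets, batch chemistry, overlapping programs, subclonal
CNV structure, or non-proportional hazards; recovery on this data
demonstrates the pipeline's correctness and calibration, not its power on
any particular real cohort.

## Numerical choices and degenerate inputs

Percentiles use linear interpolation. Zero-variance pseudobulks get
correlation 0 (flagged); zero-variance genes are excluded from line and
bulk scoring with a warning. Undefined rank-sum p-values (constant genes)
are treated as 1. Permutation p-values use the (1 + exceedances)/(B + 1)
estimator, which is a valid p-value and uniform under the null (verified
empirically). `smooth_k ≥ n_cells` is clamped with a warning; chromosomes
shorter than the CNV window fall back to a full-chromosome window with a
warning; clusters of size 1 are tested with a degeneracy warning. The
acceptance script reduces the problem sizes of the calibration loops
(80-sample null cohorts, 499 permutations, 100 replicates) — sizes at
which the checked properties are already stable.

## Known limitations

The differentiation-potential surrogate is not a full potency method; the
module-selection rule assumes fetal pseudobulks exist (it errors
otherwise, by design); CNV inference has no HMM state calling or subclone
trees; the cohort stage fits no multivariable survival model — the
published analysis this package operationalizes reports KM/log-rank and
covariate-adjusted linear associations, and the package keeps that scope.
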