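# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `prepostx`.

## Paired differential expression

**Model.** Counts for gene g in sample j follow a negative binomial with
mean `μ_gj` and dispersion `α_g` (`var = μ + α μ²`). The design is
`log μ_gj = log s_j + a_{g,subject(j)} + β_g · 1[timepoint(j) = TP2]`: a
per-subject baseline plus a single timepoint coefficient. Because every
subject contributes one TP1 and one TP2 sample, the subject indicators
absorb all between-subject variation and `β_g / ln 2` is the paired
(within-subject) log2 fold change. One cohort is analyzed at a time; mixing
cohorts in one fit is rejected.

**Normalization.** Median-of-ratios size factors: per gene, the geometric
mean across samples is the reference; a sample's factor is the median ratio
of its counts to the reference over genes with all-positive rows. Only
factor ratios are identifiable (scaling one sample's column by c multiplies
its factor by c relative to the others). Datasets in which no gene is
positive everywhere raise an error pointing at the `pseudo_reference=True`
fallback, which uses positive counts only for the reference.

**Dispersion.** A method-of-moments estimate on normalized counts:
residual variance about the least-squares fit of the paired design with an
n/(n−p) df correction, minus the Poisson component `mean(1/s_j)·q̄`, divided
by `q̄²`, floored at 1e−8. Gene-wise estimates at paired-cohort sizes
(n ≈ 30, p ≈ 16) are noisy, so by default they are blended 50:50 on the log
scale with a fitted mean–dispersion trend `a0 + a1/q̄` (both coefficients
clamped non-negative). The blend can be disabled
(`DEConfig.shrink_dispersion_trend=False`), e.g. for studying the raw
estimator. This is deliberately simpler than a Cox–Reid adjusted-likelihood
scheme; its adequacy is established by simulation (type-I error, p-value
uniformity, power) rather than by numeric equality with any reference tool.

**Fitting and testing.** All genes share one design matrix, so the IRLS
iterations are batched across genes (einsum-built normal equations, batched
solves); maximum 100 iterations, convergence when the deviance changes by
less than 1e−8 relative; non-convergent genes are flagged, get NaN p-values
and are excluded from the BH adjustment, never silently dropped. The Wald
statistic `β̂/SE` is referred to a **t distribution with n − p residual df**
rather than the normal: with ~14 residual df the normal tail is measurably
anti-conservative (simulated type-I error 0.06–0.07 at nominal 0.05), while
the t reference calibrates to 0.04–0.05. Linear predictors are clipped to
±30 and means floored at 1e−10 to keep the iterations finite for all-zero
rows.

**Two-tier DEG reporting.** A DEG is a gene with raw p < 0.05; genes with
BH FDR < 0.05 are counted separately as FDR-significant. Both tiers are
reported because stimulus effects in blood are small and short paired
designs are underpowered for genome-wide FDR control; the nominal tier
tracks the broad response, the FDR tier the defensible individual calls.
Up/down ratios are rounded to two decimals, cohort DEG-count ratios to one.

## Transcriptome displacement

PCA is computed per cohort on gene-centered log2(normalized count + 1)
values; by default each subject's mean profile is removed first
(`subject_center=True`), matching the paired framing, so the leading
components capture within-subject change. Components are deterministically
sign-oriented (largest-magnitude loading positive). TD for cohort c and
component j is the mean over subjects of |proj_TP1 − proj_TP2| on j; the
report also carries the mean TD across requested components and the
per-subject displacements. TD is invariant to component sign flips and
subject order and scales linearly with the data. Top-loading genes use a
*range* cut: loading within the top or bottom `fraction` (default 0.10) of
the loading range, not of the loading quantiles.

## Pathway activity

The per-sample gene-set score follows the variance-analysis recipe: (1) a
per-gene expression-level statistic from the gene's distribution across
samples — a Gaussian-kernel CDF estimate with bandwidth sd/4 by default, or
the plain ECDF (`kernel="ecdf"`), which is exactly rank-based and hence
invariant under any strictly monotone per-gene transform (the Gaussian
kernel is invariant under affine transforms only); (2) within each sample,
genes ranked by that statistic, weighted by the symmetric rank statistic
|N/2 − rank|^τ (τ = 1); (3) a weighted KS random walk down the ranked list;
the score is the maximum positive plus the maximum negative deviation, which
lies in [−1, 1]. Rank ties break deterministically by gene order. Sets with
fewer than `min_set_size` (default 5) measured genes are dropped with a log
entry. For large cohorts the pipeline uses the ECDF statistic: at hundreds
of samples kernel smoothing is immaterial and the quadratic-in-samples
kernel evaluation is not.

Paired pathway differential activity is a paired t-test on per-subject TP2 −
TP1 score differences (the mean difference is reported in the `log2fc`
column for schema uniformity). The cohort pathway-activation contrast
summarizes a set by PA = mean gene-level log2FC per cohort and tests the
between-cohort difference with a Welch t on the two per-gene log2FC vectors.
This replaces a full convolution-of-t-distributions treatment: the
downstream use is ranking and a hard filter, and both the PA point estimate
and the p-value ordering are preserved under the simplification — an
acknowledged deviation, not an equivalence. The activity filter is strict
exactly as specified: |PA_a| + |PA_b| > 0.05 **and** p < 0.05; boundary
records are excluded.

## Co-expression modules

Input is subject-centered log expression restricted to the top 75 % most
variable genes (ties broken lexicographically by gene id). The signed
adjacency is `((1 + cor)/2)^β`; β is the smallest power in 1..20 whose
connectivity histogram fits a power law with R² ≥ 0.8 and negative slope,
else the argmax with a warning. Note that *independent* genes do not
reliably exercise the warning path: at desk-scale sample sizes the tail of
chance correlations raised to a soft power itself looks approximately
scale-free; a degenerate equicorrelated structure does fail the fit.

Modules come from average-linkage clustering of 1 − TOM with a static cut
at 0.99 of the merge-height range. The static cut is deliberately generous,
so each retained cluster is pruned: members whose correlation with the
cluster eigengene falls below `kme_min` (default 0.5) are returned to
"unassigned". At n ≈ 32 samples a chance correlation exceeds 0.3 about 10 %
of the time, so the common 0.3 membership threshold admits noise genes;
0.5 keeps the chance admission rate below 1 % while genuine members of a
coherent module sit far above it. Clusters below `min_module_size`
(default 30) are unassigned. Modules are named by their hub gene (highest
intramodular connectivity).

Eigengenes are the first principal component of the module's standardized
expression, unit-variance, oriented so the mean gene–eigengene correlation
is non-negative. Module–trait statistics are Pearson correlations of
eigengenes with the TP2 indicator (the stimulus encoding), p from the t
approximation, BH across modules. MM is the gene × eigengene correlation
matrix; the MM–trait link correlates, within each module, member MM with
member gene–trait correlation (undefined below 3 members). Module
functional enrichment is a hypergeometric test against the catalog with BH
across all module × set tests.

## Case–control cohort

Harmonization is per-cohort: optional quantile normalization of sample
columns to the mean sorted profile, then per-gene z-scoring within the
cohort, then column concatenation over the shared gene set. Z-scoring is
idempotent and removes cohort location/scale, which is sufficient here
because the concordance analysis consumes only log2FC signs and ranks.
Outliers are flagged before harmonization: samples whose (PC1, PC2)
centroid distance exceeds the mean distance by more than 4 SD of the
distances, iterated once; with ≤ 3 samples nothing is flagged. The centered
form (d − mean) is used because the uncentered rule "d > 4·sd(d)" flags ~3 %
of homogeneous Gaussian samples (Rayleigh tail) — far from the intended
rare-event behavior. The group test is a per-gene Welch t; the group mean
difference is the log2FC since values are log-scale. A moderated-t is not
used: at hundreds of samples per group moderation is immaterial.

## Concordance

Two DE tables are inner-joined on feature id; the FDR filter applies to the
disease contrast by default (a `which="music"|"either"` flag exists for
sensitivity analysis). Sign classification: concordant if the two log2FC
share sign, discordant if opposite, "null" if either is exactly zero — null
features are excluded from percentages rather than arbitrarily signed.
Spearman ρ is reported overall and within each sign class (NaN below 3
members). The same code path serves gene- and pathway-level tables.

## Synthetic-data generator

The generator emulates (i) a paired blood RNA-seq study — 16 patients and
14 controls by default, each with TP1/TP2 samples; (ii) a large Gaussian
log-intensity case–control cohort (307 cases / 482 controls by default,
with a second 480-case cohort available from the same truth table); and
(iii) a gene-set catalog of 200 sets, 30 % of which are loaded with
responsive genes of coherent sign.

Choices and their reasons:

- **NB with dispersion trend** `α(μ) = 0.05 + 2/μ`: the standard decreasing
  mean–dispersion relationship of bulk RNA-seq. Baseline abundances are
  lognormal (ln-mean 5, ln-SD 1.5); per-sample depth factors are lognormal
  (ln-SD 0.2) so normalization is actually exercised.
- **Subject effects on the log scale** (SD 0.3 log2), shared by a subject's
  two samples — this is what makes the paired design informative.
- **Fixed-magnitude, random-sign music effects**: responsive genes (20 %)
  get β = ±0.15 log2 in controls and 2.3× that in patients. The SD of the
  effect distribution is exactly `sigma_beta`; fixing the magnitude rather
  than drawing Gaussian effects keeps per-cohort detection power analytically
  transparent — with Gaussian effects the many near-zero draws cap the
  achievable DEG-count asymmetry between cohorts well below the designed
  amplitude ratio, whatever the depth. The 0.15 log2 scale matches the small
  median DEG fold changes such stimulus studies report.
- **Disease coupling** `δ_cc = −κ·β_patient + Normal(0, σ_noise)` for
  responsive genes and δ_cc = 0 otherwise, giving the closed-form design
  correlation `−κσβ/√(κ²σβ² + σ²_noise)` among coupled genes; the defaults
  (κ = 1, σ_noise = 0.304 against σβ_patient = 0.345) set it to −0.75.
  Restricting the noise to responsive genes keeps the disease-significant
  set from being dominated by genes with no music response, which would
  dilute the designed correlation with pure noise.

What the generator does **not** emulate: microarray probe-level structure,
batch effects and cohort heterogeneity beyond a label, gene–gene correlation
outside the planted co-expression blocks used in network tests, library
composition bias, and age/sex covariates. Passing tests therefore show that
the estimators recover the truth under a clean version of the designs, not
that any real dataset satisfies the models.

## Problem sizes in tests and the acceptance script

Simulation-based checks run at 2 000 genes with the default subject counts
(or 15 where a design calls for it), 10–20 replicates for recovery means,
and 3 replicates for calibration means; planted-network checks use
100 + 100 block genes plus 100 noise genes over 32 samples. These sizes give
Monte-Carlo error comfortably inside the asserted bands while keeping the
whole suite fast on a single CPU.

## Known limitations

- The NB fit has no outlier handling, no independent filtering and no LFC
  shrinkage; extreme-count artifacts will pass through.
- The dispersion trend is a two-parameter least-squares fit, not robust
  regression; datasets with pathological mean–dispersion shapes should
  disable shrinkage.
- The pathway p-value treats genes within a set as independent (no
  variance-inflation correction for gene–gene correlation).
- The static tree cut plus kME pruning recovers well-separated modules; it
  is not a substitute for dynamic tree cutting on messy empirical networks.
- Quantile normalization assumes comparable global distributions within a
  cohort; it is applied per cohort, never across cohorts.
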