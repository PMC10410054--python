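# Methods

## Model and pipeline

`regclock` builds linear epigenetic age predictors on regional mean
methylation from Bismark coverage files. The pipeline is: per-sample
coverage filtering (≥ 5 reads per CpG) → region discovery (fixed windows
or 1-D DBSCAN over observed CpG positions) → regional quantitation →
LASSO training → zero-imputed prediction → evaluation.

**Coordinates.** Cov files and the canonical region id `chrom:start:end`
are 1-based inclusive; every internal interval is 0-based half-open, with
conversion confined to the I/O boundary. A CpG at 1-based position *p*
belongs to region \[s, e) iff s ≤ p−1 < e. The percentage column of a cov
file is never used; β is always recomputed from the read counts so
upstream rounding cannot propagate.

**Regional methylation** is the unweighted mean of per-site β over covered
member CpGs. The pooled alternative Σm/Σ(m+u) was rejected deliberately: a
single deeply covered site would dominate the region and re-import the
coverage sensitivity the regional design exists to remove. A region with
no covered CpG in a sample is explicitly missing (NaN), never zero.
Missingness is resolved differently at the two stages on purpose: training
drops any region column containing NaN; prediction imputes missing regions
as zero. This mirrors how published clocks are applied to external data,
and it is exactly the mechanism the robustness module measures.

**DBSCAN.** Classic DBSCAN specialises cleanly to one dimension: with
positions sorted, a point is core when ≥ minPts points (itself included)
lie within eps bp, and clusters of core points are maximal runs of cores
with consecutive gaps ≤ eps. Border points attach to the nearest core;
exact ties go to the lower-coordinate cluster — classic DBSCAN leaves this
order-dependent, and a deterministic rule makes region sets reproducible.
Noise points are discarded; every emitted region therefore contains ≥
minPts CpGs. Defaults: minPts = 5 CpGs. The implementation is
O(n log n) on sorted arrays; the test suite checks it against an O(n²)
brute-force reference on random instances.

**Windows** are anchored at coordinate 0 of each chromosome with step =
size; the truncated final window is kept so no CpG is silently lost.

**LASSO.** Age in months is regressed on regional β with L1 penalty
(scikit-learn). Features are standardised internally; coefficients are
back-transformed so serialised clocks apply directly to raw β. The penalty
is chosen by K-fold cross-validation minimising mean CV MSE (the
`lambda.min` convention; a one-standard-error rule is available via
`lambda_rule="1se"`). The conventional 100 folds degrade to leave-one-out
when fewer than 100 training samples are present. Fold assignment and the
coordinate-descent path are seeded, making training bit-reproducible.
A penalty large enough to zero every coefficient yields an intercept-only
model (the training-mean predictor); such a model is valid in memory but
refused by the serialiser, which requires at least one region term.

**Splitting.** The holdout receives ⌊n·(1−train_fraction)⌋ samples
(default fraction 0.9) from a seeded uniform permutation. Stratified
partitioners can produce slightly different counts on the same inputs;
the plain rule was chosen for transparency and determinism.

**Evaluation.** R² is taken from the least-squares fit of predicted on
chronological age; adjusted R² = 1 − (1−R²)(N−1)/(N−k−1) with k = 1, since
the evaluation regresses one predictor (predicted age). MAE is the
*median* absolute error in months. Group comparisons of age acceleration
(predicted − chronological) use the two-sided Wilcoxon rank-sum test
(`scipy.stats.mannwhitneyu`, exact for small tie-free samples, otherwise
the tie-corrected normal approximation), reporting the treated group's
median residual as the median error.

## Robustness analysis

Relative coverage of a feature is reads_feature / reads_sample × 10⁶,
comparable across sequencing depths. Downsampling draws a target number of
reads without replacement from the pooled (site, methylation-state) counts
— a multivariate hypergeometric draw — which conserves the target total
exactly, never exceeds original per-site counts, and preserves the
marginal coverage distribution without re-alignment. The ≥ 5-read filter
is re-applied after downsampling by default (configurable), so each depth
step mirrors the full pipeline. The zero-feature count of a clock on a
sample is the number of terms with measured β = 0 or imputed zero; when it
equals the term count the sample is "saturated" and predicts the
intercept. `downsample_curve` tabulates adjusted R², MAE, mean zero-feature
count and saturated-sample count per (depth, clock).

## Annotation

GC content is 100·(G+C)/length with ambiguous bases counted in the length
only. Methylation-age gradients are per-region OLS slopes (β/month) with
pairwise NaN exclusion, requiring ≥ 3 usable samples and ≥ 2 distinct
ages. Hyper-/hypomethylating groups are defined by coefficient sign; a
zero coefficient is rejected as unsignable. ChromHMM overlap uses clipped
interval intersection — algebraically equivalent to start/end flank
bookkeeping — with one literal exception kept as a post-filter: state
intervals bordering a region by exactly 1 bp are discarded. "Repressed" is
merged into "Heterochromatin" before proportions. Group proportions divide
by the group's total region bp; the genomic background proportion divides
by the total state bp overlapping the background (500-bp tiles retaining
≥ 1 covered CpG). States absent on either side of the ratio are reported
with log2 fold change 0 rather than ±∞.

## Synthetic cohort

The generator emulates the statistical structure the method assumes:

| parameter | default | meaning |
|---|---|---|
| n_samples | 60 | cohort size |
| age_range_months | 3–30 | uniform chronological ages |
| n_cpg_clusters / cpgs_per_cluster | 50 / 20 | CpG clusters (MspI-fragment-like) |
| intra/inter spacing | 30 bp / 2000 bp | within-cluster gap / between-cluster gap |
| n_clock_regions | 5 | clusters drifting with age |
| slope_range | 0.01–0.02 β/month | drift magnitude, signs split half/half |
| depth_mean / dispersion | 30 / 5 | negative-binomial reads per site |
| beta_concentration | 300 | Beta jitter of site β around the region mean |

Informative regions follow μ(age) = clip(baseline + slope·age, 0, 1) with
baselines drawn so μ stays inside (0.05, 0.95) over the age range;
background sites hold an age-independent level in (0.25, 0.75). Site β is
Beta-distributed around μ (support in \[0,1\] by construction), read depth
is negative binomial (RRBS coverage is overdispersed; Poisson would
understate dropout), and methylated counts are Binomial(reads, β). A
coverage-shift operation retains each site independently with probability
r, emulating an external study that shares biology but captures different
sites; an age-offset option shifts the methylation-generating age relative
to the recorded age, emulating interventions that decelerate the
methylome.

What the generator does *not* emulate: strand structure and CpG dyads,
bisulfite conversion error, SNP interference, correlated (haplotype-like)
dropout, tissue heterogeneity, and non-linear age trajectories. Passing
tests therefore demonstrate the machinery and its comparative behaviour
(regional vs single-CpG under coverage loss), not clock accuracy on real
RRBS cohorts.

## Problem sizes

Tests and the acceptance script run the default 60-sample cohort
(~1,000 CpGs, 50 candidate regions), a 10-fold CV for the single-CpG
comparison clock (thousands of features) and depth grids down to a few
hundred reads. These sizes give stable estimates of every reported
quantity while keeping a full run in seconds on one CPU.

## Known limitations

* Single-chromosome-arm geometry: simulated clusters are evenly pitched,
  so DBSCAN recovery at eps = half the inter-cluster gap is essentially
  exact; real CpG landscapes have broader spacing distributions.
* The per-sample ≥ 5-read filter is applied per sample; a stricter
  all-samples variant is available but not the default, and the choice
  affects which regions survive training-time NaN-dropping.
* Zero-imputation is the only built-in missing-data policy at prediction
  time (a custom imputer can be passed by substituting matrix values
  before `predict_age`).
* Region size conventions: end − start (half-open) internally; published
  1-based inclusive ids add one. Both conventions are parsed, but mean
  region sizes computed under the two differ by 1 bp.
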