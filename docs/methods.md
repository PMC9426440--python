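# Methods

`mpcms1` screens microbiome (or single-species) samples from MS1-only
feature intensities: no MS/MS identification is needed to decide which
treatments or diagnoses perturb the community. The pipeline reduces an
aligned feature-intensity matrix X (features × samples) to a small set of
robust feature modules, summarizes each module across samples, and
clusters the experimental conditions on those summaries. This note
documents the model, the numerical choices, and what the synthetic tests
do and do not establish.

## Data model and preprocessing

X holds non-negative intensities of aligned MS1 features; absent
measurements (a feature unmatched in a sample's map) are missing values.
Intensities are assumed log-normal-ish with a shared per-sample scaling
factor (loading/ionization efficiency) and missingness concentrated at
low intensities, because weak features drop out of consensus maps first.

Preprocessing runs in a fixed order:

1. **Quartile missingness.** Observed intensities are pooled and split
   into quartiles (linear-interpolation quantiles; no convention is
   universal, this is the common default). Entries below a threshold —
   the first quartile by default; the second or third under the
   `high+medium` / `high` censoring schemes — count as *missing for
   filtering only*.
2. **Group prevalence filter.** A feature is kept only if it is
   quantified (non-missing under rule 1) in at least `min_frac` (default
   0.5) of the samples of *every* condition, control included. Surviving
   features keep all observed values, including sub-threshold ones.
3. **kNN imputation** of genuinely absent entries only (sub-threshold
   observed values are never overwritten). Neighbors are features, with
   Euclidean distance over mutually observed samples rescaled to the full
   sample count; an absent entry takes the mean of the k = 10 nearest
   features observed at that sample. Features missing more than
   `rowmax` = 0.5 of their samples fall back to their observed mean; a
   sample missing more than `colmax` = 0.95 of its features is an error.
4. **Median-of-ratios normalization.** Per-feature reference = geometric
   mean across samples; a sample's size factor is the median of its
   value/reference ratios; values are divided by the size factor. The
   median is taken on the ratio scale (this matches the brute-force
   definition exactly; taking it on the log scale differs only when the
   feature count is even).
5. **log2 transform.**

## Robust consensus ICA

The component count n is the smallest number of principal components of
the feature-centered X explaining 99% of variance (capped at
min(features, samples−1)). ICA is then run `n_runs` = 100 times from
different seeds. Each run whitens against the feature-centered principal
subspace explicitly, so every run's sources span exactly the top-n PCA
directions and S·A reconstructs the centered data to within the PCA
truncation error; FastICA (logcosh contrast, tolerance 1e-6, at most
1000 iterations per run) supplies only the rotation. Runs that do not
converge are excluded from the consensus and logged; if fewer than two
runs converge, all runs are used with a warning rather than failing the
screen.

Pooled components from all runs are grouped by single-linkage clustering
at distance 1 − |r| ≤ 0.1 between loading vectors. Groups containing
components from at least half the runs survive; members are sign-aligned
to the member most correlated with the rest of its group and averaged
into a unit-norm centroid. Activities A are recovered by least squares
against the centered data, and components are ordered by decreasing
activity variance so output order is deterministic. The 0.1 linkage
threshold and 50% support are exposed as configuration; they are the
package's own defaults for the consensus step, chosen so that sign flips
and small rotations collapse while unstable components drop out.

## Feature modules (k-medoids)

Rows of S (one loading vector per feature) are clustered under
correlation distance d = 1 − r. The solver is k-medoids++ seeding,
Voronoi alternation (assign to nearest medoid, re-center each module on
the point minimizing within-module total distance) until stable, then
best-improvement swaps with FastPAM1 bookkeeping until no swap lowers the
cost. The tests verify that this matches a plain-loop alternation +
exhaustive-swap implementation exactly on small instances. k is chosen
over 10..50 (configurable) by maximum mean silhouette on the same
correlation distance; ties go to the smallest k, and a singleton module
contributes silhouette 0.

## Eigenfeatures and condition clustering

Each module's standardized (feature-wise centered, unit-variance)
sub-matrix is decomposed by SVD; the eigenfeature is the first right
singular vector over samples, sign-anchored to correlate non-negatively
with the module's mean standardized profile. Explained variance is the
first squared singular value over the total. Eigenfeatures are
correlated (Pearson) with one-hot condition indicators; an ordinal dose
encoding is deliberately out of scope, so the module × condition profile
R makes no assumption about condition ordering.

Conditions are clustered on d(g₁,g₂) = 1 − r between the columns of R,
with average linkage (merge height = mean inter-group pairwise
distance). The flat cut maximizes mean silhouette over k = 2..(n−1).

**Bootstrap support.** Module rows of R are resampled with replacement at
scales 0.5..1.4 (step 0.1) of the module count, 1000 resamples per
scale; each resample's tree is rebuilt and clade recovery counted. BP is
the plain proportion at scale 1. AU comes from the multiscale fit:
z(r) = Φ⁻¹(1 − BP(r)) regressed on {√r, 1/√r} by weighted least squares
(binomial-variance weights on the probit scale), AU = 1 − Φ(v − c).
Scales with BP exactly 0 or 1 carry no information for the fit and are
dropped; a node degenerate at every scale is clamped to AU 0 or 1, and a
singular fit leaves AU unavailable (NaN, logged). Resampling module rows
(rather than raw features) treats the modules as the sampling units that
generated the condition profile; this is a modeling choice, flagged in
the configuration.

## Comparing dendrograms

Two condition trees over the same leaves are compared by Pearson
correlation of their cophenetic distances (pairs aligned by label). A
self-comparison short-circuits to exactly 1. Significance comes from
uniformly shuffling the leaf labels of the second tree: p =
(#{|r_perm| ≥ |r_obs|} + 1)/(n_perm + 1), two-sided on |r| and add-one
corrected so p is never exactly zero. If either tree has constant
cophenetic distances every permutation reproduces the observed value and
p = 1.

## Marker selection

For a binary outcome the module with maximum |R| against the outcome
supplies candidate features. An L1 logistic path (100 penalties,
log-spaced over two decades below the analytic lambda_max) is fitted by
IRLS coordinate descent with warm starts; coefficients at lambda_max are
exactly zero by the soft-threshold rule. Leave-one-out cross-validated
binomial deviance selects lambda.1se (largest penalty within one
standard error of the minimum); the model is kept only if more than one
feature has a nonzero coefficient. Discrimination is the leave-one-out
AUC: each sample is scored by the covariate contribution of a model
refitted without it. The fold intercept is excluded from the score
because it tracks the fold's base rate, which moves *against* the
left-out label and would otherwise rank samples by fold composition
rather than signal; an intercept-only final model reports AUC 0.5, the
exact value for a constant classifier. Features are standardized
internally and coefficients reported on the log2 scale.

## Synthetic screens

The generator emulates: log-normal baselines (log2 mean 23 ≈ 8×10⁶,
spread 2), additive module × condition log2 shifts shared within planted
condition groups, module-level latent replicate variation (sd 0.5),
feature noise (sd 0.3), log-normal per-sample scale factors (sd 0.2),
and missing-not-at-random dropout (probability 0.3 below the 25%
intensity quantile). The default layout is a drug-screen-like design:
16 conditions × 3 replicates, 2000 features, 12 modules of 120 features,
and three planted condition groups (7 control-like, 4 strong-effect,
5 intermediate).

What the generator does **not** emulate: retention-time structure,
charge states and isotope envelopes, correlated (batch-structured)
missingness, heavy-tailed contamination, or disagreement between
technical and biological replicates. Passing tests therefore show the
pipeline recovers the structure its own data model describes; they say
nothing about feature detection or alignment quality upstream.

## Problem sizes and numerical choices

Simulation-based checks use deliberately compact problem sizes: ICA
recovery at 300 features × 40 samples with 100 runs; module-count
selection at 300 features over k = 10..50; the end-to-end recovery at the
full 2000 × 48 screen with 25 ICA restarts per run (the consensus is
already stable there because the planted sources are strong; the 100-run
default remains for real screens); bootstrap support at 1000 resamples;
the marker null study at n = 40 over 50 seeds. Degenerate inputs fail
loudly: constant matrices, single conditions, all-missing features,
non-positive values where logs are taken. Agglomeration ties follow the
deterministic order of the underlying linkage implementation; k-medoids
and ICA tie-breaking is fixed by seeding, so a master seed makes entire
runs byte-reproducible.

## Known limitations

- The AU fit is asymptotic in the bootstrap count; at 1000 resamples AU
  for weakly supported nodes carries appreciable Monte Carlo error.
- One-hot condition encoding discards dose ordering; a monotone dose
  response spreads across several indicator correlations.
- LOOCV AUC on small n is a high-variance estimate and, for models
  selected by the 1-SE rule, conservative.
- The imputation is O(features² × samples) per feature with missing
  entries; very large screens may want the rowmax fallback raised.
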