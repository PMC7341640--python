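# Methods

## Model and procedure

The pipeline stratifies bulk-expression cohorts into prognostic subtypes
using a fixed gene signature describing two cell-motility programs (EMT and
MAT).  Its stages, and the assumptions each makes:

**Signature derivation.**  Component lists come from perturbation
experiments reported as treated-vs-control expression ratios on the linear
scale.  A gene qualifies in an experiment when its ratio is ≥ *f* or
≤ 1/*f* (inclusive on both sides, matching "at least *f*-fold" semantics);
it enters the list when it qualifies in ≥ *k* experiments, pooling up- and
down-calls.  Pooled counting means a gene up in one experiment and down in
another counts twice and is labelled `mixed`; the alternative (separate
counting per direction) would only shrink lists.  Combining two lists is a
set union; genes present in both are labelled `both`, and a direction
conflict between lists also yields `mixed`.  Defaults *f* = 1.5, *k* = 2.

**Normalization.**  Cohort matrices are log2 transformed and per-gene
Z-scored across samples (population standard deviation, so the contract
"mean 0, sd 1" is exact rather than n/(n−1)-scaled; any constant row
factor cancels in the rank-correlation steps anyway).  Z-scoring is per
gene within a dataset — the only axis that makes cross-gene structure
comparable — and is applied to the full matrix before subsetting to the
signature (configurable).  Zero-variance rows are dropped with a warning.
When multiple probes map to one gene, the maximum-variance probe is kept.

**Subtype discovery.**  Samples are clustered by Ward's
variance-minimization linkage on Euclidean distances of the z-scored
signature matrix (scipy's implementation; deterministic given input
order).  The three distance measures — cosine, Euclidean, correlation
(1 − r) — enter only the silhouette evaluation used to pick the number of
clusters: each candidate K cut is scored by the mean over samples of
s = (b − a)/max(a, b), singletons contributing 0, and the K maximizing the
mean of the three average silhouettes wins; ties go to the smaller K.
Ward's objective is Euclidean, so feeding it non-Euclidean distances would
not be the same algorithm — the metrics belong to model selection, not to
the linkage.

**Cluster naming.**  The subtype numbering EMAT1…EMATK is a convention:
clusters are ordered by decreasing Kaplan–Meier survival probability at a
horizon (default 120 months, i.e. the 10-year analysis window), ties
broken toward the larger cluster.  Naming is pure relabelling and changes
no statistic.  The horizon must lie within observed follow-up; callers
with shorter follow-up pass `min(120, max_time)`.

**Classification.**  The single-sample predictor computes the Spearman
rank correlation (average ranks on ties) between a sample profile and each
per-cluster mean-expression centroid over the shared genes, assigning the
argmax; exact ties go to the lowest class index with a warning.  Rank
correlation makes the call invariant to any strictly monotone distortion
of the test cohort's intensity scale, which is what justifies
cross-platform transfer.  A minimum gene coverage of 50% of the training
genes (and ≥ 3 genes) is required; below it the classifier refuses rather
than guess.  The 5-NN variant votes over the most-correlated training
samples, resolving vote ties by summed correlation.

**Survival statistics.**  Kaplan–Meier, log-rank and Cox models are
delegated to lifelines.  Cox fits use the Efron approximation for tied
event times (robust for month-resolution data), listwise-delete missing
covariates, and warn below 10 complete rows per covariate.  Multi-level
clinical factors enter as ordinal codes — tumor size (<2 cm = 1, 2–5 = 2,
>5 = 3), grade (1–3), receptor profile (ER+HER2− = 1 … ER−HER2− = 4),
PAM50 (normal-like = 0 … basal-like = 4), EMAT (1–K) — so each factor
contributes a single trend hazard ratio rather than K−1 dummies.
Harrell's C uses the Cox linear predictor as the risk score (higher risk =
earlier event); tied scores contribute 0.5.  10-year analyses use
administrative censoring at 120 months via `truncate_follow_up`.

**CV benchmark.**  Each repeat splits samples half/half at random (odd n:
extra sample to training).  The training half is re-clustered into K = 4
groups, renamed by the outcome convention using training survival only, a
centroid classifier is fitted and labels the test half; each feature set's
Cox model is trained on the training half and its linear predictor scored
by C-index on the test half.  Summaries: PIF (percent of repeats where the
candidate strictly beats the baseline — ties count against the candidate)
and a one-sided Wilcoxon signed-rank p on the paired C-indices.  The
signed-rank p is exact for ≤ 20 nonzero differences (subset-sum dynamic
program over all 2^n sign assignments, average ranks on tied magnitudes,
zeros dropped) and a tie-corrected normal approximation with 0.5
continuity correction beyond.  Follow-up is not truncated inside CV by
default.  Splits leaving a training cluster empty are re-drawn from the
same stream; repeats with non-converging Cox fits are excluded and
counted.

**Characterization.**  Enrichment of a categorical annotation in a cluster
is the one-sided hypergeometric tail P(X ≥ k) with the universe restricted
to samples carrying the annotation; raw p-values are reported (heatmap
use), no multiplicity correction.  Stemness similarity is the per-sample
Spearman correlation to a reference profile, min-max scaled to [0, 1]
across the cohort; adjacent-subtype comparisons use one-sided Welch
t-tests.  Marker profiles and TF differential expression use unpaired
Welch t-tests (the safer default when variances differ) of cluster vs
rest, the TF analysis Bonferroni-corrected over all (TF × cluster) tests
actually run, with each cluster's top over/under-expressed significant TF
chosen by |mean difference|.  Concordance of two labelings is the pairwise
Jaccard matrix with a maximum-weight one-to-one matching
(linear-sum assignment).

## Synthetic data: what it emulates, what it does not

`generate_cohort` draws, per sample, a latent cluster from mixing
proportions defaulting to (0.194, 0.457, 0.260, 0.089) at n = 562 — the
scale of an LNN discovery cohort.  Signature-gene expression is the
cluster centroid plus Gaussian noise; non-signature genes are pure noise.
Per gene, centroid values are i.i.d. normal with variance
(separation · noise_sd)²/2, so the expected squared per-gene gap between
two centroids is (separation · noise_sd)² — "separation" is the per-gene
RMS between-centroid shift in within-cluster sd units.  The default
separation 1.0 gives clusters that overlap per gene yet are jointly
separable, like real subtypes; recovery tests use 6.0.  Survival times are
exponential (optionally Weibull-shaped) with rate = baseline hazard ×
cluster hazard ratio × exp(clinical effects); defaults: baseline
0.002/month, hazard ratios (1.0, 1.5, 1.6, 4.0) mirroring the two
similar middle subtypes, clinical effects zero (survival driven by the
clusters), censoring 0.6 via an independent exponential time whose rate is
solved analytically for the requested expected censoring fraction.
Categorical clinical covariates (size, grade, ER/PR/HER2, PAM50-like
labels) take a cluster-preferred level with probability 0.5 and otherwise
follow cohort-scale marginals, emulating the enrichment structure of real
subtypes.  The reference profile is a weighted combination of the latent
centroids, so expected sample-to-reference similarity is monotone in the
sample's cluster weight.

The generator does **not** emulate probe-level artifacts, batch effects
beyond monotone distortions, correlated gene modules within clusters,
non-proportional hazards, informative censoring, or missing clinical data.
Passing tests therefore demonstrate correctness of the machinery under the
model's assumptions, not performance on any real cohort.

## Numerical choices and degenerate inputs

- Fold-change thresholds inclusive; non-positive ratios rejected naming
  the offending gene/experiment.
- Z-scores: population sd; < 2 samples rejected; idempotent on z-scored
  input.
- Signature subsetting preserves signature gene order and refuses below
  the coverage floor, reporting the fraction found.
- Ward tie-breaks follow scipy's deterministic agglomeration; identical
  inputs give identical trees.
- Silhouette of singleton clusters is 0; a sample equidistant to its own
  and the nearest other cluster scores 0.
- Spearman ties: average ranks throughout.
- Centroid-correlation ties: lowest class index, warned.  KNN vote ties:
  larger summed correlation.
- Signed-rank: zeros dropped; all-zero differences an error; exact/normal
  cutover at n = 20.
- Hypergeometric p clipped to (0, 1]; k = 0 or K = N give p = 1.
- Min-max scaling of a constant similarity vector is undefined; all values
  set to 0.5 with a warning.
- Constant genes are excluded from per-gene Cox with a warning; clusters
  of size 1 are skipped in differential expression.

## Problem sizes used in validation

Validation runs use cohorts of 300–600 samples with 80–388 signature
genes, 10–20 generator seeds per property, 50 CV repeats, and n = 5000 for
parameter-recovery checks — sizes chosen so every property is measured
with comfortable Monte-Carlo margins while the whole suite stays quick on
a laptop.  The null behaviour of the CV benchmark is evaluated as an
average over independent null cohorts: on any single finite cohort the
repeated splits share the same realized (chance) expression–survival
association and the outcome-based per-split subtype orientation exploits
it, so single-cohort PIF is dataset-dominated (observed range ≈ 40–90
under the null) while its expectation sits near 50 with a small positive
optimism offset (~+0.007 mean paired C-index difference).  This optimism
is a property of applying the framework to one fixed cohort, worth
remembering when reading single-dataset PIF values.

## Known limitations

- Headline numbers from real cohorts (METABRIC, GSE11121, NKI295) require
  those datasets; this package validates the procedures on synthetic
  cohorts and ships only synthetic stand-in gene lists.
- PAM50 calling is out of scope; PAM50 labels are consumed as given.
- No consensus clustering or cluster-stability bootstrap; a single Ward
  tree per cohort.
- Cox models assume proportional hazards and omit time-varying covariates,
  stratification and competing risks; no proportionality diagnostics.
- The centroid classifier emits hard labels only, no posteriors.
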