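# emat

Metastasis-risk stratification of lymph node-negative (LNN) breast cancer
from an epithelial–mesenchymal–amoeboid transition (EMAT) gene signature.

Cancer cells metastasize through distinct motility programs: the
epithelial-to-mesenchymal transition (EMT) and, under microenvironmental or
xenobiotic stress, the mesenchymal-to-amoeboid transition (MAT).  Subtyping
tumors on either program alone has shown little prognostic value; this
package implements the combined approach — a 388-gene EMAT signature built
as the union of a 253-gene EMT list and a 138-gene MAT list — and everything
needed to use it for prognosis:

- **Signature derivation** from perturbation-experiment fold-change tables:
  a gene enters a component list when its treated/control ratio is ≥ *f*-fold
  up or down (default *f* = 1.5) in at least *k* experiments (default 2).
- **Subtype discovery**: Ward variance-minimization clustering of cohort
  samples over the z-scored signature genes, with the number of clusters
  chosen among {3, 4, 5} by the mean of average silhouette scores under
  cosine, Euclidean and correlation distances.  Clusters are named
  EMAT1…EMATK in decreasing Kaplan–Meier survival at 120 months, so EMAT1
  is always the best-prognosis subtype.
- **Single-sample classification**: a nearest-centroid predictor using
  Spearman rank correlation, so labels transfer across platforms and are
  invariant to monotone intensity distortions.  A Spearman k-NN variant is
  included as a secondary method.
- **Survival statistics**: Kaplan–Meier curves, log-rank tests, Cox
  proportional-hazards models (Efron ties) with ordinal covariate codings
  (tumor size 1–3, grade 1–3, IHC receptor profile 1–4, PAM50 0–4,
  EMAT 1–4), and Harrell's concordance index.
- **A repeated-split CV benchmark** comparing prognostic feature sets
  (clinical parameters alone, +receptor status, +PAM50, +EMAT) by paired
  test-half C-indices, summarized with the percentage of improved folds
  (PIF) and a one-sided Wilcoxon signed-rank test (exact for ≤ 20 pairs).
- **Cluster characterization**: hypergeometric enrichment of clinical
  categories, stem-cell-reference similarity gradients, CDH1/VIM/RHOA/JUP
  marker profiles, per-gene univariable Cox association, Bonferroni-corrected
  TF differential expression, and Jaccard concordance between labelings.
- **A synthetic cohort generator** producing expression with planted
  clusters, confounded clinical covariates and proportional-hazards
  survival, so the full pipeline is exercised and validated without any
  patient-data downloads.

The packaged EMT/MAT gene lists and TF list are synthetic stand-ins with
the published list sizes (253 / 138 / 1338, with 3 genes shared between
EMT and MAT so the union has 388 members); real analyses should substitute
the actual curated lists via `--signature`.

## Worked example

```python
from emat import (
    CohortSpec, generate_cohort, z_normalize, subset_to_signature,
    select_n_clusters, assign_cluster_names, logrank_test, cox_fit,
)

spec = CohortSpec(n_samples=400, seed=3, hazard_ratios=(1.0, 1.5, 2.0, 4.0))
cohort = generate_cohort(spec)

matrix, coverage = subset_to_signature(z_normalize(cohort.expr), cohort.signature)
report = select_n_clusters(matrix, candidates=(3, 4, 5))
print("chosen K:", report.chosen_K)

model = assign_cluster_names(report.models[report.chosen_K], cohort.surv, horizon=120)
print("log-rank p:", logrank_test(cohort.surv, model.named_labels).p_value)

covariates = cohort.covariates.assign(emat=model.ordinal_labels.astype(float))
fit = cox_fit(covariates[["emat"]], cohort.surv)
print(fit.summary.round(3))
```

Output:

```
chosen K: 4
log-rank p: 8.348384421444017e-07
            coef     hr  hr_lower  hr_upper    p
covariate
emat       0.433  1.542     1.279     1.859  0.0
```

Silhouette selection recovers the four planted subtypes, the log-rank test
confirms their survival curves separate, and the ordinal EMAT covariate
carries a hazard ratio of 1.54 per subtype step — each step toward EMAT4
multiplies the event hazard by about 1.5.

The same stages are available from the shell:

```bash
emat simulate --seed 3 --out cohort/
emat cluster --expr cohort/expression.tsv --scale log2 \
     --surv cohort/survival.csv --out clusters/
emat cv --expr cohort/expression.tsv --scale log2 \
     --clinical cohort/clinical.csv --surv cohort/survival.csv \
     --repeats 200 --seed 17 --out cv/
emat run-all --config pipeline.yaml
```

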