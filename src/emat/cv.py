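"""Repeated-split cross-validation comparison of prognostic feature sets.

In each repeat, samples are split in half at random.  The training half is
clustered into K groups over the signature genes; subtype names (EMAT1..K)
are fixed per split by the outcome-based naming convention so that the
ordinal subtype covariate is comparable across repeats.  A centroid
classifier fitted on the training half labels the test half.  For every
feature set a Cox model is trained on the training half, its linear
predictor scores the test half, and Harrell's C-index on the test half is
recorded.  Feature sets are compared with the percentage of improved
folds (PIF: percent of repeats in which the candidate's C-index strictly
exceeds the baseline's) and a one-sided Wilcoxon signed-rank test on the
paired C-index values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.exceptions import ConvergenceError
from scipy.stats import rankdata

from .classify import classify_matrix, fit_centroids
from .cluster import assign_cluster_names, ward_cluster
from .preprocess import ExpressionMatrix
from .survival import SurvivalTable, concordance_index, cox_fit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named set of Cox covariates; EMAT sets are re-derived per split."""

    name: str
    covariates: tuple[str, ...]
    includes_emat: bool = False


def default_feature_sets(clinical_columns) -> list[FeatureSetSpec]:
    """The four compared predictor classes: clinical parameters (CP) alone,
    CP + receptor (IHC) status, CP + PAM50 subtype, CP + EMAT subtype."""
    cp = tuple(
        c
        for c in ("age", "tumor_size", "grade", "chemo", "hormonal", "radiation")
        if c in clinical_columns
    )
    return [
        FeatureSetSpec("CP", cp),
        FeatureSetSpec("CP+IHC", cp + ("ihc",)),
        FeatureSetSpec("CP+PAM50", cp + ("pam50",)),
        FeatureSetSpec("CP+EMAT", cp, includes_emat=True),
    ]


@dataclass
class CVComparisonResult:
    """Per-repeat paired C-indices plus PIF / signed-rank summaries."""

    cindex: pd.DataFrame  # long format: repeat, feature_set, c_index
    summary: pd.DataFrame  # comparison, pif, p
    n_repeats: int
    seed: int
    n_excluded: int = 0
    test_labels: dict[int, pd.Series] = field(default_factory=dict, repr=False)

    def cindex_wide(self) -> pd.DataFrame:
        return self.cindex.pivot(index="repeat", columns="feature_set", values="c_index")


def pif(c_candidate, c_baseline) -> float:
    """Percentage of paired repeats where the candidate strictly wins."""
    a = np.asarray(c_candidate, dtype=float)
    b = np.asarray(c_baseline, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty C-index vectors")
    return float(100.0 * np.mean(a > b))


def wilcoxon_signed_rank_one_sided(diffs, exact_limit: int = 20) -> float:
    """One-sided Wilcoxon signed-rank p-value (alternative: diffs > 0).

    Zero differences are dropped (Wilcoxon convention).  For n <=
    ``exact_limit`` the p-value is exact, enumerating all 2^n sign
    assignments of the observed |rank| values (ties handled with average
    ranks); beyond that, a normal approximation with tie correction and a
    0.5 continuity correction is used.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    if n < 5:
        logger.warning("signed-rank test on only %d nonzero differences", n)
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_limit:
        # subset-sum distribution of W+ over all sign assignments; average
        # ranks are multiples of 0.5, so double them to get integer weights
        weights = np.round(2 * ranks).astype(int)
        total = weights.sum()
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for w in weights:
            counts[w:] += counts[:-w].copy()  # copy: slices overlap in-place
        target = int(round(2 * w_pos))
        p = counts[target:].sum() / 2.0**n
        return float(p)
    mean = n * (n + 1) / 4.0
    tie_sizes = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_sizes**3 - tie_sizes).sum() / 48.0
    z = (w_pos - mean - 0.5) / math.sqrt(var)
    return float(0.5 * math.erfc(z / math.sqrt(2)))


def run_cv_comparison(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    surv: SurvivalTable,
    feature_sets: list[FeatureSetSpec] | None = None,
    n_repeats: int = 200,
    K: int = 4,
    seed: int = 0,
    candidate: str = "CP+EMAT",
    keep_labels: bool = False,
    max_redraws: int = 20,
) -> CVComparisonResult:
    """Run the repeated half-split benchmark.

    ``expr`` is the z-scored signature matrix, ``clinical`` a numeric
    (encoded) covariate table and ``surv`` the survival table, all aligned
    on sample ids.  Repeats in which any Cox model fails to converge are
    excluded from the pairing (count reported); splits that leave a
    training cluster empty are re-drawn from the same random stream.
    """
    if feature_sets is None:
        feature_sets = default_feature_sets(clinical.columns)
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    samples = pd.Index(expr.sample_ids)
    if not samples.isin(clinical.index).all() or not samples.isin(surv.data.index).all():
        raise ValueError("expression, clinical and survival tables must share sample ids")
    clinical = clinical.loc[samples]
    surv = surv.subset(samples)
    rng = np.random.default_rng(seed)

    rows = []
    test_labels: dict[int, pd.Series] = {}
    n_excluded = 0
    for rep in range(n_repeats):
        result = None
        for _ in range(max_redraws):
            perm = rng.permutation(len(samples))
            n_train = (len(samples) + 1) // 2  # odd n: extra sample to training
            train_ids = samples[perm[:n_train]]
            test_ids = samples[perm[n_train:]]
            try:
                result = _one_repeat(
                    expr, clinical, surv, train_ids, test_ids, feature_sets, K
                )
                break
            except _EmptyClusterError:
                logger.warning("repeat %d: empty training cluster, re-drawing split", rep)
                continue
        if result is None:
            n_excluded += 1
            continue
        cvals, labels, converged = result
        if not converged:
            n_excluded += 1
            logger.warning("repeat %d excluded: Cox non-convergence", rep)
            continue
        for fs_name, c in cvals.items():
            rows.append({"repeat": rep, "feature_set": fs_name, "c_index": c})
        if keep_labels:
            test_labels[rep] = labels

    cindex = pd.DataFrame(rows, columns=["repeat", "feature_set", "c_index"])
    summary = summarize_comparisons(cindex, candidate=candidate)
    return CVComparisonResult(
        cindex=cindex,
        summary=summary,
        n_repeats=n_repeats,
        seed=seed,
        n_excluded=n_excluded,
        test_labels=test_labels,
    )


def summarize_comparisons(cindex: pd.DataFrame, candidate: str = "CP+EMAT") -> pd.DataFrame:
    """PIF and one-sided signed-rank p for the candidate against each baseline."""
    if cindex.empty:
        return pd.DataFrame(columns=["comparison", "pif", "p"])
    wide = cindex.pivot(index="repeat", columns="feature_set", values="c_index")
    rows = []
    for base in wide.columns:
        if base == candidate or candidate not in wide.columns:
            continue
        paired = wide[[candidate, base]].dropna()
        diffs = (paired[candidate] - paired[base]).to_numpy()
        try:
            p = wilcoxon_signed_rank_one_sided(diffs)
        except ValueError:
            p = 1.0
        rows.append(
            {
                "comparison": f"{candidate} vs {base}",
                "pif": pif(paired[candidate], paired[base]),
                "p": p,
            }
        )
    return pd.DataFrame(rows, columns=["comparison", "pif", "p"])


class _EmptyClusterError(RuntimeError):
    pass


def _one_repeat(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    surv: SurvivalTable,
    train_ids: pd.Index,
    test_ids: pd.Index,
    feature_sets: list[FeatureSetSpec],
    K: int,
):
    train_expr = ExpressionMatrix(expr.values[train_ids], scale=expr.scale)
    train_surv = surv.subset(train_ids)

    model = ward_cluster(train_expr, K)
    if model.labels.nunique() < K:
        raise _EmptyClusterError
    horizon = min(120.0, float(train_surv.data["time"].max()))
    model = assign_cluster_names(model, train_surv, horizon=horizon)

    clf = fit_centroids(train_expr, model.named_labels)
    test_expr = ExpressionMatrix(expr.values[test_ids], scale=expr.scale)
    test_named, _ = classify_matrix(test_expr, clf)

    emat_train = model.ordinal_labels.astype(float)
    emat_test = test_named.str.extract(r"EMAT(\d+)")[0].astype(float)

    cvals: dict[str, float] = {}
    converged = True
    for fs in feature_sets:
        X_train = clinical.loc[train_ids, list(fs.covariates)].copy()
        X_test = clinical.loc[test_ids, list(fs.covariates)].copy()
        if fs.includes_emat:
            X_train["emat"] = emat_train
            X_test["emat"] = emat_test
        try:
            fit = cox_fit(X_train, train_surv)
        except (ConvergenceError, ValueError, np.linalg.LinAlgError):
            converged = False
            break
        risk = fit.predict_risk(X_test.dropna())
        test_surv = surv.subset(risk.index)
        cvals[fs.name] = concordance_index(risk, test_surv)
    return cvals, test_named, converged
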