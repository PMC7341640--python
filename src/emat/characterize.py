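"""Cluster characterization: enrichment, stemness similarity, markers, TFs.

Covers the descriptive analyses run once subtypes exist: hypergeometric
over-representation of categorical annotations (receptor status, PAM50
labels, tumor size) in each cluster, per-sample similarity to a stem-cell
reference profile, motility-marker expression profiles (CDH1, VIM, RHOA,
JUP), per-gene univariable survival association, differential expression
of transcription factors with Bonferroni control, and Jaccard concordance
between alternative labelings of the same samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.exceptions import ConvergenceError
from scipy.optimize import linear_sum_assignment
from scipy.stats import hypergeom, ttest_ind

from .classify import _spearman_matrix
from .preprocess import ExpressionMatrix
from .signature import GeneSignature
from .survival import SurvivalTable, cox_fit

logger = logging.getLogger(__name__)

DEFAULT_MARKERS = ("CDH1", "VIM", "RHOA", "JUP")


@dataclass
class EnrichmentMatrix:
    """One-sided hypergeometric p-values, clusters x categories, with the
    (N, K, n, k) counts behind every cell."""

    pvalues: pd.DataFrame
    counts: dict[tuple[str, str], tuple[int, int, int, int]]

    def neg_log10(self) -> pd.DataFrame:
        return -np.log10(self.pvalues)


def enrichment_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Over-representation tail P(X >= k) under Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts N={N} K={K} n={n} k={k}")
    return float(min(hypergeom.sf(k - 1, N, K, n), 1.0))


def hypergeometric_enrichment(
    cluster_labels: pd.Series, category_labels: pd.Series
) -> EnrichmentMatrix:
    """Over-representation p = P(X >= k) for each (cluster, category) cell.

    The universe is the set of samples with a non-missing category; N is
    its size, K the category count, n the cluster size within the
    universe, k the overlap.  Raw p-values, no multiplicity correction.
    """
    common = cluster_labels.index.intersection(category_labels.index)
    cl = cluster_labels.loc[common]
    cat = category_labels.loc[common]
    mask = cat.notna() & cl.notna()
    cl, cat = cl[mask], cat[mask]
    N = len(cl)
    if N == 0:
        raise ValueError("empty sample universe for enrichment")
    clusters = sorted(cl.unique(), key=str)
    categories = sorted(cat.unique(), key=str)
    pv = pd.DataFrame(index=clusters, columns=categories, dtype=float)
    counts: dict[tuple[str, str], tuple[int, int, int, int]] = {}
    for c in clusters:
        in_c = cl == c
        n = int(in_c.sum())
        for g in categories:
            in_g = cat == g
            Kg = int(in_g.sum())
            k = int((in_c & in_g).sum())
            pv.loc[c, g] = enrichment_pvalue(N, Kg, n, k)
            counts[(str(c), str(g))] = (N, Kg, n, k)
    return EnrichmentMatrix(pvalues=pv, counts=counts)


def similarity_to_reference(
    m: ExpressionMatrix,
    reference: pd.Series,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman correlation of every sample to a reference profile.

    Returns a frame with the raw correlation and its min-max scaled value
    in [0, 1] across the cohort (0 = least similar sample, 1 = most).
    ``genes`` restricts the comparison (e.g. to the signature); by default
    all shared genes are used.
    """
    scope = pd.Index(genes) if genes is not None else m.values.index
    common = scope.intersection(m.values.index).intersection(reference.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} shared genes; need >= 3")
    q = m.values.loc[common].to_numpy(dtype=float)
    r = reference.loc[common].to_numpy(dtype=float)[:, None]
    raw = pd.Series(_spearman_matrix(q, r)[:, 0], index=m.values.columns, name="raw")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn(
            "all samples equally similar to reference; scaled values set to 0.5",
            UserWarning,
            stacklevel=2,
        )
        scaled = pd.Series(0.5, index=raw.index)
    else:
        scaled = (raw - lo) / (hi - lo)
    return pd.DataFrame({"raw": raw, "scaled": scaled})


def adjacent_similarity_tests(
    similarity: pd.DataFrame, named_labels: pd.Series
) -> pd.DataFrame:
    """One-sided Welch t-tests between adjacent named clusters' similarity.

    Tests EMAT(j+1) > EMAT(j) on the scaled similarity, mirroring the
    stemness-gradient reading of the subtypes.
    """
    names = sorted(named_labels.unique())
    rows = []
    for a, b in zip(names[:-1], names[1:]):
        xa = similarity.loc[named_labels.index[named_labels == a], "scaled"]
        xb = similarity.loc[named_labels.index[named_labels == b], "scaled"]
        res = ttest_ind(xb, xa, equal_var=False, alternative="greater")
        rows.append(
            {
                "lower": a,
                "higher": b,
                "mean_lower": float(xa.mean()),
                "mean_higher": float(xb.mean()),
                "p": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows)


def marker_profile(
    m: ExpressionMatrix,
    labels: pd.Series,
    markers: tuple[str, ...] = DEFAULT_MARKERS,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-cluster marker means, ranks, and cluster-vs-rest Welch t-tests.

    Returns (table, missing_markers).  Rank 1 = highest mean expression of
    the marker among clusters.  The t-test is unpaired, two-tailed,
    cluster members vs all other samples.
    """
    labels = labels.loc[m.values.columns]
    present = [g for g in markers if g in m.values.index]
    missing = [g for g in markers if g not in m.values.index]
    if missing:
        logger.warning("markers absent from matrix: %s", missing)
    clusters = sorted(labels.unique(), key=str)
    rows = []
    for g in present:
        x = m.values.loc[g]
        means = {c: float(x[labels == c].mean()) for c in clusters}
        order = sorted(clusters, key=lambda c: -means[c])
        rank = {c: order.index(c) + 1 for c in clusters}
        for c in clusters:
            res = ttest_ind(x[labels == c], x[labels != c], equal_var=False)
            rows.append(
                {
                    "marker": g,
                    "cluster": c,
                    "mean": means[c],
                    "rank": rank[c],
                    "p": float(res.pvalue),
                }
            )
    return pd.DataFrame(rows), missing


def per_gene_survival_association(
    m: ExpressionMatrix, surv: SurvivalTable, alpha: float = 0.01
) -> pd.DataFrame:
    """Univariable Cox fit per gene on its z-scored expression.

    Returns a table (gene, coef, hr, p, significant) sorted by p;
    constant genes are excluded with a warning, non-converging fits are
    reported with NaN statistics.
    """
    rows = []
    surv = surv.subset(m.values.columns)
    for g in m.values.index:
        x = m.values.loc[g]
        sd = float(x.std(ddof=0))
        if sd == 0:
            warnings.warn(f"gene {g!r} is constant; excluded", UserWarning, stacklevel=2)
            continue
        z = (x - x.mean()) / sd
        cov = z.to_frame("expr")
        try:
            fit = cox_fit(cov, surv)
        except (ConvergenceError, ValueError, np.linalg.LinAlgError):
            rows.append({"gene": g, "coef": np.nan, "hr": np.nan, "p": np.nan})
            continue
        s = fit.summary.loc["expr"]
        rows.append({"gene": g, "coef": s["coef"], "hr": s["hr"], "p": s["p"]})
    out = pd.DataFrame(rows).set_index("gene").sort_values("p")
    out["significant"] = out["p"] < alpha
    logger.info(
        "per-gene survival association: %d/%d genes at p < %g",
        int(out["significant"].sum()), len(out), alpha,
    )
    return out


def tf_differential_expression(
    m: ExpressionMatrix,
    labels: pd.Series,
    tf_list: list[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Cluster-vs-rest Welch t-tests for each TF, Bonferroni corrected.

    The Bonferroni family is all (TF, cluster) tests actually run.
    Returns a long table with the mean difference (cluster minus rest),
    raw and adjusted p, direction, and a significance flag at ``alpha``.
    """
    labels = labels.loc[m.values.columns]
    present = [g for g in tf_list if g in m.values.index]
    if not present:
        raise ValueError("no TFs from the list are present in the matrix")
    clusters = []
    for c in sorted(labels.unique(), key=str):
        if (labels == c).sum() < 2:
            warnings.warn(
                f"cluster {c!r} has fewer than 2 samples; skipped", UserWarning,
                stacklevel=2,
            )
            continue
        clusters.append(c)
    sub = m.values.loc[present]
    rows = []
    for c in clusters:
        in_c = (labels == c).to_numpy()
        a = sub.to_numpy()[:, in_c]
        b = sub.to_numpy()[:, ~in_c]
        res = ttest_ind(a, b, axis=1, equal_var=False)
        diff = a.mean(axis=1) - b.mean(axis=1)
        for g, d, p in zip(present, diff, res.pvalue):
            rows.append(
                {
                    "tf": g,
                    "cluster": c,
                    "mean_diff": float(d),
                    "p_raw": float(p),
                    "direction": "over" if d > 0 else "under",
                }
            )
    out = pd.DataFrame(rows)
    n_tests = len(out)
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * n_tests)
    out["significant"] = out["p_bonferroni"] < alpha
    return out


def top_tfs_per_cluster(de_table: pd.DataFrame) -> pd.DataFrame:
    """Per cluster, the most over- and under-expressed significant TF
    (largest |mean difference| among Bonferroni-significant tests)."""
    rows = []
    for c in sorted(de_table["cluster"].unique(), key=str):
        sig = de_table[(de_table["cluster"] == c) & de_table["significant"]]
        for direction in ("over", "under"):
            part = sig[sig["direction"] == direction]
            if part.empty:
                rows.append({"cluster": c, "direction": direction, "tf": None})
                continue
            best = part.loc[part["mean_diff"].abs().idxmax()]
            rows.append(
                {
                    "cluster": c,
                    "direction": direction,
                    "tf": best["tf"],
                    "mean_diff": best["mean_diff"],
                    "p_bonferroni": best["p_bonferroni"],
                }
            )
    return pd.DataFrame(rows)


def signature_de_fraction(
    m: ExpressionMatrix,
    labels: pd.Series,
    sig: GeneSignature,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per cluster, the fraction of each component list (EMT / MAT / both)
    among that cluster's differentially expressed signature genes."""
    de = tf_differential_expression(m, labels, sig.gene_ids, alpha=alpha)
    source = {e.gene_id: e.source for e in sig.entries}
    rows = []
    for c in sorted(de["cluster"].unique(), key=str):
        sig_de = de[(de["cluster"] == c) & de["significant"]]
        genes = sig_de["tf"].unique()
        n = len(genes)
        counts = pd.Series([source[g] for g in genes]).value_counts()
        rows.append(
            {
                "cluster": c,
                "n_de_genes": n,
                "frac_emt": float(counts.get("EMT", 0) + counts.get("both", 0)) / n if n else np.nan,
                "frac_mat": float(counts.get("MAT", 0) + counts.get("both", 0)) / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def signature_overlap(a: GeneSignature, b: GeneSignature) -> list[str]:
    """Genes shared by two signatures (generic overlap utility)."""
    return sorted(set(a.gene_ids) & set(b.gene_ids))


def jaccard_concordance(
    labels_a: pd.Series, labels_b: pd.Series
) -> tuple[pd.DataFrame, dict, float]:
    """Pairwise Jaccard matrix between two labelings plus the optimal
    one-to-one cluster matching and its mean matched Jaccard.

    J(a_i, b_j) = |a_i and b_j| / |a_i or b_j| over the shared sample
    universe; the matching maximizes the summed Jaccard of matched pairs.
    """
    common = labels_a.index.intersection(labels_b.index)
    if len(common) == 0:
        raise ValueError("labelings share no samples")
    la = labels_a.loc[common]
    lb = labels_b.loc[common]
    cats_a = sorted(la.unique(), key=str)
    cats_b = sorted(lb.unique(), key=str)
    J = pd.DataFrame(index=cats_a, columns=cats_b, dtype=float)
    for a in cats_a:
        sa = set(common[la == a])
        for b in cats_b:
            sb = set(common[lb == b])
            J.loc[a, b] = len(sa & sb) / len(sa | sb)
    cost = -J.to_numpy(dtype=float)
    ri, ci = linear_sum_assignment(cost)
    matching = {cats_a[i]: cats_b[j] for i, j in zip(ri, ci)}
    matched_mean = float(np.mean([J.loc[a, b] for a, b in matching.items()]))
    return J, matching, matched_mean
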