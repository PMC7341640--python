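"""Single-sample subtype assignment by Spearman rank correlation.

The default predictor is a nearest-centroid classifier: each training
cluster is summarized by its per-gene mean expression vector, and a test
sample receives the label of the centroid with the highest Spearman rank
correlation over the shared genes.  Rank correlation makes the call
invariant to any monotone intensity distortion of the test cohort, which
is what allows cross-platform, cross-dataset application.  A k-nearest
neighbour variant with the same similarity measure is provided as a
secondary method.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class CentroidClassifier:
    """Per-class mean-expression centroids over the training signature genes."""

    centroids: pd.DataFrame  # genes x classes
    min_coverage: float = 0.5

    def __post_init__(self) -> None:
        if self.centroids.index.has_duplicates:
            raise ValueError("duplicate gene ids in centroid matrix")
        if self.centroids.columns.has_duplicates:
            raise ValueError("duplicate class names")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.centroids.index)

    @property
    def class_names(self) -> list[str]:
        return list(self.centroids.columns)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = self.centroids.copy()
        out.index.name = "gene_id"
        out.to_csv(directory / "centroids.tsv", sep="\t")
        meta = {
            "class_names": self.class_names,
            "n_genes": len(self.gene_ids),
            "min_coverage": self.min_coverage,
        }
        (directory / "classifier.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "CentroidClassifier":
        directory = Path(directory)
        cents = pd.read_csv(directory / "centroids.tsv", sep="\t", index_col=0)
        meta = json.loads((directory / "classifier.json").read_text())
        return cls(cents[meta["class_names"]], min_coverage=meta["min_coverage"])


def fit_centroids(
    m: ExpressionMatrix, labels: pd.Series, min_coverage: float = 0.5
) -> CentroidClassifier:
    """Per-class gene means over the training samples."""
    labels = labels.loc[m.values.columns]
    cents = {}
    for cls_name in sorted(labels.unique(), key=str):
        members = labels.index[labels == cls_name]
        if len(members) == 0:
            raise ValueError(f"class {cls_name!r} has no training samples")
        cents[cls_name] = m.values[members].mean(axis=1)
    return CentroidClassifier(pd.DataFrame(cents), min_coverage=min_coverage)


def _overlap_or_raise(
    profile_genes: pd.Index, clf_genes: pd.Index, min_coverage: float
) -> pd.Index:
    common = clf_genes.intersection(profile_genes)
    coverage = len(common) / len(clf_genes)
    if coverage < min_coverage or len(common) < 3:
        raise ValueError(
            f"insufficient gene overlap: {len(common)}/{len(clf_genes)} "
            f"(coverage {coverage:.3f}, need >= {min_coverage} and >= 3 genes)"
        )
    return common


def _spearman_matrix(queries: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Spearman correlation of each query column with each target column.

    Both inputs are genes x columns over the same genes; ties get average
    ranks, so this is Pearson correlation of the rank transforms.
    """
    rq = rankdata(queries, axis=0)
    rt = rankdata(targets, axis=0)
    rq = rq - rq.mean(axis=0)
    rt = rt - rt.mean(axis=0)
    denom = np.outer(
        np.sqrt((rq**2).sum(axis=0)), np.sqrt((rt**2).sum(axis=0))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (rq.T @ rt) / denom
    return corr


def classify_centroid(
    profile: pd.Series, clf: CentroidClassifier
) -> tuple[str, pd.Series]:
    """Label one sample: argmax Spearman correlation against the centroids.

    Returns the label and the per-class correlations.  Exact ties go to
    the lowest class index with a warning.
    """
    labels, corr = classify_matrix(
        ExpressionMatrix(profile.to_frame("query"), scale="zscore"), clf
    )
    return labels.iloc[0], corr.iloc[0]


def classify_matrix(
    m: ExpressionMatrix, clf: CentroidClassifier
) -> tuple[pd.Series, pd.DataFrame]:
    """Vectorized centroid classification of every sample in a matrix."""
    common = _overlap_or_raise(m.values.index, clf.centroids.index, clf.min_coverage)
    q = m.values.loc[common].to_numpy(dtype=float)
    t = clf.centroids.loc[common].to_numpy(dtype=float)
    corr = _spearman_matrix(q, t)
    corr_df = pd.DataFrame(corr, index=m.values.columns, columns=clf.class_names)
    best = corr_df.to_numpy().argmax(axis=1)  # argmax -> first (lowest class index) on ties
    row_max = corr_df.to_numpy().max(axis=1)
    n_tied = (corr_df.to_numpy() == row_max[:, None]).sum(axis=1)
    if (n_tied > 1).any():
        warnings.warn(
            f"{int((n_tied > 1).sum())} sample(s) had tied centroid correlations; "
            "assigned the lowest class index",
            UserWarning,
            stacklevel=2,
        )
    labels = pd.Series(
        [clf.class_names[i] for i in best], index=m.values.columns, name="label"
    )
    return labels, corr_df


def classify_knn(
    profile: pd.Series,
    training: ExpressionMatrix,
    labels: pd.Series,
    k: int = 5,
    min_coverage: float = 0.5,
) -> str:
    """k-nearest-neighbour label by Spearman similarity to training samples.

    Majority vote over the k most correlated training samples; vote ties
    are resolved toward the tied class with the larger summed correlation.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > training.n_samples:
        raise ValueError(f"k={k} exceeds training size {training.n_samples}")
    common = _overlap_or_raise(
        pd.Index(profile.index), training.values.index, min_coverage
    )
    q = profile.loc[common].to_numpy(dtype=float)[:, None]
    t = training.values.loc[common].to_numpy(dtype=float)
    corr = pd.Series(
        _spearman_matrix(q, t)[0], index=training.values.columns
    )
    # stable sort keeps training order deterministic among exactly tied sims
    neighbours = corr.sort_values(ascending=False, kind="stable").index[:k]
    votes = labels.loc[neighbours].value_counts()
    top = votes[votes == votes.max()].index
    if len(top) == 1:
        return top[0]
    sums = {
        cls_name: corr[neighbours[labels.loc[neighbours] == cls_name]].sum()
        for cls_name in top
    }
    return max(sorted(sums), key=lambda c: sums[c])
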