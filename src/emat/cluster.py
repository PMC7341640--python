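"""Subtype discovery: Ward clustering with silhouette-based model selection.

Samples are clustered over the z-scored signature matrix with Ward's
variance-minimization linkage on Euclidean distances.  The number of
clusters is chosen among candidates by the mean of average silhouette
scores under three distances (cosine, Euclidean, correlation).  Clusters
are then named EMAT1..EMATK in decreasing order of Kaplan-Meier survival
at a fixed horizon, so that EMAT1 is the best-prognosis subtype.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_samples

from .preprocess import ExpressionMatrix
from .survival import SurvivalTable, km_survival_at

logger = logging.getLogger(__name__)

SILHOUETTE_METRICS = ("cosine", "euclidean", "correlation")


@dataclass
class ClusterModel:
    """Result of a hierarchical clustering of cohort samples.

    ``labels`` maps sample id -> cluster index (1..K, the `scipy.fcluster`
    numbering); ``linkage_record`` is the merge history, sufficient to
    re-cut the tree; ``centroids`` holds per-cluster mean expression
    (genes x K); ``name_map`` maps cluster index to a display name.
    """

    labels: pd.Series
    K: int
    linkage_record: np.ndarray
    centroids: pd.DataFrame
    name_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name_map:
            self.name_map = {k: f"cluster{k}" for k in sorted(self.labels.unique())}
        if len(set(self.name_map.values())) != len(self.name_map):
            raise ValueError("name_map must be a bijection")

    @property
    def named_labels(self) -> pd.Series:
        """Per-sample display names."""
        return self.labels.map(self.name_map)

    @property
    def ordinal_labels(self) -> pd.Series:
        """Per-sample ordinal code parsed from EMAT names (EMATj -> j)."""
        def code(name: str) -> int:
            m = re.fullmatch(r"EMAT(\d+)", name)
            if not m:
                raise ValueError(f"cluster name {name!r} is not an EMAT name")
            return int(m.group(1))

        return self.named_labels.map(code)

    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class SilhouetteReport:
    """Average silhouettes per candidate K and metric, and the chosen K."""

    scores: pd.DataFrame  # index = K, columns = metrics
    chosen_K: int
    models: dict[int, ClusterModel] = field(default_factory=dict)


def _compute_centroids(m: ExpressionMatrix, labels: pd.Series) -> pd.DataFrame:
    cents = {}
    for k in sorted(labels.unique()):
        members = labels.index[labels == k]
        cents[k] = m.values[members].mean(axis=1)
    return pd.DataFrame(cents)


def ward_linkage(m: ExpressionMatrix) -> np.ndarray:
    """Ward merge history over samples (Euclidean distances)."""
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples to cluster")
    return linkage(m.values.to_numpy().T, method="ward")


def cut_tree(
    m: ExpressionMatrix, linkage_record: np.ndarray, K: int
) -> ClusterModel:
    """Cut a precomputed Ward tree into exactly K clusters."""
    n = m.n_samples
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}], got {K}")
    flat = fcluster(linkage_record, t=K, criterion="maxclust")
    labels = pd.Series(flat, index=m.values.columns, name="cluster")
    got = labels.nunique()
    if got != K:
        raise ValueError(f"tree cut produced {got} clusters instead of {K}")
    return ClusterModel(
        labels=labels,
        K=K,
        linkage_record=linkage_record,
        centroids=_compute_centroids(m, labels),
    )


def ward_cluster(m: ExpressionMatrix, K: int) -> ClusterModel:
    """Ward hierarchical clustering of samples cut to exactly K clusters."""
    if K > m.n_samples:
        raise ValueError(f"K={K} exceeds number of samples ({m.n_samples})")
    return cut_tree(m, ward_linkage(m), K)


def silhouette_mean(
    m: ExpressionMatrix, labels: pd.Series, metric: str = "euclidean"
) -> float:
    """Mean silhouette over samples; singleton clusters contribute 0."""
    if metric not in SILHOUETTE_METRICS:
        raise ValueError(f"metric must be one of {SILHOUETTE_METRICS}, got {metric!r}")
    labels = labels.loc[m.values.columns]
    if labels.nunique() < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    X = m.values.to_numpy().T
    s = silhouette_samples(X, labels.to_numpy(), metric=metric)
    return float(np.mean(s))


def select_n_clusters(
    m: ExpressionMatrix, candidates: tuple[int, ...] = (3, 4, 5)
) -> SilhouetteReport:
    """Choose K by the mean of average silhouettes over the three metrics.

    Ties break toward the smaller K.
    """
    candidates = tuple(sorted(set(int(k) for k in candidates)))
    if any(k < 2 for k in candidates):
        raise ValueError("all candidate K must be >= 2")
    Z = ward_linkage(m)
    rows = {}
    models = {}
    for K in candidates:
        model = cut_tree(m, Z, K)
        models[K] = model
        rows[K] = {
            metric: silhouette_mean(m, model.labels, metric)
            for metric in SILHOUETTE_METRICS
        }
    scores = pd.DataFrame(rows).T
    scores.index.name = "K"
    means = scores.mean(axis=1)
    chosen = int(means.index[np.argmax(means.to_numpy())])  # argmax: first = smallest K
    logger.info("silhouette model selection: chose K=%d from %s", chosen, candidates)
    return SilhouetteReport(scores=scores, chosen_K=chosen, models=models)


def assign_cluster_names(
    model: ClusterModel, surv: SurvivalTable, horizon: float = 120.0
) -> ClusterModel:
    """Name clusters EMAT1..EMATK in decreasing Kaplan-Meier survival order.

    Survival is evaluated at ``horizon`` months (default 120, i.e. 10-year
    follow-up).  Ties put the larger cluster first.  The numbering is a
    display convention only; survival curves are unchanged by renaming.
    """
    missing = model.labels.index.difference(surv.data.index)
    if len(missing):
        raise ValueError(f"survival table missing {len(missing)} labelled samples")
    surv_aligned = surv.subset(model.labels.index)
    if horizon > float(surv_aligned.data["time"].max()):
        raise ValueError(
            f"naming horizon {horizon} exceeds maximum follow-up "
            f"{surv_aligned.data['time'].max():.6g}"
        )
    rows = []
    for k in sorted(model.labels.unique()):
        members = model.labels.index[model.labels == k]
        s = km_survival_at(surv.subset(members), horizon)
        rows.append((k, s, len(members)))
    # best survival first; ties -> larger cluster first
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    name_map = {k: f"EMAT{rank + 1}" for rank, (k, _, _) in enumerate(rows)}
    logger.info("cluster naming by %.6g-month survival: %s", horizon, name_map)
    return replace(model, name_map=name_map)
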