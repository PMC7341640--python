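"""Expression-matrix container and cohort normalization.

Cohort expression is log2 transformed and per-gene Z normalized before any
clustering or classification step.  Matrices are genes x samples; the scale
tag tracks where a matrix sits in the raw -> log2 -> zscore chain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .signature import GeneSignature

logger = logging.getLogger(__name__)

SCALES = ("raw", "log2", "zscore")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with unique identifiers on both axes."""

    values: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        v = self.values
        if v.index.has_duplicates:
            raise ValueError(
                f"duplicate gene ids: {sorted(v.index[v.index.duplicated()].unique())}"
            )
        if v.columns.has_duplicates:
            raise ValueError(
                f"duplicate sample ids: "
                f"{sorted(v.columns[v.columns.duplicated()].unique())}"
            )
        arr = v.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite entry at gene={v.index[i]!r} sample={v.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise base-2 logarithm of a raw-intensity matrix."""
    if m.scale != "raw":
        raise ValueError(f"log2_transform expects a raw matrix, got scale={m.scale!r}")
    arr = m.values.to_numpy()
    if (arr <= 0).any():
        i, j = np.argwhere(arr <= 0)[0]
        raise ValueError(
            "log2 transform requires strictly positive intensities; offending "
            f"entry gene={m.values.index[i]!r} sample={m.values.columns[j]!r} "
            f"value={m.values.iat[i, j]!r}"
        )
    return ExpressionMatrix(np.log2(m.values), scale="log2")


def z_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene Z score across samples (population standard deviation).

    Zero-variance gene rows carry no ranking information and are dropped
    with a warning.  Accepts a log2 matrix (the normal path) or an already
    z-scored matrix, on which the operation is idempotent.
    """
    if m.scale == "raw":
        raise ValueError("z_normalize expects log2 (or zscore) input, got raw")
    if m.n_samples < 2:
        raise ValueError("z_normalize requires at least 2 samples")
    v = m.values
    sd = v.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        dropped = list(v.index[flat])
        warnings.warn(
            f"dropping {len(dropped)} zero-variance gene row(s): {dropped[:10]}",
            UserWarning,
            stacklevel=2,
        )
        logger.warning("z_normalize dropped %d zero-variance genes", len(dropped))
        v = v.loc[~flat]
        sd = sd[~flat]
    z = v.sub(v.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, scale="zscore")


class SubsetResult(NamedTuple):
    matrix: ExpressionMatrix
    coverage: float


def subset_to_signature(
    m: ExpressionMatrix, sig: GeneSignature, min_coverage: float = 0.5
) -> SubsetResult:
    """Restrict a matrix to signature genes, preserving signature order.

    ``coverage`` is the fraction of signature genes found in the matrix;
    below ``min_coverage`` the subset is refused (cross-platform matrices
    with poor gene overlap would make downstream rank correlations
    meaningless).
    """
    if not 0 < min_coverage <= 1:
        raise ValueError(f"min_coverage must be in (0, 1], got {min_coverage}")
    present = [g for g in sig.gene_ids if g in m.values.index]
    coverage = len(present) / len(sig) if len(sig) else 0.0
    if coverage < min_coverage:
        raise ValueError(
            f"signature coverage {coverage:.3f} ({len(present)}/{len(sig)} genes) "
            f"below required minimum {min_coverage}"
        )
    logger.info("subset to signature: %d/%d genes (coverage %.3f)", len(present), len(sig), coverage)
    return SubsetResult(ExpressionMatrix(m.values.loc[present], scale=m.scale), coverage)


def collapse_probes(
    values: pd.DataFrame, probe_to_gene: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes by keeping, per gene, the
    probe with maximal variance across samples."""
    mapping = pd.Series(probe_to_gene)
    common = values.index.intersection(mapping.index)
    sub = values.loc[common]
    genes = mapping.loc[common]
    variances = sub.var(axis=1, ddof=0)
    best = variances.groupby(genes).idxmax()
    collapsed = sub.loc[best.to_numpy()]
    collapsed.index = best.index
    logger.info("collapsed %d probes to %d genes", len(sub), len(collapsed))
    return collapsed
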