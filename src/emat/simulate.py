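"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a lymph node-negative breast-cancer cohort: a gene
panel containing the signature genes, K latent expression clusters with
tunable separation over those genes, clinical covariates optionally
confounded with the clusters, proportional-hazards survival times with
cluster-dependent hazard and independent censoring, and a stem-cell-like
reference profile correlated with a chosen cluster gradient.  Everything
is fully determined by (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .preprocess import ExpressionMatrix
from .signature import FoldChangeTable, GeneSignature, SignatureEntry, load_emat_signature
from .survival import SurvivalTable, encode_covariates

logger = logging.getLogger(__name__)

# Global marginals for the categorical clinical covariates, chosen to match
# the scale of a lymph node-negative METABRIC-like cohort.
_SIZE_LEVELS = ("<2", "2-5", ">5")
_SIZE_PROBS = (0.40, 0.57, 0.03)
_GRADE_LEVELS = ("low", "intermediate", "high")
_GRADE_PROBS = (0.09, 0.45, 0.46)
_PAM50_LEVELS = ("normal-like", "luminal A", "luminal B", "HER2-enriched", "basal-like")
_PAM50_PROBS = (0.13, 0.44, 0.20, 0.08, 0.15)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``separation`` is the between-centroid shift over signature genes in
    units of the within-cluster standard deviation: per gene, cluster
    means are drawn so the expected squared centroid gap equals
    ``(separation * noise_sd)**2``.  Hazard ratios are per latent cluster
    (ordered; cluster 1 is the reference), on an exponential baseline
    hazard per month unless a Weibull shape is given.  ``censoring_rate``
    is the expected fraction of censored subjects, achieved by an
    independent exponential censoring time whose rate is solved
    analytically.
    """

    n_samples: int = 562
    n_genes: int = 2000
    signature_size: int = 388
    K: int = 4
    proportions: tuple[float, ...] = (0.194, 0.457, 0.260, 0.089)
    separation: float = 1.0
    noise_sd: float = 1.0
    hazard_ratios: tuple[float, ...] = (1.0, 1.5, 1.6, 4.0)
    baseline_hazard: float = 0.002  # events per month for cluster 1
    censoring_rate: float = 0.6
    weibull_shape: float = 1.0
    clinical_log_hr: tuple[tuple[str, float], ...] = ()  # (encoded covariate, log-HR/unit)
    cluster_confounding: float = 0.5  # P(categorical covariate takes its cluster-preferred level)
    baseline_expression: float = 8.0  # log2-intensity offset
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.proportions) != self.K or len(self.hazard_ratios) != self.K:
            raise ValueError("proportions and hazard_ratios must have length K")
        if abs(sum(self.proportions) - 1.0) > 1e-8:
            raise ValueError("mixing proportions must sum to 1")
        if any(h <= 0 for h in self.hazard_ratios):
            raise ValueError("hazard ratios must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring rate must be in [0, 1)")
        if self.K > self.n_samples:
            raise ValueError("K exceeds n_samples")
        if self.signature_size > self.n_genes:
            raise ValueError("signature_size exceeds n_genes")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    expr: ExpressionMatrix  # log2 scale, genes x samples
    clinical: pd.DataFrame  # categorical clinical table
    covariates: pd.DataFrame  # encoded numeric covariates
    surv: SurvivalTable
    labels: pd.Series  # true latent cluster per sample (1..K)
    centroids: pd.DataFrame  # signature genes x K latent centroids
    signature: GeneSignature
    spec: CohortSpec = field(repr=False, default=None)


def _signature_for(size: int) -> GeneSignature:
    packaged = load_emat_signature()
    if size <= len(packaged):
        return GeneSignature(packaged.entries[:size], name=f"synthetic-{size}")
    extra = [
        SignatureEntry(f"SIG{i:04d}", source="MAT", direction="unknown")
        for i in range(size - len(packaged))
    ]
    return GeneSignature(packaged.entries + extra, name=f"synthetic-{size}")


def _sample_categorical(rng, n, levels, probs, cluster_idx, preferred, confounding):
    """Draw a categorical covariate: with probability ``confounding`` the
    cluster-preferred level, otherwise from the global marginal."""
    base = rng.choice(len(levels), size=n, p=np.asarray(probs) / np.sum(probs))
    take_pref = rng.random(n) < confounding
    pref_codes = np.array([levels.index(preferred[c - 1]) for c in cluster_idx])
    codes = np.where(take_pref, pref_codes, base)
    return pd.Categorical.from_codes(codes, categories=list(levels))


def _censoring_rate_for(mu: float, rates: np.ndarray, shape: float) -> float:
    if shape == 1.0:
        return float(np.mean(mu / (rates + mu)))
    # P(censored) = E[P(C < T)] via numeric integration of the censoring
    # density against Weibull survival, shared grid across subjects
    t = np.linspace(0, 12.0 / mu, 4000)[None, :]
    dens = mu * np.exp(-mu * t)
    surv_t = np.exp(-rates[:, None] * t**shape)
    return float(np.mean(np.trapezoid(dens * surv_t, t, axis=1)))


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> SyntheticCohort:
    """Generate expression, clinical, survival and truth for one cohort."""
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    K, n = spec.K, spec.n_samples

    sig = _signature_for(spec.signature_size)
    sig_genes = sig.gene_ids
    bg_genes = [f"GENE{i:05d}" for i in range(spec.n_genes - spec.signature_size)]
    genes = sig_genes + bg_genes
    samples = [f"S{i:04d}" for i in range(n)]

    labels = rng.choice(np.arange(1, K + 1), size=n, p=np.asarray(spec.proportions))
    # guarantee every cluster is populated (tiny cohorts)
    for k in range(1, K + 1):
        if not (labels == k).any():
            labels[rng.integers(n)] = k

    centroid_sd = spec.separation * spec.noise_sd / np.sqrt(2.0)
    centroids = rng.normal(0.0, centroid_sd, size=(spec.signature_size, K))
    X = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))
    X[: spec.signature_size] += centroids[:, labels - 1]
    X += spec.baseline_expression
    expr = ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=samples), scale="log2"
    )

    age = np.clip(rng.normal(61.0, 12.0, size=n), 25, 90).round(1)
    clinical = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    clinical["age"] = age
    conf = spec.cluster_confounding
    clinical["tumor_size"] = _sample_categorical(
        rng, n, list(_SIZE_LEVELS), _SIZE_PROBS, labels,
        ["<2", "2-5", "2-5", ">5"][:K] + ["2-5"] * max(0, K - 4), conf,
    )
    clinical["grade"] = _sample_categorical(
        rng, n, list(_GRADE_LEVELS), _GRADE_PROBS, labels,
        ["low", "intermediate", "intermediate", "high"][:K] + ["high"] * max(0, K - 4), conf,
    )
    clinical["er"] = _sample_categorical(
        rng, n, ["+", "-"], (0.79, 0.21), labels,
        ["+", "+", "+", "-"][:K] + ["-"] * max(0, K - 4), conf,
    )
    clinical["pr"] = _sample_categorical(
        rng, n, ["+", "-"], (0.56, 0.44), labels,
        ["+", "+", "+", "-"][:K] + ["-"] * max(0, K - 4), conf,
    )
    clinical["her2"] = _sample_categorical(
        rng, n, ["-", "+"], (0.81, 0.19), labels,
        ["-", "+", "-", "-"][:K] + ["-"] * max(0, K - 4), conf,
    )
    clinical["pam50"] = _sample_categorical(
        rng, n, list(_PAM50_LEVELS), _PAM50_PROBS, labels,
        ["normal-like", "luminal A", "luminal B", "basal-like"][:K]
        + ["basal-like"] * max(0, K - 4), conf,
    )
    for flag, prob in (("chemo", 0.07), ("hormonal", 0.48), ("radiation", 0.54)):
        clinical[flag] = (rng.random(n) < prob).astype(int)

    covariates = encode_covariates(clinical)

    rates = spec.baseline_hazard * np.asarray(spec.hazard_ratios)[labels - 1]
    if spec.clinical_log_hr:
        lin = np.zeros(n)
        for cov_name, beta in spec.clinical_log_hr:
            x = covariates[cov_name].to_numpy(dtype=float)
            if cov_name == "age":
                x = x - 60.0
            lin += beta * x
        rates = rates * np.exp(lin)

    shape = spec.weibull_shape
    e = rng.exponential(1.0, size=n)
    event_time = (e / rates) ** (1.0 / shape)
    if spec.censoring_rate > 0:
        lo, hi = 1e-10, 1e4
        mu = brentq(
            lambda m: _censoring_rate_for(m, rates, shape) - spec.censoring_rate, lo, hi
        )
        cens_time = rng.exponential(1.0 / mu, size=n)
    else:
        cens_time = np.full(n, np.inf)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)
    surv = SurvivalTable.from_arrays(samples, time, event, endpoint="synthetic")

    labels_s = pd.Series(labels, index=pd.Index(samples, name="sample_id"), name="cluster")
    cent_df = pd.DataFrame(
        centroids, index=sig_genes, columns=[k for k in range(1, K + 1)]
    )
    logger.info(
        "generated cohort: n=%d genes=%d K=%d events=%d", n, spec.n_genes, K,
        int(event.sum()),
    )
    return SyntheticCohort(
        expr=expr,
        clinical=clinical,
        covariates=covariates,
        surv=surv,
        labels=labels_s,
        centroids=cent_df,
        signature=sig,
        spec=spec,
    )


def generate_perturbation_experiments(
    n_genes: int = 1000,
    n_experiments: int = 4,
    planted: list[str] | int = 138,
    fold_range: tuple[float, float] = (1.8, 3.0),
    noise_sd: float = 0.2,
    min_experiments: int = 2,
    seed: int = 0,
) -> tuple[FoldChangeTable, dict[str, str]]:
    """Fold-change tables from simulated perturbation experiments.

    Planted genes receive ratios beyond ``fold_range[0]`` (up or down,
    consistent per gene) in at least ``min_experiments`` experiments;
    background ratios are log-normal, concentrated near 1 with log2-scale
    standard deviation ``noise_sd``.  Returns the table and the planted
    truth (gene -> direction).
    """
    if fold_range[0] <= 1 or fold_range[1] < fold_range[0]:
        raise ValueError(
            f"fold range must satisfy 1 < lo <= hi, got {fold_range}"
        )
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    if isinstance(planted, int):
        planted_genes = list(rng.choice(genes, size=planted, replace=False))
    else:
        planted_genes = list(planted)
        unknown = set(planted_genes) - set(genes)
        if unknown:
            raise ValueError(f"planted genes outside the gene universe: {sorted(unknown)}")
    log_ratios = rng.normal(0.0, noise_sd, size=(n_genes, n_experiments))
    truth: dict[str, str] = {}
    index = {g: i for i, g in enumerate(genes)}
    for g in planted_genes:
        i = index[g]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        n_hit = rng.integers(min_experiments, n_experiments + 1)
        hits = rng.choice(n_experiments, size=n_hit, replace=False)
        mags = rng.uniform(np.log2(fold_range[0]), np.log2(fold_range[1]), size=n_hit)
        log_ratios[i, hits] = sign * mags
        truth[g] = "up" if sign > 0 else "down"
    values = pd.DataFrame(
        np.exp2(log_ratios),
        index=genes,
        columns=[f"exp{j + 1}" for j in range(n_experiments)],
    )
    return FoldChangeTable(values), truth


def generate_reference_profile(
    centroids: pd.DataFrame,
    weights,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """A reference expression profile correlated with a cluster gradient.

    The profile is the weights-weighted combination of the latent cluster
    centroids plus optional Gaussian noise, so the expected similarity of
    a sample to the reference is monotone in its cluster's weight.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != centroids.shape[1]:
        raise ValueError(
            f"weights length {w.shape[0]} != number of clusters {centroids.shape[1]}"
        )
    rng = np.random.default_rng(seed)
    profile = centroids.to_numpy(dtype=float) @ w
    if noise_sd > 0:
        profile = profile + rng.normal(0.0, noise_sd, size=profile.shape)
    return pd.Series(profile, index=centroids.index, name="reference")
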