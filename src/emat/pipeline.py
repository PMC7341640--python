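"""End-to-end orchestration of the subtype analysis.

``run_full_pipeline`` wires the stages together on file inputs or
in-memory tables: normalization, silhouette-based cluster-number
selection, outcome-ordered cluster naming, survival analyses (Kaplan-
Meier, log-rank, univariable and multivariable Cox), cluster
characterization, and optionally the repeated-split CV benchmark.  Each
output file carries a provenance header (tool version, seed, config
hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .characterize import hypergeometric_enrichment, marker_profile, per_gene_survival_association
from .cluster import assign_cluster_names, select_n_clusters
from .cv import run_cv_comparison
from .io import read_clinical, read_expression, read_survival, write_labels
from .preprocess import log2_transform, subset_to_signature, z_normalize
from .signature import load_emat_signature, read_gene_list
from .survival import cox_fit, cox_fit_univariable, encode_covariates, kaplan_meier, logrank_test

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File paths and parameters for a full run."""

    expression: str
    output_dir: str
    signature: str | None = None  # gene-list TSV; packaged EMAT list if omitted
    clinical: str | None = None
    survival: str | None = None
    expression_scale: str = "raw"
    candidates: tuple[int, ...] = (3, 4, 5)
    min_coverage: float = 0.5
    naming_horizon: float = 120.0
    run_cv: bool = False
    cv_repeats: int = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)

    def config_hash(self) -> str:
        # fingerprint of the analysis parameters; the output location is not one
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(config: PipelineConfig) -> list[str]:
    return [
        f"emat {__version__}",
        f"seed={config.seed}",
        f"config_hash={config.config_hash()}",
    ]


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage the available inputs allow; returns a manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _header(config)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "parameters": dataclasses.asdict(config),
        "outputs": [],
        "skipped": [],
    }

    def _record(name: str) -> Path:
        manifest["outputs"].append(name)
        return out / name

    current_stage = "setup"

    def _stage(name):
        nonlocal current_stage
        current_stage = name
        logger.info("pipeline stage: %s", name)

    try:
        _stage("preprocess")
        m = read_expression(config.expression, scale=config.expression_scale)
        if m.scale == "raw":
            m = log2_transform(m)
        m = z_normalize(m)
        sig = (
            read_gene_list(config.signature, name="signature")
            if config.signature
            else load_emat_signature()
        )
        m_sig, coverage = subset_to_signature(m, sig, min_coverage=config.min_coverage)
        manifest["signature_coverage"] = coverage

        _stage("cluster-select")
        report = select_n_clusters(m_sig, candidates=config.candidates)
        model = report.models[report.chosen_K]
        manifest["chosen_K"] = report.chosen_K
        scores = report.scores.copy()
        scores.insert(0, "K", scores.index)
        scores.to_csv(_record("silhouette.tsv"), sep="\t", index=False)

        surv = read_survival(config.survival) if config.survival else None
        clinical = read_clinical(config.clinical) if config.clinical else None

        if surv is not None:
            _stage("name-clusters")
            horizon = min(config.naming_horizon, float(surv.data["time"].max()))
            model = assign_cluster_names(model, surv.subset(model.labels.index), horizon=horizon)
        write_labels(model.named_labels, _record("cluster_labels.tsv"), header)

        if surv is not None:
            _stage("survival")
            km = kaplan_meier(surv)
            km.to_csv(_record("kaplan_meier.tsv"), sep="\t", index=False)
            lr = logrank_test(surv.subset(model.labels.index), model.named_labels, pairwise=True)
            manifest["logrank"] = {"statistic": lr.statistic, "p": lr.p_value, "df": lr.df}
            lr.pairwise.to_csv(_record("logrank_pairwise.tsv"), sep="\t", index=False)
            if clinical is not None:
                cov = encode_covariates(clinical).loc[model.labels.index]
                cov["emat"] = model.ordinal_labels.astype(float)
                uni = cox_fit_univariable(cov, surv.subset(cov.index))
                uni.to_csv(_record("cox_univariable.tsv"), sep="\t")
                multi = cox_fit(cov, surv.subset(cov.index))
                multi.summary.to_csv(_record("cox_multivariable.tsv"), sep="\t")
                manifest["cox_lrt_p"] = multi.lrt_p
        else:
            manifest["skipped"].append("survival (no survival table provided)")
            logger.info("survival stages skipped: no survival table provided")

        _stage("characterize")
        markers, missing = marker_profile(m_sig, model.named_labels)
        if not markers.empty:
            markers.to_csv(_record("marker_profile.tsv"), sep="\t", index=False)
        if clinical is not None:
            for col in ("pam50", "er", "pr", "her2", "tumor_size", "grade"):
                if col in clinical.columns:
                    enr = hypergeometric_enrichment(model.named_labels, clinical[col])
                    enr.pvalues.to_csv(_record(f"enrichment_{col}.tsv"), sep="\t")
        if surv is not None:
            pg = per_gene_survival_association(m_sig, surv.subset(model.labels.index))
            pg.to_csv(_record("per_gene_cox.tsv"), sep="\t")

        if config.run_cv and surv is not None and clinical is not None:
            _stage("cv-benchmark")
            cov = encode_covariates(clinical).loc[model.labels.index]
            res = run_cv_comparison(
                m_sig,
                cov,
                surv.subset(model.labels.index),
                n_repeats=config.cv_repeats,
                K=model.K,
                seed=config.seed,
            )
            res.cindex.to_csv(_record("cv_cindex.tsv"), sep="\t", index=False)
            res.summary.to_csv(_record("cv_summary.tsv"), sep="\t", index=False)
        elif config.run_cv:
            manifest["skipped"].append("cv (needs clinical and survival tables)")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {current_stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
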