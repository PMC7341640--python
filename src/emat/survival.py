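"""Survival analysis: Kaplan-Meier, log-rank, Cox regression, C-index.

Thin, validated wrappers around lifelines with the covariate encodings
used throughout the analysis: multi-level clinical factors enter Cox
models as ordinal (numeric trend) codes rather than dummy variables, so
each factor contributes a single hazard ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex

logger = logging.getLogger(__name__)

ENDPOINTS = ("DSS", "DMFS", "synthetic")

# Ordinal encodings for multi-level clinical factors.  Each factor enters a
# Cox model as one numeric-trend covariate with a single hazard ratio.
TUMOR_SIZE_CODES = {"<2": 1, "2-5": 2, ">5": 3}
GRADE_CODES = {"low": 1, "intermediate": 2, "high": 3}
IHC_CODES = {"ER+HER2-": 1, "ER+HER2+": 2, "ER-HER2+": 3, "ER-HER2-": 4}
PAM50_CODES = {
    "normal-like": 0,
    "luminal A": 1,
    "luminal B": 2,
    "HER2-enriched": 3,
    "basal-like": 4,
}


@dataclass
class SurvivalTable:
    """Per-sample follow-up time (months), event indicator, endpoint tag."""

    data: pd.DataFrame  # index sample_id, columns: time, event
    endpoint: str = "synthetic"

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {ENDPOINTS}, got {self.endpoint!r}")
        d = self.data
        if not {"time", "event"}.issubset(d.columns):
            raise ValueError("survival table needs 'time' and 'event' columns")
        if d.index.has_duplicates:
            raise ValueError("duplicate sample ids in survival table")
        if (d["time"].to_numpy() < 0).any():
            bad = d.index[d["time"] < 0][0]
            raise ValueError(f"negative follow-up time for sample {bad!r}")
        if not d["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")

    @classmethod
    def from_arrays(cls, sample_ids, time, event, endpoint: str = "synthetic"):
        return cls(
            pd.DataFrame(
                {"time": np.asarray(time, dtype=float), "event": np.asarray(event, dtype=int)},
                index=pd.Index(sample_ids, name="sample_id"),
            ),
            endpoint=endpoint,
        )

    def subset(self, sample_ids) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(sample_ids)], endpoint=self.endpoint)

    @property
    def n(self) -> int:
        return len(self.data)


def truncate_follow_up(surv: SurvivalTable, horizon: float = 120.0) -> SurvivalTable:
    """Administrative censoring at ``horizon`` months (10-year analyses)."""
    d = surv.data.copy()
    beyond = d["time"] > horizon
    d.loc[beyond, "time"] = horizon
    d.loc[beyond, "event"] = 0
    return SurvivalTable(d, endpoint=surv.endpoint)


def kaplan_meier(surv: SurvivalTable) -> pd.DataFrame:
    """Product-limit estimate: rows (time, n_at_risk, n_events, survival)."""
    if surv.n < 1:
        raise ValueError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(surv.data["time"], surv.data["event"])
    et = kmf.event_table.iloc[1:] if 0.0 not in surv.data["time"].values else kmf.event_table
    sf = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": et.index.to_numpy(dtype=float),
            "n_at_risk": et["at_risk"].to_numpy(dtype=int),
            "n_events": et["observed"].to_numpy(dtype=int),
            "survival": sf.reindex(et.index).to_numpy(dtype=float),
        }
    ).reset_index(drop=True)
    return out


def km_survival_at(surv: SurvivalTable, t: float) -> float:
    """Kaplan-Meier survival probability S(t)."""
    kmf = KaplanMeierFitter()
    kmf.fit(surv.data["time"], surv.data["event"])
    return float(kmf.predict(t))


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    df: int
    pairwise: pd.DataFrame | None = None


def logrank_test(
    surv: SurvivalTable, groups: pd.Series, pairwise: bool = False
) -> LogrankResult:
    """Unweighted log-rank test across >= 2 groups (chi-square, groups-1 df).

    With ``pairwise=True`` also returns all two-group comparisons.
    """
    groups = groups.loc[surv.data.index]
    levels = sorted(groups.dropna().unique(), key=str)
    if len(levels) < 2:
        raise ValueError("log-rank test requires at least 2 non-empty groups")
    mask = groups.notna()
    d = surv.data.loc[mask]
    g = groups.loc[mask]
    res = multivariate_logrank_test(d["time"], g, d["event"])
    pw = None
    if pairwise:
        rows = []
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                sel = g.isin([a, b])
                sub = multivariate_logrank_test(
                    d.loc[sel, "time"], g[sel], d.loc[sel, "event"]
                )
                rows.append((a, b, float(sub.test_statistic), float(sub.p_value)))
        pw = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p"])
    return LogrankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        df=len(levels) - 1,
        pairwise=pw,
    )


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary.

    ``summary`` rows are covariates with columns coef, hr, hr_lower,
    hr_upper, p (Wald); ``lrt_p`` is the model likelihood-ratio-test p.
    """

    summary: pd.DataFrame
    lrt_p: float
    n: int
    n_events: int
    model: CoxPHFitter = field(repr=False, default=None)

    def predict_risk(self, covariates: pd.DataFrame) -> pd.Series:
        """Cox linear predictor (log partial hazard); higher = higher risk."""
        lp = self.model.predict_log_partial_hazard(covariates[self.summary.index])
        return pd.Series(np.asarray(lp, dtype=float).ravel(), index=covariates.index)


def cox_fit(covariates: pd.DataFrame, surv: SurvivalTable) -> CoxFit:
    """Multivariable Cox regression with Efron tie handling.

    Rows with any missing covariate are excluded listwise; a warning is
    emitted when complete rows are fewer than 10x the covariate count.
    """
    if covariates.shape[1] < 1:
        raise ValueError("at least one covariate required")
    df = covariates.join(surv.data[["time", "event"]], how="inner").dropna()
    n, p = len(df), covariates.shape[1]
    n_events = int(df["event"].sum())
    if n_events < 1:
        raise ValueError("no events among complete-case rows")
    if n < 10 * p:
        warnings.warn(
            f"only {n} complete rows for {p} covariates (<10 per covariate)",
            UserWarning,
            stacklevel=2,
        )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")  # lifelines default = Efron ties
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "hr_lower": s["exp(coef) lower 95%"],
            "hr_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    summary.index.name = "covariate"
    lrt_p = float(cph.log_likelihood_ratio_test().p_value)
    return CoxFit(summary=summary, lrt_p=lrt_p, n=n, n_events=n_events, model=cph)


def cox_fit_univariable(covariates: pd.DataFrame, surv: SurvivalTable) -> pd.DataFrame:
    """One single-covariate Cox fit per column; rows mirror CoxFit.summary."""
    rows = []
    for col in covariates.columns:
        fit = cox_fit(covariates[[col]], surv)
        row = fit.summary.loc[col]
        rows.append(
            {
                "covariate": col,
                "coef": row["coef"],
                "hr": row["hr"],
                "hr_lower": row["hr_lower"],
                "hr_upper": row["hr_upper"],
                "p": row["p"],
                "n": fit.n,
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


def concordance_index(risk_scores, surv: SurvivalTable) -> float:
    """Harrell's C over admissible pairs; higher risk should mean earlier
    event.  Tied risk scores contribute 0.5."""
    risk = np.asarray(risk_scores, dtype=float)
    if len(risk) != surv.n:
        raise ValueError("risk scores not aligned to survival rows")
    try:
        return float(
            _lifelines_cindex(surv.data["time"], -risk, surv.data["event"])
        )
    except ZeroDivisionError as exc:
        raise ValueError("no admissible pairs for concordance index") from exc


def encode_covariates(clinical: pd.DataFrame) -> pd.DataFrame:
    """Encode a categorical clinical table into numeric Cox covariates.

    Expected columns (those present are encoded, others passed through if
    already numeric): age, tumor_size (<2 / 2-5 / >5), grade
    (low/intermediate/high), er/her2 status (+/-) -> combined ihc code,
    pam50, emat (EMATj names), chemo/hormonal/radiation 0-1 flags.
    Unmappable or missing levels become NaN (excluded listwise by cox_fit).
    """
    out = pd.DataFrame(index=clinical.index)
    if "age" in clinical:
        out["age"] = pd.to_numeric(clinical["age"], errors="coerce")
    if "tumor_size" in clinical:
        out["tumor_size"] = clinical["tumor_size"].map(TUMOR_SIZE_CODES)
    if "grade" in clinical:
        out["grade"] = clinical["grade"].map(GRADE_CODES)
    if "er" in clinical and "her2" in clinical:
        key = "ER" + clinical["er"].astype(str) + "HER2" + clinical["her2"].astype(str)
        out["ihc"] = key.map(IHC_CODES)
    if "pam50" in clinical:
        out["pam50"] = clinical["pam50"].map(PAM50_CODES)
    if "emat" in clinical:
        out["emat"] = (
            clinical["emat"].astype(str).str.extract(r"EMAT(\d+)")[0].astype(float)
        )
    for flag in ("chemo", "hormonal", "radiation"):
        if flag in clinical:
            out[flag] = pd.to_numeric(clinical[flag], errors="coerce")
    return out
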