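"""Survival analysis of predicted diagnosis groups and finding proportions.

Kaplan–Meier product-limit curves compare cases predicted UIP vs non-UIP
(with survival read off at a 5-year horizon, 1826 days); a two-group
log-rank test checks the separation; and a Cox proportional-hazards model
(Efron tie handling, via lifelines) estimates per-finding hazard ratios.
Highly correlated finding frequencies are pruned before the Cox fit: for
each pair with |Pearson r| at or above the threshold (default 0.7) the
member with the larger mean absolute correlation to all remaining
covariates is dropped, iterating until no pair exceeds the threshold.
Subgroup analyses rerun the same model inside pathologist-diagnosed strata.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

logger = logging.getLogger("mixture.survival")

__all__ = ["SurvivalRecord", "CoxResult", "km_estimate", "logrank_test",
           "filter_collinear", "cox_fit", "subgroup_analysis",
           "FIVE_YEARS_DAYS"]

FIVE_YEARS_DAYS = 1826.0


@dataclasses.dataclass
class SurvivalRecord:
    case_id: str
    time: float                  # days, > 0
    event: int                   # 1 death, 0 censored
    group: str | None = None
    covariates: dict | None = None

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError("time must be > 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclasses.dataclass
class CoxResult:
    summary: pd.DataFrame        # per covariate: hazard_ratio, ci, p
    log_likelihood: float
    n: int
    n_events: int

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hazard_ratio"])


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for r in records:
        row = {"case_id": r.case_id, "time": r.time, "event": r.event,
               "group": r.group}
        if r.covariates:
            row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def km_estimate(records, group_by: str = "group",
                horizons=(FIVE_YEARS_DAYS,)) -> dict:
    """Per-group Kaplan–Meier curves plus survival at given horizons.

    Returns ``{group: {"times", "survival", "at_horizon": {h: S(h)}}}``.
    The estimator is the product over event times of (1 - d_i / n_i).
    """
    df = _records_frame(records)
    out = {}
    for grp, sub in df.groupby(group_by, sort=True):
        if len(sub) == 0:
            raise ValueError(f"group {grp!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        out[grp] = {
            "times": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
            "at_horizon": {float(h): float(kmf.predict(h)) for h in horizons},
            "n": int(len(sub)),
            "n_events": int(sub["event"].sum()),
        }
    if not out:
        raise ValueError("no groups found")
    return out


def logrank_test(records, group_by: str = "group"):
    """Two-group log-rank test; returns (chi2 statistic, p-value)."""
    df = _records_frame(records)
    groups = sorted(df[group_by].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {len(groups)}")
    a = df[df[group_by] == groups[0]]
    b = df[df[group_by] == groups[1]]
    if int(df["event"].sum()) < 1:
        raise ValueError("log-rank requires at least one event")
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"],
                      event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def filter_collinear(covariates: pd.DataFrame, r_threshold: float = 0.7):
    """Drop one covariate of each highly correlated pair, iteratively.

    Constant covariates (undefined correlation) are dropped first with a
    warning. At each step the pair with the largest |r| >= threshold is
    found and the member with the larger mean absolute correlation to all
    other retained covariates is removed (ties: the later column). Returns
    ``(retained DataFrame, report DataFrame)`` listing each drop.
    """
    df = covariates.copy()
    report = []
    for col in list(df.columns):
        if df[col].nunique() <= 1:
            logger.warning("covariate %r is constant; dropped", col)
            report.append({"dropped": col, "kept": None, "r": np.nan,
                           "reason": "constant"})
            df = df.drop(columns=[col])
    while df.shape[1] >= 2:
        corr = df.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        absr = np.abs(corr)
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] < r_threshold:
            break
        cols = list(df.columns)
        mean_i = absr[i].mean()
        mean_j = absr[j].mean()
        if mean_i > mean_j:
            drop, keep = i, j
        elif mean_j > mean_i:
            drop, keep = j, i
        else:
            drop, keep = (max(i, j), min(i, j))   # tie: later column order
        report.append({"dropped": cols[drop], "kept": cols[keep],
                       "r": float(corr[i, j]), "reason": "collinear"})
        df = df.drop(columns=[cols[drop]])
    return df, pd.DataFrame(report, columns=["dropped", "kept", "r", "reason"])


def cox_fit(records, covariate_cols=None, penalizer: float = 0.0,
            alpha: float = 0.05) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) with Wald CI and p-values."""
    df = _records_frame(records)
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns
                          if c not in ("case_id", "time", "event", "group")]
    n_events = int(df["event"].sum())
    if n_events < len(covariate_cols):
        raise ValueError(f"{n_events} events < {len(covariate_cols)} covariates")
    data = df[["time", "event", *covariate_cols]].astype(float)
    cph = CoxPHFitter(penalizer=penalizer, alpha=alpha)
    try:
        cph.fit(data, duration_col="time", event_col="event")
    except Exception as exc:       # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame({
        "hazard_ratio": np.exp(s["coef"]),
        "coef": s["coef"],
        "se": s["se(coef)"],
        "ci_lower": np.exp(s["coef lower 95%"]),
        "ci_upper": np.exp(s["coef upper 95%"]),
        "p": s["p"],
    })
    summary.index.name = "covariate"
    return CoxResult(summary=summary,
                     log_likelihood=float(cph.log_likelihood_),
                     n=int(len(data)), n_events=n_events)


def subgroup_analysis(records, subgroup_col: str, covariate_cols=None,
                      penalizer: float = 0.0) -> dict:
    """Independent Cox fit per subgroup with a shared covariate set.

    Subgroups too small to support the model (fewer events than covariates,
    or a failed fit) are skipped with a warning.
    """
    df = _records_frame(records)
    out = {}
    for grp, sub in df.groupby(subgroup_col, sort=True):
        try:
            out[grp] = cox_fit(sub, covariate_cols=covariate_cols,
                               penalizer=penalizer)
        except (ValueError, RuntimeError) as exc:
            logger.warning("subgroup %r skipped: %s", grp, exc)
    return out
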