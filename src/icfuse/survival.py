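"""EFS/OS construction, Kaplan-Meier, log-rank and Cox PH regression.

Event-free survival counts failure to achieve remission as an event at day
0; relapse, secondary malignancy and death are events at their recorded
times. Estimation and inference are delegated to lifelines (Kaplan-Meier
product-limit, multivariate log-rank, Cox partial likelihood with the Efron
tie approximation) behind this module's interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .types import ClinicalRecord, ValidationError

log = logging.getLogger("icfuse")


def efs_from_clinical(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Build (time, event) EFS intervals; induction failure -> event at 0 d."""
    rows = []
    for r in records:
        if r.efs_time_days < 0:
            raise ValidationError(f"{r.case_id}: negative EFS time")
        if r.remission_failure:
            time, event = 0.0, True
        else:
            time, event = float(r.efs_time_days), bool(r.efs_event)
        rows.append({"case_id": r.case_id, "time": time, "event": event,
                     "group": r.cluster_label})
    return pd.DataFrame(rows).set_index("case_id")


def os_from_clinical(records: list[ClinicalRecord]) -> pd.DataFrame:
    rows = [{"case_id": r.case_id, "time": float(r.os_time_days),
             "event": bool(r.os_event), "group": r.cluster_label}
            for r in records]
    return pd.DataFrame(rows).set_index("case_id")


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate with at-risk counts.

    Events and censorings tied at the same time are handled with events
    first (the product-limit convention). Returns one row per distinct
    event/censoring time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValidationError("km_curve requires >= 1 sample")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    # drop the synthetic baseline row (no events, no censorings at t)
    table = table[(table["observed"] + table["censored"]) > 0]
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame({
        "time": table.index.to_numpy(dtype=float),
        "at_risk": table["at_risk"].to_numpy(dtype=int),
        "events": table["observed"].to_numpy(dtype=int),
        "censored": table["censored"].to_numpy(dtype=int),
        "survival": surv.reindex(table.index).to_numpy(dtype=float),
    })
    return out


def logrank_test(times, events, groups) -> dict:
    """K-sample log-rank test (chi-square statistic, df = groups - 1)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValidationError("log-rank requires >= 2 groups")
    if not events.any():
        raise ValidationError("log-rank undefined with no events")
    res = multivariate_logrank_test(times, groups, events)
    return {
        "statistic": float(res.test_statistic),
        "df": int(len(np.unique(groups)) - 1),
        "p": float(res.p_value),
    }


@dataclass
class CoxResult:
    table: pd.DataFrame          # per covariate: coef, HR, CI bounds, p
    converged: bool
    warnings: list[str]

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])


def expand_covariates(df: pd.DataFrame, categorical: dict[str, str] | None = None
                      ) -> pd.DataFrame:
    """Reference-code categorical covariates (reference level per column)."""
    out = df.copy()
    for col, ref in (categorical or {}).items():
        levels = [l for l in pd.unique(out[col]) if l != ref]
        for level in levels:
            out[f"{col}[{level}]"] = (out[col] == level).astype(float)
        out = out.drop(columns=[col])
    return out


def cox_ph_fit(times, events, covariates: pd.DataFrame) -> CoxResult:
    """Cox proportional-hazards fit via partial-likelihood maximization.

    Ties are handled with the Efron approximation. Zero event times are
    kept as the earliest event time (shifted to half the smallest positive
    time, which leaves all risk-set orderings unchanged). Non-convergence
    or separation is flagged in the result rather than raised.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape[0] <= covariates.shape[1]:
        raise ValidationError("need n > number of covariates")
    if not events.any():
        raise ValidationError("Cox model undefined with no events")
    if (times < 0).any():
        raise ValidationError("negative survival time")
    t = times.copy()
    if (t == 0).any():
        positive = t[t > 0]
        eps = positive.min() / 2 if positive.size else 1.0
        t[t == 0] = eps
    # constant covariates leave the partial likelihood flat: report the
    # null effect instead of letting the optimizer choke on them
    constant = [c for c in covariates.columns
                if np.ptp(covariates[c].to_numpy(dtype=float)) == 0]
    covariates = covariates.drop(columns=constant)
    if covariates.shape[1] == 0:
        table = pd.DataFrame(
            {"coef": 0.0, "hr": 1.0, "ci_low": 1.0, "ci_high": 1.0, "p": 1.0},
            index=pd.Index(constant, name="covariate"),
        )
        return CoxResult(table=table, converged=True, warnings=[])
    df = covariates.astype(float).copy()
    df["_time"] = t
    df["_event"] = events.astype(int)
    cph = CoxPHFitter()
    warnings_seen: list[str] = []
    import warnings as _warnings
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="_time", event_col="_event")
        except Exception as exc:  # monotone likelihood / separation
            return CoxResult(table=pd.DataFrame(), converged=False,
                             warnings=[str(exc)])
        warnings_seen = [str(w.message) for w in caught
                         if "convergence" in str(w.message).lower()
                         or "collinear" in str(w.message).lower()]
    summary = cph.summary
    table = pd.DataFrame({
        "coef": summary["coef"],
        "hr": summary["exp(coef)"],
        "ci_low": summary["exp(coef) lower 95%"],
        "ci_high": summary["exp(coef) upper 95%"],
        "p": summary["p"],
    })
    for c in constant:
        table.loc[c] = [0.0, 1.0, 1.0, 1.0, 1.0]
    table.index.name = "covariate"
    return CoxResult(table=table, converged=not warnings_seen,
                     warnings=warnings_seen)
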