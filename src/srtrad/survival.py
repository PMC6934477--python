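"""Kaplan-Meier risk stratification of predicted LC/LF cohorts.

Lesions (local control) or patients (overall survival) are split into
cohort 1 (predicted LC) and cohort 2 (predicted LF); the product-limit
curves of the two cohorts are compared with the one-degree-of-freedom
log-rank test. A patient belongs to the LF cohort as soon as one of their
lesions is predicted LF. Administrative censoring is applied at five
years, matching a long-term follow-up window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

MAX_FOLLOWUP_MONTHS = 60.0


@dataclass
class KMCurve:
    """Product-limit estimate Ŝ(t): steps at event times only."""

    event_times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogrankResult:
    statistic: float
    p_value: float


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Kaplan-Meier estimate; censoring decrements the risk set silently."""
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    observed = table[table["observed"] > 0]
    ts = observed.index.to_numpy(dtype=np.float64)
    at_risk = observed["at_risk"].to_numpy(dtype=np.float64)
    surv = np.array([float(kmf.predict(t)) for t in ts])
    return KMCurve(ts, at_risk, surv)


def logrank_test(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> LogrankResult:
    """Two-group log-rank comparison; undefined without any event."""
    events_a = np.asarray(events_a, dtype=bool)
    events_b = np.asarray(events_b, dtype=bool)
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be nonempty")
    if not events_a.any() and not events_b.any():
        return LogrankResult(np.nan, np.nan)
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return LogrankResult(float(res.test_statistic), float(res.p_value))


def assign_cohorts(predictions: pd.DataFrame, unit: str = "lesion") -> pd.DataFrame:
    """Cohort 1 (predicted LC) vs cohort 2 (predicted LF) per lesion or patient.

    At patient level the OR-rule applies: one predicted-LF lesion puts the
    whole patient in cohort 2.
    """
    required = {"lesion_id", "patient_id", "predicted"}
    if not required.issubset(predictions.columns):
        raise ValueError(f"predictions must contain columns {sorted(required)}")
    if unit == "lesion":
        out = predictions[["lesion_id", "patient_id"]].copy()
        out["cohort"] = np.where(predictions["predicted"] == "LF", 2, 1)
        return out
    if unit == "patient":
        grp = (
            predictions.assign(is_lf=predictions["predicted"] == "LF")
            .groupby("patient_id")["is_lf"]
            .any()
        )
        return pd.DataFrame(
            {"patient_id": grp.index, "cohort": np.where(grp.to_numpy(), 2, 1)}
        )
    raise ValueError("unit must be 'lesion' or 'patient'")


@dataclass
class RiskAssessment:
    unit: str
    curves: dict[int, KMCurve]
    logrank: LogrankResult
    n_per_cohort: dict[int, int]


def risk_assessment(
    predictions: pd.DataFrame,
    times: pd.Series,
    events: pd.Series,
    unit: str = "lesion",
    max_followup: float = MAX_FOLLOWUP_MONTHS,
) -> RiskAssessment:
    """KM curves and log-rank p for the two predicted cohorts.

    ``times``/``events`` are indexed by lesion_id (unit='lesion', clinical
    local control) or patient_id (unit='patient', overall survival).
    Administrative censoring at ``max_followup`` months.
    """
    cohorts = assign_cohorts(predictions, unit)
    key = "lesion_id" if unit == "lesion" else "patient_id"
    cohorts = cohorts.drop_duplicates(subset=key).set_index(key)
    t = times.reindex(cohorts.index).to_numpy(dtype=np.float64)
    e = events.reindex(cohorts.index).to_numpy(dtype=bool)
    if np.isnan(t).any():
        missing = cohorts.index[np.isnan(t)][:3].tolist()
        raise ValueError(f"missing survival records for {missing}")
    e = e & (t <= max_followup)
    t = np.minimum(t, max_followup)
    grp = cohorts["cohort"].to_numpy()
    curves = {}
    n_per = {}
    for c in (1, 2):
        sel = grp == c
        n_per[c] = int(sel.sum())
        if sel.any():
            curves[c] = km_estimate(t[sel], e[sel])
    if n_per[1] == 0 or n_per[2] == 0:
        lr = LogrankResult(np.nan, np.nan)
    else:
        lr = logrank_test(t[grp == 1], e[grp == 1], t[grp == 2], e[grp == 2])
    return RiskAssessment(unit, curves, lr, n_per)


def plot_km(assessment: RiskAssessment, ax=None, title: str | None = None):
    """Step-plot of the two cohort curves (optional SVG export by caller)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c, curve in assessment.curves.items():
        ts = np.concatenate([[0.0], curve.event_times])
        ss = np.concatenate([[1.0], curve.survival])
        label = {1: "Cohort 1 (predicted LC)", 2: "Cohort 2 (predicted LF)"}[c]
        ax.step(ts, ss, where="post", label=label)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if title is None:
        title = f"log-rank p = {assessment.logrank.p_value:.2g}"
    ax.set_title(title)
    return ax
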