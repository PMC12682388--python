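"""Relating TCFA status to 2-year clinical outcome.

Kaplan–Meier curves, the two-group log-rank test and univariable Cox
models (Efron tie handling) are delegated to lifelines; the C-statistic of
a binary exposure for the binary 2-year outcome and its DeLong confidence
interval / paired comparison are implemented here, since DeLong machinery
is not available in the installed stack. For a binary marker the
C-statistic reduces to (sensitivity + specificity)/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import norm

EVENT_TYPES = ("death", "mi", "revascularisation", "none")


@dataclass
class SurvivalRecord:
    """Per-patient follow-up: time, composite-event indicator, exposures."""

    patient_id: str
    time_days: float
    event: bool
    event_type: str = "none"
    exposure_target_lesion: Optional[bool] = None
    exposure_complete_segment: Optional[bool] = None

    def __post_init__(self):
        if self.time_days < 0:
            raise ValueError("time_days must be non-negative")
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")
        if not self.event and self.event_type != "none":
            raise ValueError("censored records must have event_type 'none'")


@dataclass(frozen=True)
class CoxResult:
    hr: float
    ci95: Tuple[float, float]
    p: float
    n_events: int
    log_hr: float
    log_hr_se: float
    converged: bool = True
    message: str = ""


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "time_days": [r.time_days for r in records],
            "event": [bool(r.event) for r in records],
            "event_type": [r.event_type for r in records],
            "exposure_target_lesion": [r.exposure_target_lesion for r in records],
            "exposure_complete_segment": [
                r.exposure_complete_segment for r in records
            ],
        }
    )


def kaplan_meier(
    times: Sequence[float], events: Sequence[bool], label: str = "KM"
) -> pd.DataFrame:
    """Product-limit survival curve as a step-function table (time, S)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events, label=label)
    sf = kmf.survival_function_
    return pd.DataFrame({"time_days": sf.index.values, "survival": sf[label].values})


def logrank(
    times: Sequence[float],
    events: Sequence[bool],
    group: Sequence[bool],
) -> Tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group, dtype=bool)
    if group.all() or not group.any():
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(
        times[group], times[~group], events[group], events[~group]
    )
    return float(res.test_statistic), float(res.p_value)


def cox_univariable(
    times: Sequence[float],
    events: Sequence[bool],
    exposure: Sequence[bool],
) -> CoxResult:
    """Univariable Cox PH fit of a binary exposure (Efron ties, Wald CI)."""
    df = pd.DataFrame(
        {
            "time": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=bool).astype(int),
            "exposure": np.asarray(exposure, dtype=bool).astype(int),
        }
    )
    n_events = int(df["event"].sum())
    if df["exposure"].nunique() < 2:
        raise ValueError("both exposure levels must be present")
    if n_events == 0:
        raise ValueError("no events observed")
    # monotone likelihood: all events in one arm -> the MLE diverges
    ev = df.loc[df["event"] == 1, "exposure"]
    if ev.nunique() < 2:
        return CoxResult(
            hr=np.inf if ev.iloc[0] == 1 else 0.0,
            ci95=(np.nan, np.nan),
            p=np.nan,
            n_events=n_events,
            log_hr=np.inf if ev.iloc[0] == 1 else -np.inf,
            log_hr_se=np.nan,
            converged=False,
            message="monotone partial likelihood: no events in one arm",
        )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["exposure"])
    se = float(cph.standard_errors_["exposure"])
    z = norm.ppf(0.975)
    p = float(2 * norm.sf(abs(beta / se)))
    with np.errstate(over="ignore"):  # near-monotone fits can overflow exp
        return CoxResult(
            hr=float(np.exp(beta)),
            ci95=(float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
            p=p,
            n_events=n_events,
            log_hr=beta,
            log_hr_se=se,
        )


# --------------------------------------------------------------------------
# C-statistic with DeLong machinery
# --------------------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks as used in the fast DeLong computation (Sun & Xu)."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = x.size
    t = np.zeros(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n, dtype=float)
    out[order] = t
    return out


def _delong_components(scores: np.ndarray, outcome: np.ndarray):
    """AUC plus the per-case structural components V10 (cases) / V01 (controls)."""
    pos = scores[outcome]
    neg = scores[~outcome]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")
    allr = _midrank(np.concatenate([pos, neg]))
    rp = _midrank(pos)
    rn = _midrank(neg)
    auc = (allr[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (allr[:m] - rp) / n
    v01 = 1.0 - (allr[m:] - rn) / m
    return auc, v10, v01


def binary_cstat(
    exposure: Sequence[bool], outcome: Sequence[bool], alpha: float = 0.05
) -> Tuple[float, Tuple[float, float]]:
    """C-statistic of a binary marker for a binary outcome, DeLong 95% CI.

    Identical to the Mann–Whitney AUC of the 0/1 exposure, hence to
    (sensitivity + specificity)/2.
    """
    scores = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    auc, v10, v01 = _delong_components(scores, y)
    var = (
        (np.var(v10, ddof=1) / v10.size if v10.size > 1 else 0.0)
        + (np.var(v01, ddof=1) / v01.size if v01.size > 1 else 0.0)
    )
    se = float(np.sqrt(var))
    z = norm.ppf(1 - alpha / 2)
    return float(auc), (float(auc - z * se), float(auc + z * se))


def delong_paired_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    outcome: Sequence[bool],
) -> Tuple[float, float, float]:
    """Paired DeLong z-test for the AUC difference of two markers.

    Both markers must be scored on the same patients in the same order.
    Returns (auc_a - auc_b, z, two-sided p). Identical markers give a
    difference of 0 with p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("markers must cover the identical patient set")
    auc_a, v10a, v01a = _delong_components(a, y)
    auc_b, v10b, v01b = _delong_components(b, y)
    m, n = v10a.size, v01a.size

    def _cov(u, v):
        return np.cov(u, v, ddof=1)[0, 1] if u.size > 1 else 0.0

    var = (
        np.var(v10a, ddof=1) + np.var(v10b, ddof=1) - 2 * _cov(v10a, v10b)
    ) / m + (
        np.var(v01a, ddof=1) + np.var(v01b, ddof=1) - 2 * _cov(v01a, v01b)
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        return float(diff), 0.0, 1.0 if np.isclose(diff, 0) else 0.0
    z = diff / np.sqrt(var)
    return float(diff), float(z), float(2 * norm.sf(abs(z)))


def binary_outcome_at_2y(
    records: Sequence[SurvivalRecord], min_followup_days: float = 700.0
):
    """Dichotomise follow-up for the C-statistic analysis.

    Patients with an event count as outcome-positive; event-free patients
    censored before ``min_followup_days`` have unknown 2-year status and
    are excluded (their ids are returned for the audit trail).
    """
    keep, outcome, dropped = [], [], []
    for r in records:
        if r.event:
            keep.append(r)
            outcome.append(True)
        elif r.time_days >= min_followup_days:
            keep.append(r)
            outcome.append(False)
        else:
            dropped.append(r.patient_id)
    return keep, np.asarray(outcome, dtype=bool), dropped
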