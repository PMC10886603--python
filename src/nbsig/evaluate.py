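"""Survival evaluation of the prognostic score.

Kaplan-Meier product-limit curves, multi-group log-rank tests with the
hypergeometric variance, restricted mean survival time, median-split risk
groups, per-gene KM with z = 0 dichotomisation, and time-dependent ROC/AUC
with cumulative cases / dynamic controls and Kaplan-Meier weighting
(the Heagerty-Lumley-Pepe estimator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import RiskTable


@dataclass
class KMCurve:
    """Product-limit survival estimate: step function over event times."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray
    max_observed_time: float
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.n_events,
            }
        )


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


@dataclass
class ROCResult:
    horizon: float
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr})


def kaplan_meier(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored subjects leave the risk set after their time; S is 1 before the
    first event and right-continuous at event times.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    rt = RiskTable.from_data(time, event)
    factors = 1.0 - rt.n_events / rt.n_at_risk
    survival = np.cumprod(factors)
    return KMCurve(
        times=rt.times,
        survival=survival,
        at_risk=rt.n_at_risk,
        n_events=rt.n_events,
        max_observed_time=float(time.max()),
        n_subjects=time.size,
    )


def survival_at(curve: KMCurve, t: float) -> float:
    """Step-function (right-continuous) evaluation of S(t)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t > curve.max_observed_time:
        warnings.warn(
            f"t={t} beyond the last observed time {curve.max_observed_time}; "
            "returning the last estimate",
            UserWarning,
            stacklevel=2,
        )
    pos = np.searchsorted(curve.times, t, side="right")
    return 1.0 if pos == 0 else float(curve.survival[pos - 1])


def mean_survival(curve: KMCurve, horizon: float = 5.0) -> float:
    """Restricted mean survival time: area under S(t) on [0, horizon]."""
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    knots = np.concatenate([[0.0], curve.times[curve.times < horizon], [horizon]])
    values = np.concatenate([[1.0], curve.survival[curve.times < horizon]])
    widths = np.diff(knots)
    return float(np.sum(values * widths))


def logrank_test(groups: list[tuple]) -> LogRankResult:
    """Multi-group log-rank test (observed minus expected, hypergeometric variance)."""
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {g} is empty")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, g))
    time = np.concatenate(times)
    event = np.concatenate(events)
    label = np.concatenate(labels)
    if (event == 1).sum() < 1:
        raise ValueError("no events in any group")

    k = len(groups)
    etimes = np.unique(time[event == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in etimes:
        at_risk = time >= t
        n_t = at_risk.sum()
        d_t = ((time == t) & (event == 1)).sum()
        n_gt = np.array([np.sum(at_risk & (label == g)) for g in range(k)], dtype=float)
        d_gt = np.array(
            [np.sum((time == t) & (event == 1) & (label == g)) for g in range(k)], dtype=float
        )
        O += d_gt
        E += d_t * n_gt / n_t
        if n_t > 1:
            hyper = d_t * (n_t - d_t) / (n_t - 1.0)
            frac = n_gt / n_t
            V += hyper * (np.diag(frac) - np.outer(frac, frac))

    z = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    if np.allclose(Vsub, 0):
        chi2 = 0.0
    else:
        chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    chi2 = max(chi2, 0.0)
    df = k - 1
    return LogRankResult(chi_square=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df)))


def median_split(scores, training_median: float) -> np.ndarray:
    """Label scores 'high' (> training median) or 'low' (<=, ties to low)."""
    if not np.isfinite(training_median):
        raise ValueError("training_median must be finite")
    scores = np.asarray(scores, dtype=float)
    return np.where(scores > training_median, "high", "low")


def td_roc(scores, time, event, horizon: float) -> ROCResult:
    """Time-dependent ROC at a fixed horizon (cumulative/dynamic, KM-weighted).

    Cases are subjects with events by the horizon; controls are event-free
    beyond it.  Sensitivity and specificity are estimated with the
    Kaplan-Meier plug-in: for cutoff c,

        TPR(c) = [1 - S(t | X > c)] P(X > c) / [1 - S(t)]
        FPR(c) = 1 - S(t | X <= c) P(X <= c) / S(t)

    with each conditional S from the subgroup KM estimate.  AUC by trapezoidal
    integration over the cutoff sweep.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if horizon > time.max() or horizon <= 0:
        raise ValueError("horizon must lie within the observed time range")
    if np.sum((time <= horizon) & (event == 1)) == 0:
        raise ValueError("no events before the horizon")

    s_all = survival_at(kaplan_meier(time, event), horizon)
    if s_all >= 1.0:
        raise ValueError("no events before the horizon")

    def km_at(mask) -> float:
        if not mask.any():
            return 1.0
        return survival_at(kaplan_meier(time[mask], event[mask]), min(horizon, time[mask].max()))

    cutoffs = np.concatenate([[-np.inf], np.unique(scores)])
    tpr = np.empty(cutoffs.size)
    fpr = np.empty(cutoffs.size)
    n = scores.size
    for i, c in enumerate(cutoffs):
        high = scores > c
        p_high = high.mean()
        s_high = km_at(high) if high.any() else 1.0
        s_low = km_at(~high) if (~high).any() else 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            tpr[i] = (1.0 - s_high) * p_high / (1.0 - s_all)
            fpr[i] = 1.0 - s_low * (1.0 - p_high) / s_all
    tpr = np.clip(tpr, 0.0, 1.0)
    fpr = np.clip(fpr, 0.0, 1.0)

    # sweep from the most permissive cutoff (everything high) to the strictest;
    # ties in FPR must keep TPR ascending so the trapezoid junctions are right
    order = np.lexsort((tpr, fpr))
    fx = np.concatenate([[0.0], fpr[order], [1.0]])
    fy = np.concatenate([[0.0], tpr[order], [1.0]])
    auc = float(np.trapezoid(fy, fx))
    return ROCResult(horizon=float(horizon), thresholds=cutoffs, fpr=fpr, tpr=tpr, auc=auc)


def gene_km(expr_z, time, event) -> tuple[KMCurve, KMCurve, LogRankResult]:
    """Per-gene KM analysis with z = 0 dichotomisation (z > 0 high, z <= 0 low)."""
    expr_z = np.asarray(expr_z, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    high = expr_z > 0
    if high.all() or (~high).all():
        raise ValueError("one-sided split: all z-scores on the same side of 0")
    km_low = kaplan_meier(time[~high], event[~high])
    km_high = kaplan_meier(time[high], event[high])
    lr = logrank_test([(time[~high], event[~high]), (time[high], event[high])])
    return km_low, km_high, lr
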