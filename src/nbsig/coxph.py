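"""Univariate Cox proportional-hazards fitting.

A single-covariate Newton-Raphson maximiser of the Cox partial likelihood
with Efron (default) or Breslow handling of tied event times.  The screen
fits thousands of these inside simulation studies, so everything is
vectorised: one O(n log n) sort up front, then O(n) work per Newton step.

The estimate is the log hazard ratio; the standard error comes from the
observed information at the maximum, and the reported p-value is the
two-sided Wald test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: |beta| beyond which the likelihood is treated as monotone (perfect
#: separation); the estimate is capped here and flagged.
BETA_CAP = 50.0


@dataclass
class CoxFit:
    feature: str
    beta: float
    se: float
    hazard_ratio: float
    p_value: float
    n_events: int
    converged: bool
    flagged: bool = False  # monotone likelihood / separation

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "beta": self.beta,
            "se": self.se,
            "hazard_ratio": self.hazard_ratio,
            "p_value": self.p_value,
            "n_events": self.n_events,
            "converged": self.converged,
            "flagged": self.flagged,
        }


class _PartialLikelihood:
    """Pre-indexed Efron/Breslow partial likelihood for one covariate."""

    def __init__(self, x, time, event, ties: str = "efron"):
        x = np.asarray(x, dtype=float)
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        # sort descending by time so risk sets are prefixes
        order = np.argsort(-time, kind="stable")
        self.x = x[order]
        self.time = time[order]
        self.event = event[order]
        self.n = x.size

        etimes, inv = np.unique(-self.time[self.event == 1], return_inverse=True)
        # etimes ascending in -time == descending event times; group id per event
        self.n_groups = etimes.size
        self.event_pos = np.flatnonzero(self.event == 1)
        self.group_of_event = inv
        self.d = np.bincount(inv, minlength=self.n_groups).astype(float)
        # risk-set size for each group: count of time >= t_j
        tj = -etimes
        self.m = np.searchsorted(-self.time, -tj, side="right")
        # per-(group, l) expansion for Efron: group index and fraction l/d
        reps = self.d.astype(int)
        self.gl_group = np.repeat(np.arange(self.n_groups), reps)
        if ties == "efron":
            self.gl_frac = np.concatenate([np.arange(k) / k for k in reps]) if reps.size else np.array([])
        else:
            self.gl_frac = np.zeros(int(reps.sum()))
        self.sum_x_events = np.bincount(inv, weights=self.x[self.event_pos], minlength=self.n_groups)

    def loglik_grad_info(self, beta: float) -> tuple[float, float, float]:
        z = beta * self.x
        z = np.clip(z, -700, 700)
        w = np.exp(z)
        wx = w * self.x
        wx2 = wx * self.x
        cw, cwx, cwx2 = np.cumsum(w), np.cumsum(wx), np.cumsum(wx2)
        S0 = cw[self.m - 1]
        S1 = cwx[self.m - 1]
        S2 = cwx2[self.m - 1]
        we = w[self.event_pos]
        s0D = np.bincount(self.group_of_event, weights=we, minlength=self.n_groups)
        s1D = np.bincount(self.group_of_event, weights=we * self.x[self.event_pos], minlength=self.n_groups)
        s2D = np.bincount(
            self.group_of_event, weights=we * self.x[self.event_pos] ** 2, minlength=self.n_groups
        )
        g, f = self.gl_group, self.gl_frac
        phi0 = S0[g] - f * s0D[g]
        phi1 = S1[g] - f * s1D[g]
        phi2 = S2[g] - f * s2D[g]
        loglik = float(beta * self.sum_x_events.sum() - np.sum(np.log(phi0)))
        ratio1 = phi1 / phi0
        grad = float(self.sum_x_events.sum() - np.sum(ratio1))
        info = float(np.sum(phi2 / phi0 - ratio1**2))
        return loglik, grad, info


def cox_univariate(
    x,
    time,
    event,
    feature: str = "x",
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 60,
) -> CoxFit:
    """Fit a univariate Cox model, returning the log hazard ratio and Wald p.

    Raises for a constant covariate or fewer than two events.  A monotone
    likelihood (perfect separation) is flagged and the estimate capped.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if x.shape != time.shape or x.shape != event.shape:
        raise ValueError("x, time, event must have identical shapes")
    n_events = int((event == 1).sum())
    if n_events < 2:
        raise ValueError(f"need >=2 events, got {n_events}")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    if np.any(time < 0):
        raise ValueError("negative survival times")

    pl = _PartialLikelihood(x, time, event, ties=ties)
    beta = 0.0
    loglik, grad, info = pl.loglik_grad_info(beta)
    converged = False
    flagged = False
    for _ in range(max_iter):
        if info <= 0:
            flagged = True
            break
        step = grad / info
        # step-halving to keep the likelihood non-decreasing
        new_beta = beta + step
        for _ in range(30):
            new_ll, new_grad, new_info = pl.loglik_grad_info(new_beta)
            if new_ll >= loglik - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        delta = new_beta - beta
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        if abs(beta) > BETA_CAP:
            flagged = True
            break
        if abs(delta) < tol:
            converged = True
            break

    if flagged:
        beta = float(np.clip(beta, -BETA_CAP, BETA_CAP))
        warnings.warn(
            f"monotone partial likelihood for {feature!r}; beta capped at +/-{BETA_CAP}",
            UserWarning,
            stacklevel=2,
        )
        _, _, info = pl.loglik_grad_info(beta)

    se = float(1.0 / np.sqrt(info)) if info > 0 else np.inf
    zstat = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(zstat)))
    return CoxFit(
        feature=feature,
        beta=float(beta),
        se=se,
        hazard_ratio=float(np.exp(beta)),
        p_value=p,
        n_events=n_events,
        converged=converged,
        flagged=flagged,
    )


def cox_partial_loglik(beta: float, x, time, event, ties: str = "efron") -> float:
    """Partial log-likelihood at a given beta (exposed for oracle checks)."""
    pl = _PartialLikelihood(x, time, event, ties=ties)
    return pl.loglik_grad_info(float(beta))[0]
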