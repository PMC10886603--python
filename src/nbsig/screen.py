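"""Univariate EFS screening with Bonferroni family-wise control.

Each candidate feature (gene z-scores or clinical covariates) is fitted in a
univariate Cox model against event-free survival; features with a Wald
p-value below alpha/m (strict) are selected.  The screen is exposed both as
plain functions and as the :class:`UnivariateCoxScreen` estimator, which
plugs into sklearn pipelines as a feature selector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .coxph import CoxFit, cox_univariate


@dataclass
class ScreenResult:
    fits: list[CoxFit]
    alpha: float

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not self.fits:
            raise ValueError("no fits to select from")

    @property
    def m(self) -> int:
        return len(self.fits)

    @property
    def threshold(self) -> float:
        return self.alpha / self.m

    @property
    def selected(self) -> list[str]:
        return [f.feature for f in self.fits if f.p_value < self.threshold]

    def to_frame(self) -> pd.DataFrame:
        rows = [f.to_dict() for f in self.fits]
        df = pd.DataFrame(rows)
        df["selected"] = df["p_value"] < self.threshold
        return df[["feature", "beta", "se", "hazard_ratio", "p_value", "selected"]]


def bonferroni_select(fits: list[CoxFit], alpha: float = 0.05) -> ScreenResult:
    """Select features with Wald p < alpha / m (strict inequality)."""
    return ScreenResult(fits=list(fits), alpha=alpha)


def bonferroni_threshold(alpha: float, m: int, digits: int | None = None) -> float:
    """The Bonferroni per-test threshold alpha/m, optionally rounded as printed."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    t = alpha / m
    return round(t, digits) if digits is not None else t


def screen_features(
    features: pd.DataFrame,
    time,
    event,
    alpha: float = 0.05,
    ties: str = "efron",
) -> ScreenResult:
    """Univariate Cox screen over the columns of a samples x features frame."""
    fits = [
        cox_univariate(features[col].to_numpy(dtype=float), time, event, feature=col, ties=ties)
        for col in features.columns
    ]
    return bonferroni_select(fits, alpha=alpha)


class UnivariateCoxScreen(BaseEstimator, TransformerMixin):
    """Feature selector: keep features univariately predictive of survival.

    Parameters
    ----------
    alpha : float
        Family-wise significance level; the per-feature threshold is
        ``alpha / n_features`` (Bonferroni).
    ties : str
        'efron' (default) or 'breslow' tied-event handling.

    Attributes
    ----------
    fits_ : list of CoxFit
    results_ : DataFrame with per-feature beta, se, HR, p and selection flag
    threshold_ : float, the Bonferroni per-test threshold
    selected_ : list of selected feature names
    """

    def __init__(self, alpha: float = 0.05, ties: str = "efron"):
        self.alpha = alpha
        self.ties = ties

    def fit(self, X: pd.DataFrame, y):
        time, event = _unpack_survival(y)
        X = _as_frame(X)
        result = screen_features(X, time, event, alpha=self.alpha, ties=self.ties)
        self.fits_ = result.fits
        self.results_ = result.to_frame()
        self.threshold_ = result.threshold
        self.selected_ = result.selected
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self) -> np.ndarray:
        return np.asarray([f in set(self.selected_) for f in self.feature_names_in_])

    def transform(self, X) -> pd.DataFrame:
        X = _as_frame(X)
        missing = [f for f in self.selected_ if f not in X.columns]
        if missing:
            raise ValueError(f"features absent from X: {missing}")
        return X[self.selected_]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def _unpack_survival(y) -> tuple[np.ndarray, np.ndarray]:
    """Accept (time, event) tuples, 2-column arrays, or sksurv structured y."""
    if isinstance(y, tuple) and len(y) == 2:
        return np.asarray(y[0], float), np.asarray(y[1], int)
    y = np.asarray(y)
    if y.dtype.names:  # structured array, sksurv convention: (event, time)
        names = y.dtype.names
        event_name = names[0]
        time_name = names[1]
        return y[time_name].astype(float), y[event_name].astype(int)
    if y.ndim == 2 and y.shape[1] == 2:
        return y[:, 0].astype(float), y[:, 1].astype(int)
    raise ValueError("y must be (time, event), a 2-column array, or a structured array")
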