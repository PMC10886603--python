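"""Core data containers shared across the pipeline.

Expression data lives in a genes x samples :class:`pandas.DataFrame`; the thin
:class:`ExpressionMatrix` wrapper only adds the ``scaled`` flag (has every gene
row been z-transformed?) and light invariant checks.  Clinical tables are plain
DataFrames with a fixed column schema (see :data:`CLINICAL_COLUMNS`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Required clinical columns.  ``histology`` may be missing per sample;
#: the four prognostic fields must be present for a sample to enter a model.
CLINICAL_COLUMNS = [
    "sample_id",
    "efs_time_years",
    "efs_event",
    "age_months",
    "mycn_amplified",
    "inss_stage",
    "histology",
]

#: The four fields a sample must have to be retained (completeness filter).
REQUIRED_CLINICAL_FIELDS = [
    "efs_time_years",
    "efs_event",
    "age_months",
    "mycn_amplified",
    "inss_stage",
]

INSS_STAGES = ["1", "2", "3", "4", "4S"]

#: Ordered risk coding for INSS; 4S sits between stage 1 and stage 2
#: (metastatic infant pattern with favourable outcome).
INSS_ORDERED_CODE = {"1": 0, "4S": 1, "2": 2, "3": 3, "4": 4}


class DegenerateCohortWarning(UserWarning):
    """Raised when a cohort carries no usable survival signal (e.g. no events)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued expression with an explicit scaling flag."""

    values: pd.DataFrame
    scaled: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), scaled=self.scaled)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path, scaled: bool = False) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="gene"), scaled=scaled)


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check the clinical-table schema; returns the frame unchanged."""
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns and c != "histology"]
    if missing:
        raise ValueError(f"clinical table missing required columns: {missing}")
    if clinical["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in clinical table")
    times = clinical["efs_time_years"].dropna()
    if (times <= 0).any():
        raise ValueError("efs_time_years must be positive")
    events = clinical["efs_event"].dropna()
    if not set(np.unique(events)).issubset({0, 1, 0.0, 1.0}):
        raise ValueError("efs_event must be 0/1")
    return clinical


def as_time_event(clinical: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Extract (time, event) arrays from a clinical table."""
    return (
        clinical["efs_time_years"].to_numpy(dtype=float),
        clinical["efs_event"].to_numpy(dtype=int),
    )


def check_events(event: np.ndarray, minimum: int = 1) -> int:
    """Return the event count, warning if the cohort is degenerate."""
    n_events = int(np.sum(np.asarray(event) == 1))
    if n_events < minimum:
        warnings.warn(
            f"cohort has {n_events} events (< {minimum}); survival analyses are degenerate",
            DegenerateCohortWarning,
            stacklevel=2,
        )
    return n_events


@dataclass
class RiskTable:
    """Distinct event times with at-risk and event counts (the KM/log-rank backbone)."""

    times: np.ndarray          # distinct event times, ascending
    n_at_risk: np.ndarray      # subjects with observed time >= times[k]
    n_events: np.ndarray       # events exactly at times[k]

    @classmethod
    def from_data(cls, time, event) -> "RiskTable":
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if time.size == 0:
            raise ValueError("empty sample")
        if np.any(time < 0):
            raise ValueError("negative survival times")
        etimes = np.unique(time[event == 1])
        # at-risk: observed time >= t (censored subjects leave after their time)
        order = np.sort(time)
        n = time.size
        n_at_risk = n - np.searchsorted(order, etimes, side="left")
        n_events = np.array([np.sum((time == t) & (event == 1)) for t in etimes])
        return cls(etimes, n_at_risk.astype(int), n_events.astype(int))
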