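"""Cohort pre-processing: completeness filtering, cleaning, z-scaling,
gene-list intersection, EFS capping, and collinearity checks.

All operations are pure: they return new objects and log what they removed.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, REQUIRED_CLINICAL_FIELDS

logger = logging.getLogger(__name__)


def filter_complete_samples(clinical: pd.DataFrame) -> pd.DataFrame:
    """Retain samples with all four prognostic fields present.

    The fields are EFS time/event, age at diagnosis, MYCN amplification and
    INSS stage; histology may be missing.  Counts removed per field are
    logged; an empty result is a warning, not an error.
    """
    mask = pd.Series(True, index=clinical.index)
    for col in REQUIRED_CLINICAL_FIELDS:
        missing = clinical[col].isna()
        if missing.any():
            logger.info("filter_complete_samples: %d samples missing %s", int(missing.sum()), col)
        mask &= ~missing
    out = clinical.loc[mask].reset_index(drop=True)
    if out.empty:
        warnings.warn("no samples with complete prognostic fields", UserWarning, stacklevel=2)
    return out


def clean_and_scale(
    expr: ExpressionMatrix,
    population_sd: bool = True,
) -> ExpressionMatrix:
    """Drop unusable genes, average duplicate gene rows, then z-scale per gene.

    Genes with any missing or non-finite value are dropped; duplicate gene ids
    (multiple probes/isoforms) are collapsed to the per-sample arithmetic mean
    *before* scaling; zero-variance genes cannot be z-scored and are dropped
    with a log entry.  Input already flagged ``scaled`` passes through
    untouched (the operation is idempotent).
    """
    if expr.scaled:
        return expr.copy()
    values = expr.values

    finite = np.isfinite(values.to_numpy(dtype=float)).all(axis=1) & values.notna().all(axis=1).to_numpy()
    n_bad = int((~finite).sum())
    if n_bad:
        logger.info("clean_and_scale: dropped %d genes with missing/non-finite values", n_bad)
    values = values.loc[finite]

    if values.index.has_duplicates:
        n_dup = int(values.index.duplicated().sum())
        logger.info("clean_and_scale: averaged %d duplicate gene rows", n_dup)
        values = values.groupby(level=0, sort=False).mean()

    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0 if population_sd else 1, keepdims=True)
    nonzero = sd[:, 0] > 0
    if (~nonzero).any():
        logger.info("clean_and_scale: dropped %d zero-variance genes", int((~nonzero).sum()))
    z = (arr[nonzero] - mean[nonzero]) / sd[nonzero]
    return ExpressionMatrix(
        pd.DataFrame(z, index=values.index[nonzero], columns=values.columns), scaled=True
    )


def cap_efs(clinical: pd.DataFrame, horizon: float = 5.0) -> pd.DataFrame:
    """Administratively censor EFS at a fixed horizon.

    Samples followed beyond the horizon are censored at the horizon (events
    after it cannot be observed under a fixed-horizon EFS definition); nothing
    else changes.  Never increases a time and never converts censoring into an
    event.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if (clinical["efs_time_years"].dropna() <= 0).any():
        raise ValueError("non-positive efs_time_years")
    out = clinical.copy()
    over = out["efs_time_years"] > horizon
    out.loc[over, "efs_time_years"] = horizon
    out.loc[over, "efs_event"] = 0
    return out


def intersect_gene_lists(gene_lists: list) -> list[str]:
    """Alphabetically ordered intersection of two or more gene sets."""
    if len(gene_lists) < 2:
        raise ValueError("need at least two gene lists")
    common = set(gene_lists[0])
    for lst in gene_lists[1:]:
        common &= set(lst)
    return sorted(common)


def check_collinearity(
    expr: ExpressionMatrix, genes: list[str], r_max: float = 0.9
) -> pd.DataFrame:
    """Report gene pairs with absolute Pearson correlation >= ``r_max``.

    An empty report means the multicollinearity criterion passes.  A
    zero-variance gene should have been dropped upstream and raises.
    """
    genes = sorted(set(genes))
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    sub = expr.values.loc[genes]
    if sub.shape[1] < 3:
        raise ValueError("need at least three samples")
    arr = sub.to_numpy(dtype=float)
    if np.any(arr.std(axis=1) == 0):
        bad = [g for g, s in zip(genes, arr.std(axis=1)) if s == 0]
        raise ValueError(f"zero-variance genes: {bad}")
    corr = np.corrcoef(arr)
    rows = []
    for i, j in itertools.combinations(range(len(genes)), 2):
        if abs(corr[i, j]) >= r_max:
            rows.append({"gene_a": genes[i], "gene_b": genes[j], "r": corr[i, j]})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])
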