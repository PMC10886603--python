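"""Association of the prognostic score with stratifying markers.

Markers: MYCN amplification, diagnosis before 18 months, tumour histology,
and the NTRK1-PTPN6-TP53 module-activation classifier (a sample is *active*
when its TP53 and PTPN6 z-scores are negative and its NTRK1 z-score is
positive — strict inequalities, so boundary zeros are inactive).  Group
scores are compared with the two-sided Mann-Whitney U test: exact when the
combined sample is small and tie-free, otherwise the normal approximation
with tie and continuity corrections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Combined sample size at or below which the exact MWU distribution is used
#: (provided there are no ties).
EXACT_MWU_MAX_N = 20

MODULE_GENES = ("TP53", "PTPN6", "NTRK1")


@dataclass(frozen=True)
class ModuleStatus:
    tp53_z: float
    ptpn6_z: float
    ntrk1_z: float

    @property
    def active(self) -> bool:
        return self.tp53_z < 0 and self.ptpn6_z < 0 and self.ntrk1_z > 0


@dataclass
class MWUResult:
    u_statistic: float
    p_value: float
    group_means: tuple[float, float]  # (group a / stratum False, group b / stratum True)


def classify_module(tp53_z: float, ptpn6_z: float, ntrk1_z: float) -> ModuleStatus:
    """Classify one sample's module activation from the three gene z-scores."""
    for name, v in (("TP53", tp53_z), ("PTPN6", ptpn6_z), ("NTRK1", ntrk1_z)):
        if not np.isfinite(v):
            raise ValueError(f"non-finite z-score for {name}")
    return ModuleStatus(tp53_z=float(tp53_z), ptpn6_z=float(ptpn6_z), ntrk1_z=float(ntrk1_z))


def classify_module_samples(expr_z: ExpressionMatrix) -> pd.Series:
    """Module-activation flags for every sample of a z-scaled expression matrix.

    Samples missing any of TP53/PTPN6/NTRK1 (non-finite values) are excluded
    with a log entry; if a required gene is absent cohort-wide the active
    class is empty and every sample is excluded.
    """
    values = expr_z.values
    missing_genes = [g for g in MODULE_GENES if g not in values.index]
    if missing_genes:
        logger.info("classify_module_samples: genes absent cohort-wide: %s", missing_genes)
        return pd.Series(dtype=bool)
    sub = values.loc[list(MODULE_GENES)]
    finite = np.isfinite(sub.to_numpy()).all(axis=0)
    n_excluded = int((~finite).sum())
    if n_excluded:
        logger.info("classify_module_samples: excluded %d samples with missing z-scores", n_excluded)
    sub = sub.loc[:, finite]
    active = (sub.loc["TP53"] < 0) & (sub.loc["PTPN6"] < 0) & (sub.loc["NTRK1"] > 0)
    return active.astype(bool)


def mann_whitney(a, b) -> MWUResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    Exact null distribution when the combined sample size is at most
    ``EXACT_MWU_MAX_N`` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  The reported U is the
    statistic of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if np.ptp(combined) == 0:
        # all values identical: no evidence either way
        return MWUResult(
            u_statistic=float(a.size * b.size / 2.0),
            p_value=1.0,
            group_means=(float(a.mean()), float(b.mean())),
        )
    method = "exact" if (combined.size <= EXACT_MWU_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return MWUResult(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        group_means=(float(a.mean()), float(b.mean())),
    )


def stratified_comparison(scores, stratum) -> MWUResult:
    """Compare prognostic scores across a boolean stratum (False vs True)."""
    scores = np.asarray(scores, dtype=float)
    stratum = np.asarray(stratum, dtype=bool)
    if scores.shape != stratum.shape:
        raise ValueError("scores and stratum must align")
    if stratum.all() or (~stratum).all():
        raise ValueError("single-stratum input: both strata must be non-empty")
    return mann_whitney(scores[~stratum], scores[stratum])


def stratify_table(
    scores: pd.Series, markers: pd.DataFrame
) -> pd.DataFrame:
    """Run stratified comparisons for each boolean marker column.

    Returns a frame with marker, group0_mean, group1_mean, u_statistic,
    p_value.  Samples with a missing marker value are dropped per marker.
    """
    rows = []
    for marker in markers.columns:
        col = markers[marker]
        ok = col.notna()
        if ok.sum() == 0:
            continue
        strat = col[ok].astype(bool).to_numpy()
        sc = scores[ok].to_numpy(dtype=float)
        if strat.all() or (~strat).all():
            logger.info("stratify_table: marker %s has a single stratum; skipped", marker)
            continue
        res = stratified_comparison(sc, strat)
        rows.append(
            {
                "marker": marker,
                "group0_mean": res.group_means[0],
                "group1_mean": res.group_means[1],
                "u_statistic": res.u_statistic,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows, columns=["marker", "group0_mean", "group1_mean", "u_statistic", "p_value"])
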