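"""Relative qPCR quantification by the 2^-ddCT method.

Per replicate, dCT = target CT minus the arithmetic mean of the reference-gene
CTs (dual references, e.g. beta-actin and HPRT, combined by mean CT — the
standard multi-reference convention, equivalent to geometric-mean
normalisation of expression).  ddCT = dCT(test) - dCT(control), matched by
replicate; the fold change is 2^-ddCT, summarised over replicates by the
arithmetic mean (geometric optional).  Significance is a two-sided paired
t-test on the replicate dCT values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class FoldChange:
    gene: str
    value: float
    replicate_values: list[float]
    p_value: float
    n_replicates: int


def _ref_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("ct_ref")]
    if not cols:
        raise ValueError("need at least one reference-gene column (ct_ref1, ct_ref2, ...)")
    return cols


def _delta_ct(df: pd.DataFrame) -> pd.Series:
    """Per-row dCT = ct_target - mean(reference CTs); NaN-refs drop the row."""
    refs = df[_ref_columns(df)]
    complete = refs.notna().all(axis=1) & df["ct_target"].notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("delta_delta_ct: excluded %d replicates with missing CT values", n_dropped)
    dct = df.loc[complete, "ct_target"] - refs.loc[complete].mean(axis=1)
    dct.index = df.loc[complete, "replicate"]
    return dct


def delta_delta_ct(
    test: pd.DataFrame,
    control: pd.DataFrame,
    gene: str | None = None,
    summary: str = "arithmetic",
) -> FoldChange:
    """Relative expression of the test condition versus control for one gene.

    ``test`` and ``control`` are long-format CT tables for one gene with
    columns replicate, ct_target, ct_ref1[, ct_ref2, ...]; replicates are
    matched by their ``replicate`` label.  Replicates missing a reference CT
    are excluded (logged); no complete matched replicate is an error.
    """
    if summary not in ("arithmetic", "geometric"):
        raise ValueError("summary must be 'arithmetic' or 'geometric'")
    gene = gene or (test["gene"].iloc[0] if "gene" in test.columns else "gene")
    dct_test = _delta_ct(test)
    dct_ctrl = _delta_ct(control)
    common = dct_test.index.intersection(dct_ctrl.index)
    if len(common) == 0:
        raise ValueError(f"{gene}: no complete matched replicates")
    ddct = dct_test.loc[common].to_numpy() - dct_ctrl.loc[common].to_numpy()
    fold = 2.0 ** (-ddct)
    value = float(fold.mean()) if summary == "arithmetic" else float(stats.gmean(fold))
    p = paired_significance(dct_test.loc[common].to_numpy(), dct_ctrl.loc[common].to_numpy())
    return FoldChange(
        gene=str(gene),
        value=value,
        replicate_values=[float(f) for f in fold],
        p_value=p,
        n_replicates=len(common),
    )


def paired_significance(replicate_dcts_test, replicate_dcts_control) -> float:
    """Two-sided paired t-test on per-replicate dCT values.

    Degenerate zero-variance differences are flagged: all-zero differences
    report p = 1; a constant non-zero difference reports the smallest positive
    float (the evidence is a point mass), both with a warning.
    """
    a = np.asarray(replicate_dcts_test, dtype=float)
    b = np.asarray(replicate_dcts_control, dtype=float)
    if a.shape != b.shape:
        raise ValueError("unpaired replicate vectors")
    if a.size < 2:
        raise ValueError("need >=2 paired replicates")
    diff = a - b
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            warnings.warn("zero-variance, zero-mean differences: p reported as 1", UserWarning, stacklevel=2)
            return 1.0
        warnings.warn(
            "zero-variance non-zero differences: t undefined, p reported as the "
            "smallest positive float",
            UserWarning,
            stacklevel=2,
        )
        return float(np.finfo(float).tiny)
    res = stats.ttest_rel(a, b)
    return float(res.pvalue)


def analyze_ct_table(
    ct_table: pd.DataFrame,
    test_condition: str,
    control_condition: str,
    summary: str = "arithmetic",
) -> pd.DataFrame:
    """Per-gene fold changes and paired p-values from a long-format CT table.

    Expected columns: gene, condition, replicate, ct_target, ct_ref1[, ...].
    Returns a frame with gene, fold_change, p_value, n_replicates.
    """
    required = {"gene", "condition", "replicate", "ct_target"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"CT table needs columns {sorted(required)}")
    rows = []
    for gene, sub in ct_table.groupby("gene", sort=True):
        test = sub[sub["condition"] == test_condition]
        control = sub[sub["condition"] == control_condition]
        if test.empty or control.empty:
            logger.info("analyze_ct_table: %s missing a condition; skipped", gene)
            continue
        fc = delta_delta_ct(test, control, gene=str(gene), summary=summary)
        rows.append(
            {
                "gene": fc.gene,
                "fold_change": fc.value,
                "p_value": fc.p_value,
                "n_replicates": fc.n_replicates,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "fold_change", "p_value", "n_replicates"])
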