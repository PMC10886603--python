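"""Differential expression calling and the cross-condition filtering algebra.

The scientific contribution here is the *filtering algebra*, not the callers:
genes responding uniquely to activation of the NTRK1-PTPN6-TP53 module are
isolated by (1) calling DEGs for the module-carrying line against the parental
line at each temperature, (2) removing genes that merely respond to tsp53
itself — unless the direction flips or the magnitude differs by more than a
ratio (default 3x on the log1.5 scale), (3) keeping only genes exclusive to
the permissive 32 °C condition, and (4) taking the union over callers with
per-gene provenance.

Fold changes are stored canonically in log base 1.5 (a value of 1.0 means a
1.5-fold change); helpers convert to/from log2.

Callers are pluggable.  Two internal callers ship with the package:

``moderated_t``
    Two-sample test on log2 library-size-normalised counts with limma-style
    empirical-Bayes shrinkage of the per-gene variances.
``welch_t``
    Plain per-gene Welch t-test on the same transformed values.

Externally produced DEG tables can be loaded from CSV via
:func:`DEGTable.from_csv` and slotted into the same algebra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .simulate import CountMatrix

logger = logging.getLogger(__name__)

LOG1P5 = np.log(1.5)


def log2_to_log1p5(logfc2: float | np.ndarray) -> float | np.ndarray:
    """Convert a log2 fold change to log base 1.5."""
    return logfc2 * (np.log(2.0) / LOG1P5)


def log1p5_to_log2(logfc: float | np.ndarray) -> float | np.ndarray:
    return logfc * (LOG1P5 / np.log(2.0))


@dataclass(frozen=True)
class Contrast:
    group_a: str
    group_b: str
    temperature: str

    def __post_init__(self):
        if self.group_a == self.group_b:
            raise ValueError("contrast conditions must be distinct")


@dataclass
class DEGTable:
    """Significant genes from one contrast by one caller.

    ``table`` has columns gene, logfc_base1p5, p_adj, caller and contains only
    the genes passing the caller's FDR and fold-change thresholds.
    """

    contrast: Contrast
    table: pd.DataFrame

    def __post_init__(self):
        required = {"gene", "logfc_base1p5", "p_adj", "caller"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"DEG table needs columns {sorted(required)}")
        if self.table.duplicated(["gene", "caller"]).any():
            raise ValueError("one record per gene per caller")
        bad = ~self.table["p_adj"].between(0, 1)
        if bad.any():
            raise ValueError("p_adj outside [0, 1]")
        if not np.isfinite(self.table["logfc_base1p5"]).all():
            raise ValueError("non-finite log fold change")

    @property
    def genes(self) -> set[str]:
        return set(self.table["gene"])

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, genes) -> "DEGTable":
        keep = self.table["gene"].isin(set(genes))
        return DEGTable(self.contrast, self.table.loc[keep].reset_index(drop=True))

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["contrast"] = f"{self.contrast.group_a}_vs_{self.contrast.group_b}_{self.contrast.temperature}"
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, contrast: Contrast) -> "DEGTable":
        df = pd.read_csv(path)
        cols = [c for c in ["gene", "logfc_base1p5", "p_adj", "caller"] if c in df.columns]
        return cls(contrast, df[cols])


def _normalise_log2(counts: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """Library-size normalisation then log2.  Columns are scaled to the mean depth."""
    libsize = counts.sum(axis=0).astype(float)
    if np.any(libsize == 0):
        raise ValueError("sample with zero total counts")
    sf = libsize / libsize.mean()
    return np.log2(counts / sf[None, :] + pseudocount)


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (limma's approach)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(np.abs(dif / y)) < 1e-8:
            break
    return y


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to the per-gene variances (eBayes).

    Returns (d0, s0_sq): the prior degrees of freedom (may be inf) and the
    prior variance.
    """
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * float(_trigamma_inverse(np.array([e_var]))[0])
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _moderated_t(y_a: np.ndarray, y_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene moderated t statistics and p-values (log-scale input)."""
    na, nb = y_a.shape[1], y_b.shape[1]
    mean_a, mean_b = y_a.mean(axis=1), y_b.mean(axis=1)
    ss = ((y_a - mean_a[:, None]) ** 2).sum(axis=1) + ((y_b - mean_b[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    s2 = ss / df
    d0, s0_sq = _fit_f_dist(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    t = (mean_a - mean_b) / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p


def _welch_t(y_a: np.ndarray, y_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    res = stats.ttest_ind(y_a, y_b, axis=1, equal_var=False)
    return res.statistic, res.pvalue


_CALLERS = {"moderated_t": _moderated_t, "welch_t": _welch_t}


def available_callers() -> list[str]:
    return sorted(_CALLERS)


def register_caller(name: str, func) -> None:
    """Plug in a caller: func(log2_a, log2_b) -> (stat, pvalue) per gene."""
    _CALLERS[name] = func


def call_degs(
    counts: CountMatrix,
    group_a: str,
    group_b: str,
    temperature: str,
    alpha_fdr: float = 0.05,
    min_fc: float = 1.5,
    caller: str = "moderated_t",
) -> DEGTable:
    """Call DEGs for ``group_a`` vs ``group_b`` at one temperature.

    Returns only genes with BH-adjusted p < ``alpha_fdr`` and absolute fold
    change >= ``min_fc``; log fold changes are reported in log base 1.5.
    All-zero gene rows are dropped (count logged).
    """
    if not (0 < alpha_fdr < 1):
        raise ValueError("alpha_fdr must be in (0, 1)")
    if min_fc <= 1:
        raise ValueError("min_fc must be > 1")
    if caller not in _CALLERS:
        raise ValueError(f"unknown caller {caller!r}; available: {available_callers()}")

    cols_a = counts.samples_for(group_a, temperature)
    cols_b = counts.samples_for(group_b, temperature)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs >=2 replicates")

    sub = counts.counts[cols_a + cols_b]
    nonzero = sub.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("call_degs: dropped %d all-zero gene rows", n_dropped)
    sub = sub.loc[nonzero]

    y = _normalise_log2(sub.to_numpy(dtype=float))
    y_a, y_b = y[:, : len(cols_a)], y[:, len(cols_a) :]
    _, p = _CALLERS[caller](y_a, y_b)
    p = np.nan_to_num(p, nan=1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    logfc = log2_to_log1p5(y_a.mean(axis=1) - y_b.mean(axis=1))

    min_abs_logfc = np.log(min_fc) / LOG1P5
    keep = (p_adj < alpha_fdr) & (np.abs(logfc) >= min_abs_logfc)
    table = pd.DataFrame(
        {
            "gene": sub.index[keep],
            "logfc_base1p5": logfc[keep],
            "p_adj": p_adj[keep],
            "caller": caller,
        }
    ).reset_index(drop=True)
    return DEGTable(Contrast(group_a, group_b, temperature), table)


def filter_against_tsp53(target: DEGTable, control: DEGTable, ratio: float = 3.0) -> DEGTable:
    """Remove target DEGs explained by tsp53 alone.

    A target gene found in the control (tsp53-only) list is kept only when the
    fold-change direction differs, or the magnitude is more than ``ratio``
    times higher or lower than in the control (strict inequality, log1.5
    scale).  The result is always a subset of ``target``.
    """
    if target.contrast.temperature != control.contrast.temperature:
        raise ValueError("target and control tables must share the same temperature")
    if ratio <= 1:
        raise ValueError("ratio must be > 1")

    ctrl_fc = control.table.set_index("gene")["logfc_base1p5"]
    # control may hold several callers' records for a gene; use the first
    ctrl_fc = ctrl_fc[~ctrl_fc.index.duplicated()]

    def keep(row) -> bool:
        g = row["gene"]
        if g not in ctrl_fc.index:
            return True
        t, c = row["logfc_base1p5"], ctrl_fc[g]
        if np.sign(t) != np.sign(c):
            return True
        return abs(t) > ratio * abs(c) or abs(t) < abs(c) / ratio

    mask = target.table.apply(keep, axis=1)
    return DEGTable(target.contrast, target.table.loc[mask].reset_index(drop=True))


def exclusive_to_32C(degs_32: DEGTable, degs_37: DEGTable) -> DEGTable:
    """Keep only genes of the 32 °C list absent from the 37 °C list."""
    if degs_32.contrast.temperature == degs_37.contrast.temperature:
        raise ValueError("expected tables from the two different temperatures")
    drop = degs_37.genes
    mask = ~degs_32.table["gene"].isin(drop)
    return DEGTable(degs_32.contrast, degs_32.table.loc[mask].reset_index(drop=True))


def combine_callers(per_caller_results: dict[str, set[str]] | list[set[str]]) -> pd.DataFrame:
    """Union of per-caller filtered gene sets, with provenance.

    Returns a DataFrame with columns gene, callers (comma-joined sorted
    labels), n_callers; one row per gene in the union.
    """
    if isinstance(per_caller_results, dict):
        items = list(per_caller_results.items())
    else:
        items = [(f"caller{i}", s) for i, s in enumerate(per_caller_results)]
    if not items:
        raise ValueError("empty list of caller results")
    provenance: dict[str, list[str]] = {}
    for name, genes in items:
        for g in genes:
            provenance.setdefault(g, []).append(name)
    rows = [
        {"gene": g, "callers": ",".join(sorted(cs)), "n_callers": len(cs)}
        for g, cs in sorted(provenance.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "callers", "n_callers"])


def run_deg_pipeline(
    counts: CountMatrix,
    alpha_fdr: float = 0.05,
    min_fc: float = 1.5,
    ratio: float = 3.0,
    callers: tuple[str, ...] = ("moderated_t",),
    target_line: str = "NTRK1_tsp53",
    control_line: str = "tsp53_only",
    baseline_line: str = "parental",
) -> pd.DataFrame:
    """Full module-activation filtering pipeline over one or more callers.

    Per caller and temperature: call target-vs-baseline and control-vs-baseline
    DEGs, remove tsp53-explained genes, then keep the 32 °C-exclusive
    remainder; finally union the per-caller gene sets with provenance.
    """
    per_caller: dict[str, set[str]] = {}
    for caller in callers:
        filtered = {}
        for temp in ("32C", "37C"):
            target = call_degs(counts, target_line, baseline_line, temp, alpha_fdr, min_fc, caller)
            control = call_degs(counts, control_line, baseline_line, temp, alpha_fdr, min_fc, caller)
            filtered[temp] = filter_against_tsp53(target, control, ratio)
        final = exclusive_to_32C(filtered["32C"], filtered["37C"])
        per_caller[caller] = final.genes
    return combine_callers(per_caller)
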