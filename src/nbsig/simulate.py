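"""Synthetic data generators for every stage of the pipeline.

Two experiments are emulated:

* a six-condition cell-line RNA-seq design — three SH-SY5Y-derived backgrounds
  (``NTRK1_tsp53``: NTRK1 + temperature-sensitive p53, ``tsp53_only``, and the
  ``parental`` line) each grown at 32 °C (wild-type p53 conformation, module
  active in the NTRK1_tsp53 line) and 37 °C (mutant conformation, module
  inactive), with negative-binomial counts and planted differential-expression
  structure;
* patient cohorts with per-gene standard-normal expression, proportional-hazards
  event times driven by a planted signature-gene linear predictor plus
  MYCN/age/INSS covariates correlated through a shared latent risk variable,
  and independent censoring.

Both generators are deterministic under a fixed seed, and both expose the
planted truth so recovery tests can score the downstream pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    CLINICAL_COLUMNS,
    INSS_ORDERED_CODE,
    INSS_STAGES,
    DegenerateCohortWarning,
    ExpressionMatrix,
)

CELL_LINES = ["NTRK1_tsp53", "tsp53_only", "parental"]
TEMPERATURES = ["32C", "37C"]

#: Genes used by the module-activation classifier; always present in cohorts.
MODULE_CLASSIFIER_GENES = ("NTRK1", "PTPN6", "TP53")


@dataclass(frozen=True)
class CellLineDesign:
    """One sequenced sample: cell background, growth temperature, replicate."""

    cell_line: str
    temperature: str
    replicate: int

    def __post_init__(self):
        if self.cell_line not in CELL_LINES:
            raise ValueError(f"unknown cell line {self.cell_line!r}")
        if self.temperature not in TEMPERATURES:
            raise ValueError(f"unknown temperature {self.temperature!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    @property
    def sample_id(self) -> str:
        return f"{self.cell_line}_{self.temperature}_r{self.replicate}"


def make_design(n_replicates: int = 3) -> list[CellLineDesign]:
    """Full-factorial design: 3 cell lines x 2 temperatures x replicates."""
    if n_replicates < 2:
        raise ValueError("need >=2 replicates per condition")
    return [
        CellLineDesign(line, temp, r)
        for line in CELL_LINES
        for temp in TEMPERATURES
        for r in range(1, n_replicates + 1)
    ]


def design_frame(design: list[CellLineDesign]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [d.sample_id for d in design],
            "cell_line": [d.cell_line for d in design],
            "temperature": [d.temperature for d in design],
            "replicate": [d.replicate for d in design],
        }
    )


@dataclass
class PlantedTruth:
    """Truth labels for the cell-line simulation.

    ``module_genes`` shift only in the NTRK1_tsp53 line at 32 °C (the
    activated-module condition) — these are the genes the filtering algebra
    must recover.  ``tsp53_genes`` shift identically in both tsp53-carrying
    lines at 32 °C, so the tsp53-control filter must remove them.
    ``temp_genes`` shift in the NTRK1_tsp53 line at both temperatures, so the
    32 °C-exclusivity filter must remove them.
    """

    module_genes: tuple[str, ...]
    tsp53_genes: tuple[str, ...] = ()
    temp_genes: tuple[str, ...] = ()
    effect_log2fc: float = 3.0
    dispersion: float = 0.05

    def __post_init__(self):
        self.module_genes = tuple(self.module_genes)
        self.tsp53_genes = tuple(self.tsp53_genes)
        self.temp_genes = tuple(self.temp_genes)
        sets = [set(self.module_genes), set(self.tsp53_genes), set(self.temp_genes)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("planted gene sets must be disjoint")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    @property
    def all_planted(self) -> set[str]:
        return set(self.module_genes) | set(self.tsp53_genes) | set(self.temp_genes)


@dataclass
class CountMatrix:
    """Non-negative integer counts (genes x samples) plus the sample design."""

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.counts.shape[1] != len(self.design):
            raise ValueError("column count does not match design size")

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene")

    def samples_for(self, cell_line: str, temperature: str) -> list[str]:
        d = self.design
        mask = (d["cell_line"] == cell_line) & (d["temperature"] == temperature)
        return list(d.loc[mask, "sample_id"])


def simulate_cellline_counts(
    n_genes: int,
    truth: PlantedTruth,
    seed: int,
    n_replicates: int = 3,
    mean_log_expression: float = 5.0,
    sd_log_expression: float = 1.0,
    libsize_sigma: float = 0.1,
) -> CountMatrix:
    """Negative-binomial counts for the six-condition cell-line design.

    Per-gene baseline means are log-normal; planted genes multiply their mean
    by ``2**(+/- effect_log2fc)`` in their designated conditions only (the sign
    is drawn per gene so both up- and down-regulation occur).  Library-size
    factors are log-normal with ``sigma=libsize_sigma``.  Counts are drawn
    NB(mean, dispersion) with Var = mu + dispersion * mu^2.
    """
    planted = truth.all_planted
    if n_genes < len(planted):
        raise ValueError(f"n_genes={n_genes} smaller than planted union ({len(planted)})")
    design = make_design(n_replicates)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCE11]))

    planted_sorted = sorted(planted)
    background = [f"G{i:05d}" for i in range(n_genes - len(planted_sorted))]
    gene_ids = planted_sorted + background

    base = rng.lognormal(mean=mean_log_expression, sigma=sd_log_expression, size=n_genes)
    signs = {g: s for g, s in zip(planted_sorted, rng.choice([-1.0, 1.0], len(planted_sorted)))}

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    mu = np.tile(base[:, None], (1, len(design)))
    for j, d in enumerate(design):
        active = d.cell_line == "NTRK1_tsp53" and d.temperature == "32C"
        for g in truth.module_genes:
            if active:
                mu[gene_pos[g], j] *= 2.0 ** (signs[g] * truth.effect_log2fc)
        for g in truth.tsp53_genes:
            if d.temperature == "32C" and d.cell_line in ("NTRK1_tsp53", "tsp53_only"):
                mu[gene_pos[g], j] *= 2.0 ** (signs[g] * truth.effect_log2fc)
        for g in truth.temp_genes:
            if d.cell_line == "NTRK1_tsp53":
                mu[gene_pos[g], j] *= 2.0 ** (signs[g] * truth.effect_log2fc)

    size_factors = rng.lognormal(mean=0.0, sigma=libsize_sigma, size=len(design))
    mu = mu * size_factors[None, :]

    # NB via gamma-Poisson: shape r = 1/dispersion, Var = mu + dispersion*mu^2
    r = 1.0 / truth.dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam)

    frame = pd.DataFrame(counts, index=gene_ids, columns=[d.sample_id for d in design])
    return CountMatrix(counts=frame, design=design_frame(design))


@dataclass
class CohortTruth:
    """Planted proportional-hazards structure for a patient cohort.

    ``beta`` is the per-gene log hazard ratio applied to every signature gene
    (or a mapping gene -> beta).  Covariate log-HRs act on: MYCN amplification,
    age >= 18 months at diagnosis, and the ordered INSS code (per step).
    """

    signature_genes: tuple[str, ...]
    beta: float | dict[str, float] = 0.5
    covariate_betas: dict[str, float] = field(
        default_factory=lambda: {"mycn_amplified": 0.7, "age_ge18": 0.5, "inss_stage": 0.3}
    )
    baseline_hazard: float = 0.1
    censor_rate: float = 0.05
    admin_horizon_years: float = 10.0

    def __post_init__(self):
        self.signature_genes = tuple(self.signature_genes)
        betas = self.gene_betas()
        if not all(np.isfinite(list(betas.values()) or [0.0])):
            raise ValueError("non-finite gene betas")
        if self.censor_rate <= 0:
            raise ValueError("censor_rate must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not self.signature_genes and np.any(np.asarray(list(betas.values()) or [0.0]) != 0):
            raise ValueError("empty signature set with nonzero beta")

    def gene_betas(self) -> dict[str, float]:
        if isinstance(self.beta, dict):
            unknown = set(self.beta) - set(self.signature_genes)
            if unknown:
                raise ValueError(f"betas for genes outside the signature: {sorted(unknown)}")
            return dict(self.beta)
        if not self.signature_genes and self.beta != 0:
            raise ValueError("empty signature set with nonzero beta")
        return {g: float(self.beta) for g in self.signature_genes}


#: Marginal frequencies for the clinical covariates.
MYCN_AMPLIFIED_RATE = 0.20
AGE_GE18_RATE = 0.55
INSS_PROBS = {"1": 0.20, "2": 0.15, "3": 0.20, "4": 0.35, "4S": 0.10}
FAVOURABLE_HISTOLOGY_RATE = 0.5
LATENT_RISK_CORRELATION = 0.5


def simulate_cohort(
    n_patients: int,
    gene_ids: list[str],
    truth: CohortTruth,
    seed: int,
    missing_rate: float = 0.0,
    histology_missing_rate: float = 0.0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a patient cohort: expression matrix plus clinical table.

    Expression is standard normal per gene, independent across genes.  Event
    times are exponential proportional hazards with linear predictor
    ``sum_g beta_g x_g + covariate terms``; covariates are correlated with each
    other through a shared latent risk variable so stratified comparisons are
    non-trivial.  Censoring is independent exponential plus an administrative
    horizon.  ``missing_rate`` knocks out required clinical fields at random to
    exercise the completeness filter.
    """
    if n_patients < 20:
        raise ValueError("n_patients must be >= 20")
    gene_ids = list(gene_ids)
    missing_sig = set(truth.signature_genes) - set(gene_ids)
    if missing_sig:
        raise ValueError(f"signature genes not in gene_ids: {sorted(missing_sig)}")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0409]))
    n_genes = len(gene_ids)
    expr = rng.standard_normal((n_genes, n_patients))
    sample_ids = [f"P{i:04d}" for i in range(n_patients)]
    expr_df = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)

    # covariates share a latent risk variable
    rho = LATENT_RISK_CORRELATION
    latent = rng.standard_normal(n_patients)

    def correlated_uniform():
        z = rho * latent + np.sqrt(1 - rho**2) * rng.standard_normal(n_patients)
        from scipy.stats import norm

        return norm.cdf(z)

    mycn = (correlated_uniform() > 1 - MYCN_AMPLIFIED_RATE).astype(int)

    u_age = correlated_uniform()
    from scipy.stats import lognorm

    # age in months, lognormal with median ~20 months -> P(age>=18) ~ AGE_GE18_RATE
    mu_age = np.log(18.0) - np.sqrt(2) * 1.0 * _erfinv(1 - 2 * AGE_GE18_RATE)
    age_months = np.round(lognorm.ppf(u_age, s=1.0, scale=np.exp(mu_age))).astype(int)
    age_months = np.clip(age_months, 0, 400)
    age_ge18 = (age_months >= 18).astype(int)

    u_inss = correlated_uniform()
    stage_order = ["1", "4S", "2", "3", "4"]  # ordered by risk coding
    cuts = np.cumsum([INSS_PROBS[s] for s in stage_order])
    inss = np.array([stage_order[int(np.searchsorted(cuts, u))] for u in np.clip(u_inss, 0, cuts[-1] - 1e-12)])
    inss_code = np.array([INSS_ORDERED_CODE[s] for s in inss], dtype=float)

    u_hist = correlated_uniform()
    histology = np.where(u_hist < FAVOURABLE_HISTOLOGY_RATE, "favourable", "unfavourable").astype(object)

    betas = truth.gene_betas()
    eta = np.zeros(n_patients)
    for g, b in betas.items():
        eta += b * expr_df.loc[g].to_numpy()
    cb = truth.covariate_betas
    eta += cb.get("mycn_amplified", 0.0) * mycn
    eta += cb.get("age_ge18", 0.0) * age_ge18
    eta += cb.get("inss_stage", 0.0) * inss_code

    rate = truth.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(1.0 / truth.censor_rate, size=n_patients)
    t_cens = np.minimum(t_cens, truth.admin_horizon_years)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)  # efs_time must be strictly positive

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "efs_time_years": time,
            "efs_event": event,
            "age_months": age_months.astype(float),
            "mycn_amplified": mycn.astype(float),
            "inss_stage": inss,
            "histology": histology,
        },
        columns=CLINICAL_COLUMNS,
    )

    if missing_rate > 0:
        for col in ["age_months", "mycn_amplified", "inss_stage"]:
            knock = rng.random(n_patients) < missing_rate
            clinical.loc[knock, col] = np.nan
    if histology_missing_rate > 0:
        knock = rng.random(n_patients) < histology_missing_rate
        clinical.loc[knock, "histology"] = np.nan

    if int(event.sum()) == 0:
        warnings.warn(
            "simulated cohort has no events; downstream survival analyses are degenerate",
            DegenerateCohortWarning,
            stacklevel=2,
        )

    return ExpressionMatrix(expr_df, scaled=False), clinical


def _erfinv(x: float) -> float:
    from scipy.special import erfinv

    return float(erfinv(x))


def simulate_ct_table(
    genes: list[str],
    true_log2_fc: dict[str, float],
    seed: int,
    n_replicates: int = 3,
    noise_sd: float = 0.15,
    test_condition: str = "module_active_32C",
    control_condition: str = "module_inactive_37C",
) -> pd.DataFrame:
    """Synthetic qPCR CT table (long format) with known fold changes.

    Reference-gene CTs sit near 20 cycles; target CTs in the test condition are
    shifted by ``-log2_fc`` cycles relative to control (one cycle = one
    doubling), plus Gaussian replicate noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x09CB]))
    rows = []
    for gene in genes:
        base_ct = rng.uniform(22.0, 30.0)
        fc = true_log2_fc.get(gene, 0.0)
        for rep in range(1, n_replicates + 1):
            ref1 = 20.0 + rng.normal(0, noise_sd)
            ref2 = 21.0 + rng.normal(0, noise_sd)
            rows.append(
                dict(
                    gene=gene,
                    condition=control_condition,
                    replicate=rep,
                    ct_target=base_ct + rng.normal(0, noise_sd),
                    ct_ref1=ref1,
                    ct_ref2=ref2,
                )
            )
            ref1 = 20.0 + rng.normal(0, noise_sd)
            ref2 = 21.0 + rng.normal(0, noise_sd)
            rows.append(
                dict(
                    gene=gene,
                    condition=test_condition,
                    replicate=rep,
                    ct_target=base_ct - fc + rng.normal(0, noise_sd),
                    ct_ref1=ref1,
                    ct_ref2=ref2,
                )
            )
    return pd.DataFrame(rows)
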