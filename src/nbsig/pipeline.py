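"""End-to-end pipeline orchestration.

Stages run in a fixed order — simulate, deg, prep, screen, train, evaluate,
stratify, qpcr — against a working directory; each stage reads the artifacts
earlier stages persisted, and a manifest records every output file with its
SHA-256 hash plus the seeds used, so re-running with an identical config
reproduces identical artifacts.

Stage parameters default to the published analysis settings: FDR 0.05 and
fold change 1.5 with the 3x tsp53 ratio for DEG filtering; Bonferroni-corrected
alpha 0.05 for the univariate screen; a 200-tree depth-3 survival forest with
node size 15 and mtry 6; a five-year horizon with median-split risk groups
for evaluation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deg as deg_mod
from . import evaluate as ev
from . import prep, qpcr, signature, stratify
from .containers import INSS_ORDERED_CODE, ExpressionMatrix, as_time_event
from .rsf import RandomSurvivalForest, permutation_importance
from .screen import screen_features
from .simulate import (
    MODULE_CLASSIFIER_GENES,
    CohortTruth,
    PlantedTruth,
    simulate_cellline_counts,
    simulate_cohort,
    simulate_ct_table,
)

logger = logging.getLogger(__name__)

STAGES = ["simulate", "deg", "prep", "screen", "train", "evaluate", "stratify", "qpcr"]

COHORTS = ["train", "val1", "val2"]


@dataclass
class SimulateConfig:
    n_genes: int = 2000
    n_module_genes: int = 30
    n_tsp53_genes: int = 30
    n_temp_genes: int = 30
    effect_log2fc: float = 3.0
    dispersion: float = 0.05
    n_replicates: int = 3
    n_train: int = 498
    n_val1: int = 272
    n_val2: int = 244
    n_background_cohort_genes: int = 15
    gene_beta: float = 0.5
    qpcr_log2fc: float = 1.0


@dataclass
class DegConfig:
    alpha_fdr: float = 0.05
    min_fc: float = 1.5
    ratio: float = 3.0
    callers: tuple = ("moderated_t",)


@dataclass
class ScreenConfig:
    alpha: float = 0.05
    ties: str = "efron"


@dataclass
class RSFConfig:
    n_trees: int = 200
    max_depth: int = 3
    nodesize: int = 15
    mtry: int = 6


@dataclass
class EvaluateConfig:
    horizon: float = 5.0
    roc_horizons: tuple = (1.0, 3.0, 5.0)
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    deg: DegConfig = field(default_factory=DegConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    rsf: RSFConfig = field(default_factory=RSFConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {
            "simulate": SimulateConfig,
            "deg": DegConfig,
            "screen": ScreenConfig,
            "rsf": RSFConfig,
            "evaluate": EvaluateConfig,
        }
        kwargs = {}
        for key, value in raw.items():
            if key == "seed":
                kwargs["seed"] = int(value)
            elif key in known:
                section = known[key]
                valid = {f.name for f in section.__dataclass_fields__.values()}
                bad = set(value) - valid
                if bad:
                    raise ValueError(f"unknown field(s) in config section '{key}': {sorted(bad)}")
                kwargs[key] = section(**value)
            else:
                raise ValueError(f"unknown config section '{key}'")
        return cls(**kwargs)

    def validate(self) -> None:
        s = self.simulate
        if s.n_genes < s.n_module_genes + s.n_tsp53_genes + s.n_temp_genes:
            raise ValueError("simulate.n_genes too small for the planted sets")
        if not (0 < self.deg.alpha_fdr < 1):
            raise ValueError("deg.alpha_fdr must be in (0, 1)")
        if self.deg.min_fc <= 1:
            raise ValueError("deg.min_fc must be > 1")
        if self.deg.ratio <= 1:
            raise ValueError("deg.ratio must be > 1")
        if not (0 < self.screen.alpha < 1):
            raise ValueError("screen.alpha must be in (0, 1)")
        n_features = len(signature.SIGNATURE_GENES) + len(signature.CLINICAL_FEATURES)
        if self.rsf.mtry > n_features:
            raise ValueError(
                f"rsf.mtry ({self.rsf.mtry}) exceeds the model feature count ({n_features})"
            )
        if self.rsf.n_trees < 1 or self.rsf.nodesize < 1:
            raise ValueError("rsf.n_trees and rsf.nodesize must be >= 1")
        if self.evaluate.horizon <= 0:
            raise ValueError("evaluate.horizon must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


# -- helpers ----------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    """Named per-stage substream derived from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _cohort_gene_universe(cfg: SimulateConfig) -> list[str]:
    background = [f"BG{i:03d}" for i in range(cfg.n_background_cohort_genes)]
    return sorted(
        set(signature.SIGNATURE_GENES) | set(MODULE_CLASSIFIER_GENES) | set(background)
    )


def _cohort_truth(cfg: SimulateConfig) -> CohortTruth:
    # high expression of the favourable-high genes lowers hazard; the
    # favourable-low genes carry positive log-HRs
    betas = {g: -cfg.gene_beta for g in signature.FAVOURABLE_HIGH}
    betas.update({g: cfg.gene_beta for g in signature.FAVOURABLE_LOW})
    return CohortTruth(signature_genes=tuple(sorted(betas)), beta=betas)


def _model_matrix(expr_z: ExpressionMatrix, clinical: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    """Samples x features frame: gene z-scores plus encoded clinical features."""
    feats = expr_z.values.loc[genes].T.copy()
    feats = feats.loc[clinical["sample_id"]]
    feats["mycn_amplified"] = clinical.set_index("sample_id")["mycn_amplified"].astype(float)
    feats["age_lt_18_months"] = (
        clinical.set_index("sample_id")["age_months"] < 18
    ).astype(float)
    feats["inss_stage"] = clinical.set_index("sample_id")["inss_stage"].map(
        INSS_ORDERED_CODE
    ).astype(float)
    return feats


# -- stages -----------------------------------------------------------------


def _stage_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    s = cfg.simulate
    seed = _stage_seed(cfg.seed, "simulate")
    module = tuple(f"MOD{i:03d}" for i in range(s.n_module_genes))
    tsp53 = tuple(f"P53{i:03d}" for i in range(s.n_tsp53_genes))
    temp = tuple(f"TMP{i:03d}" for i in range(s.n_temp_genes))
    truth = PlantedTruth(module, tsp53, temp, s.effect_log2fc, s.dispersion)
    counts = simulate_cellline_counts(s.n_genes, truth, seed, s.n_replicates)
    files = []
    counts.to_tsv(out / "counts.tsv")
    counts.design.to_csv(out / "design.csv", index=False)
    files += [out / "counts.tsv", out / "design.csv"]
    (out / "planted_truth.json").write_text(
        json.dumps({"module_genes": list(module), "tsp53_genes": list(tsp53), "temp_genes": list(temp)})
    )
    files.append(out / "planted_truth.json")

    genes = _cohort_gene_universe(s)
    truth_c = _cohort_truth(s)
    for cohort, n in zip(COHORTS, [s.n_train, s.n_val1, s.n_val2]):
        expr, clin = simulate_cohort(n, genes, truth_c, _stage_seed(cfg.seed, f"cohort:{cohort}"))
        expr.to_tsv(out / f"cohort_{cohort}_expression.tsv")
        clin.to_csv(out / f"cohort_{cohort}_clinical.csv", index=False)
        files += [out / f"cohort_{cohort}_expression.tsv", out / f"cohort_{cohort}_clinical.csv"]

    fcs = {g: s.qpcr_log2fc for g in signature.FAVOURABLE_HIGH}
    fcs.update({g: -s.qpcr_log2fc for g in signature.FAVOURABLE_LOW})
    ct = simulate_ct_table(sorted(fcs), fcs, _stage_seed(cfg.seed, "qpcr_sim"))
    ct.to_csv(out / "ct_table.csv", index=False)
    files.append(out / "ct_table.csv")
    return files


def _load_counts(out: Path):
    from .simulate import CountMatrix

    counts = pd.read_csv(out / "counts.tsv", sep="\t", index_col="gene")
    design = pd.read_csv(out / "design.csv")
    return CountMatrix(counts=counts, design=design)


def _stage_deg(cfg: PipelineConfig, out: Path) -> list[Path]:
    counts = _load_counts(out)
    d = cfg.deg
    result = deg_mod.run_deg_pipeline(
        counts, alpha_fdr=d.alpha_fdr, min_fc=d.min_fc, ratio=d.ratio, callers=tuple(d.callers)
    )
    result.to_csv(out / "deg_genes.csv", index=False)
    return [out / "deg_genes.csv"]


def _stage_prep(cfg: PipelineConfig, out: Path) -> list[Path]:
    files = []
    gene_lists = []
    for cohort in COHORTS:
        expr = ExpressionMatrix.from_tsv(out / f"cohort_{cohort}_expression.tsv")
        clin = pd.read_csv(out / f"cohort_{cohort}_clinical.csv")
        clin = prep.filter_complete_samples(clin)
        clin = prep.cap_efs(clin, horizon=cfg.evaluate.horizon)
        expr_z = prep.clean_and_scale(
            ExpressionMatrix(expr.values[clin["sample_id"]], scaled=False)
        )
        expr_z.to_tsv(out / f"prepared_{cohort}_expression_z.tsv")
        clin.to_csv(out / f"prepared_{cohort}_clinical.csv", index=False)
        files += [out / f"prepared_{cohort}_expression_z.tsv", out / f"prepared_{cohort}_clinical.csv"]
        gene_lists.append(expr_z.gene_ids)
    common = prep.intersect_gene_lists(gene_lists)
    candidates = sorted(set(common) & set(signature.SIGNATURE_GENES))
    (out / "common_genes.txt").write_text("\n".join(common) + "\n")
    files.append(out / "common_genes.txt")
    train_z = ExpressionMatrix.from_tsv(out / "prepared_train_expression_z.tsv", scaled=True)
    report = prep.check_collinearity(train_z, candidates if len(candidates) >= 2 else common)
    report.to_csv(out / "collinearity.csv", index=False)
    files.append(out / "collinearity.csv")
    return files


def _prepared(out: Path, cohort: str):
    expr_z = ExpressionMatrix.from_tsv(out / f"prepared_{cohort}_expression_z.tsv", scaled=True)
    clin = pd.read_csv(out / f"prepared_{cohort}_clinical.csv")
    return expr_z, clin


def _stage_screen(cfg: PipelineConfig, out: Path) -> list[Path]:
    expr_z, clin = _prepared(out, "train")
    common = (out / "common_genes.txt").read_text().split()
    candidates = sorted(set(common) & set(signature.SIGNATURE_GENES)) or common
    time, event = as_time_event(clin)
    feats = expr_z.values.loc[candidates].T.loc[clin["sample_id"]]
    result = screen_features(feats, time, event, alpha=cfg.screen.alpha, ties=cfg.screen.ties)
    result.to_frame().to_csv(out / "screen.csv", index=False)
    (out / "selected_genes.txt").write_text("\n".join(sorted(result.selected)) + "\n")
    return [out / "screen.csv", out / "selected_genes.txt"]


def _stage_train(cfg: PipelineConfig, out: Path) -> list[Path]:
    expr_z, clin = _prepared(out, "train")
    selected = (out / "selected_genes.txt").read_text().split()
    feats = _model_matrix(expr_z, clin, selected)
    time, event = as_time_event(clin)
    forest = RandomSurvivalForest(
        n_estimators=cfg.rsf.n_trees,
        max_depth=cfg.rsf.max_depth,
        min_node_size=cfg.rsf.nodesize,
        max_features=min(cfg.rsf.mtry, feats.shape[1]),
        random_state=_stage_seed(cfg.seed, "train"),
        oob_score=True,
    ).fit(feats, (time, event))
    (out / "model.json").write_text(forest.to_json())
    scores = pd.Series(forest.predict(feats), index=feats.index, name="mortality")
    scores.rename_axis("sample_id").to_csv(out / "train_scores.csv")
    imp = permutation_importance(
        forest, feats, (time, event), seed=_stage_seed(cfg.seed, "importance")
    )
    imp.rename_axis("feature").to_csv(out / "permutation_importance.csv")
    meta = {
        "training_median": float(np.median(scores)),
        "oob_concordance": forest.oob_score_,
        "n_features": feats.shape[1],
        "features": list(feats.columns),
    }
    (out / "model_meta.json").write_text(json.dumps(meta, indent=2))
    return [out / "model.json", out / "train_scores.csv", out / "permutation_importance.csv", out / "model_meta.json"]


def _stage_evaluate(cfg: PipelineConfig, out: Path) -> list[Path]:
    forest = RandomSurvivalForest.from_json((out / "model.json").read_text())
    meta = json.loads((out / "model_meta.json").read_text())
    selected = (out / "selected_genes.txt").read_text().split()
    files = []
    n_tests = len(signature.SIGNATURE_GENES) + len(signature.CLINICAL_FEATURES)
    threshold = cfg.evaluate.alpha / n_tests
    for cohort in COHORTS[1:]:
        expr_z, clin = _prepared(out, cohort)
        feats = _model_matrix(expr_z, clin, selected)
        scores = pd.Series(forest.predict(feats), index=feats.index, name="mortality")
        scores.rename_axis("sample_id").to_csv(out / f"scores_{cohort}.csv")
        files.append(out / f"scores_{cohort}.csv")
        labels = ev.median_split(scores.to_numpy(), meta["training_median"])
        time, event = as_time_event(clin)
        summary = {"cohort": cohort, "n": int(len(clin)), "logrank_threshold": threshold}
        groups = {}
        for grp in ("low", "high"):
            mask = labels == grp
            if mask.sum() == 0:
                continue
            km = ev.kaplan_meier(time[mask], event[mask])
            km.to_frame().to_csv(out / f"km_{cohort}_{grp}.csv", index=False)
            files.append(out / f"km_{cohort}_{grp}.csv")
            groups[grp] = {
                "n": int(mask.sum()),
                "survival_5y": ev.survival_at(km, cfg.evaluate.horizon),
                "rmst_5y": ev.mean_survival(km, cfg.evaluate.horizon),
            }
        summary["groups"] = groups
        if len(groups) == 2:
            lr = ev.logrank_test(
                [(time[labels == g], event[labels == g]) for g in ("low", "high")]
            )
            summary["logrank"] = {
                "chi_square": lr.chi_square,
                "p_value": lr.p_value,
                "significant": lr.p_value < threshold,
            }
        summary["auc"] = {}
        for h in cfg.evaluate.roc_horizons:
            try:
                roc = ev.td_roc(scores.to_numpy(), time, event, h)
            except ValueError as exc:
                summary["auc"][str(h)] = None
                logger.info("evaluate: no ROC at %s y for %s (%s)", h, cohort, exc)
                continue
            roc.to_frame().to_csv(out / f"roc_{cohort}_{h:g}y.csv", index=False)
            files.append(out / f"roc_{cohort}_{h:g}y.csv")
            summary["auc"][str(h)] = roc.auc
        (out / f"evaluate_{cohort}.json").write_text(json.dumps(summary, indent=2))
        files.append(out / f"evaluate_{cohort}.json")
    return files


def _stage_stratify(cfg: PipelineConfig, out: Path) -> list[Path]:
    files = []
    for cohort in COHORTS[1:]:
        expr_z, clin = _prepared(out, cohort)
        scores = pd.read_csv(out / f"scores_{cohort}.csv", index_col="sample_id")["mortality"]
        markers = pd.DataFrame(index=clin["sample_id"])
        markers["mycn_amplified"] = clin.set_index("sample_id")["mycn_amplified"].astype(bool)
        markers["age_lt_18_months"] = clin.set_index("sample_id")["age_months"] < 18
        hist = clin.set_index("sample_id")["histology"]
        markers["favourable_histology"] = hist.map({"favourable": True, "unfavourable": False})
        active = stratify.classify_module_samples(expr_z)
        markers["module_active"] = active.reindex(markers.index)
        table = stratify.stratify_table(scores.loc[markers.index], markers)
        table.to_csv(out / f"stratify_{cohort}.csv", index=False)
        files.append(out / f"stratify_{cohort}.csv")
    return files


def _stage_qpcr(cfg: PipelineConfig, out: Path) -> list[Path]:
    ct = pd.read_csv(out / "ct_table.csv")
    res = qpcr.analyze_ct_table(ct, "module_active_32C", "module_inactive_37C")
    res.to_csv(out / "qpcr_results.csv", index=False)
    return [out / "qpcr_results.csv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "deg": _stage_deg,
    "prep": _stage_prep,
    "screen": _stage_screen,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
    "stratify": _stage_stratify,
    "qpcr": _stage_qpcr,
}


def run_pipeline(config: PipelineConfig, outdir, stages: list[str] | None = None) -> dict:
    """Run the pipeline stages in order and write a manifest.

    The config is validated before any stage runs.  The manifest records, for
    every stage, the output files with SHA-256 hashes, plus the master seed
    and config echo; a stage failure leaves the manifest recording partial
    completion.
    """
    config.validate()
    stages = list(STAGES if stages is None else stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages.sort(key=STAGES.index)

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "complete": False,
    }
    try:
        for stage in stages:
            logger.info("pipeline: running stage %s", stage)
            files = _STAGE_FUNCS[stage](config, out)
            manifest["stages"][stage] = {
                "seed": _stage_seed(config.seed, stage),
                "outputs": {str(f.relative_to(out)): _sha256(f) for f in files},
            }
        manifest["complete"] = True
    finally:
        manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
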