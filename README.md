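# nbsig

A prognostic gene-signature pipeline for neuroblastoma, built around
expression changes induced by activation of the **NTRK1–PTPN6–TP53 module**
(TP53-dependent repression of the phosphatase PTPN6, which leaves the
neurotrophin receptor NTRK1 phosphorylated and active — a marker of
favourable outcome in neuroblastoma).

The package is for computational biologists and biostatisticians who want to
derive, validate, or stress-test survival gene signatures of this kind on
their own cohorts, or on synthetic cohorts with known planted structure.

## What it does

1. **Synthetic data with planted truth** (`nbsig.simulate`): negative-binomial
   RNA-seq counts for a 3-cell-line × 2-temperature design in which a
   temperature-sensitive p53 switches the module on at 32 °C, and patient
   cohorts (standard-normal expression, exponential proportional-hazards
   event times, correlated MYCN/age/INSS covariates, independent censoring).
2. **DEG filtering algebra** (`nbsig.deg`): per-contrast DEG calling
   (moderated-t on log₂ library-size-normalised counts, BH-FDR < 0.05,
   fold change ≥ 1.5, log fold changes stored in base 1.5), removal of genes
   explained by tsp53 alone (kept only if the direction flips or the
   magnitude differs by more than 3×), restriction to 32 °C-exclusive genes,
   and a per-caller union with provenance.
3. **Cohort preparation** (`nbsig.prep`): completeness filtering on the four
   prognostic fields, duplicate-probe averaging, per-gene z-scaling,
   five-year administrative EFS capping, gene-list intersection, and a
   pairwise-correlation (|r| ≥ 0.9) multicollinearity check.
4. **Univariate screen** (`nbsig.screen`): per-feature Cox fits
   (Newton–Raphson on the partial likelihood, Efron ties), hazard ratios and
   Wald p-values, Bonferroni selection at α/m. `UnivariateCoxScreen` is an
   sklearn-style feature selector.
5. **Random survival forest** (`nbsig.rsf`): bootstrap trees split by the
   two-sample log-rank statistic (defaults: 200 trees, depth 3, node size 15,
   mtry 6); terminal nodes hold Nelson–Aalen cumulative hazards; a subject's
   prognostic score is the **ensemble mortality**
   `sum over event times of the forest-averaged cumulative hazard`.
   Out-of-bag concordance and permutation importance are built in.
6. **Validation** (`nbsig.evaluate`): Kaplan–Meier curves, multi-group
   log-rank tests, restricted mean survival time, median-split risk groups,
   per-gene KM at the z = 0 threshold, and time-dependent ROC/AUC
   (cumulative cases / dynamic controls with Kaplan–Meier weighting).
7. **Stratification** (`nbsig.stratify`): Mann–Whitney U comparisons of the
   prognostic score across MYCN amplification, age < 18 months, histology,
   and module activation (active ⇔ TP53 z < 0, PTPN6 z < 0, NTRK1 z > 0).
8. **qPCR confirmation** (`nbsig.qpcr`): 2^−ΔΔCT relative quantification with
   dual reference genes and paired t-tests on replicate ΔCT values.

The published 17-gene signature (BASP1, BSG/CD147, CCDC125, CD9, DLG2,
FNBP1, FRMD3, GABRB3, GNB2L1/RACK1, HAPLN4, HEBP2, HSD17B12, IGSF10, IL11RA,
IQCE, KCNQ3, TOX2), the 35-gene common list it was screened from, and the
three clinical model features ship as constants in `nbsig.signature`.

## Worked example

Train on one synthetic cohort with eight planted risk genes, validate on a
second cohort drawn from the same truth:

```python
import numpy as np
from nbsig import (CohortTruth, RandomSurvivalForest, UnivariateCoxScreen,
                   simulate_cohort, median_split, kaplan_meier, survival_at,
                   logrank_test, td_roc)
from nbsig.containers import as_time_event

genes = [f"g{i}" for i in range(20)]
truth = CohortTruth(signature_genes=tuple(genes[:8]), beta=0.6)
expr_train, clin_train = simulate_cohort(400, genes, truth, seed=1)
expr_val, clin_val = simulate_cohort(250, genes, truth, seed=2)

X_train, y_train = expr_train.values.T, as_time_event(clin_train)
screen = UnivariateCoxScreen(alpha=0.05).fit(X_train, y_train)
print(f"screen: {len(screen.selected_)}/{X_train.shape[1]} genes pass "
      f"Bonferroni p < {screen.threshold_:.4f}")

forest = RandomSurvivalForest(n_estimators=200, max_depth=3, min_node_size=15,
                              max_features=6, random_state=0, oob_score=True)
forest.fit(screen.transform(X_train), y_train)
print(f"training OOB concordance: {forest.oob_score_:.3f}")

scores = forest.predict(screen.transform(expr_val.values.T))
labels = median_split(scores, np.median(forest.predict(screen.transform(X_train))))
t_val, e_val = as_time_event(clin_val)
for grp in ("low", "high"):
    km = kaplan_meier(t_val[labels == grp], e_val[labels == grp])
    print(f"{grp}-risk n={int((labels == grp).sum())}: "
          f"5-year EFS {100 * survival_at(km, 5.0):.1f}%")
lr = logrank_test([(t_val[labels == g], e_val[labels == g]) for g in ("low", "high")])
print(f"log-rank chi2 = {lr.chi_square:.1f}, p = {lr.p_value:.2e}")
print(f"5-year AUC = {td_roc(scores, t_val, e_val, 5.0).auc:.3f}")
```

Output:

```
screen: 8/20 genes pass Bonferroni p < 0.0025
training OOB concordance: 0.686
low-risk n=115: 5-year EFS 45.4%
high-risk n=135: 5-year EFS 20.0%
log-rank chi2 = 21.9, p = 2.81e-06
5-year AUC = 0.752
```

The screen recovers exactly the eight planted genes; the forest's median-split
risk groups separate validation survival (log-rank p ≪ 0.0025, the
Bonferroni-corrected evaluation threshold for 20 features), and the score
discriminates five-year events with AUC ≈ 0.75.

## Command line

Every stage is a subcommand sharing one working directory:

```bash
nbsig run-all --seed 1 -o work/          # simulate → deg → … → qpcr + manifest
nbsig simulate -o work/                  # or stage by stage
nbsig deg -o work/ --config my.yaml
```

`work/manifest.json` records every output file with its SHA-256 hash and the
per-stage seeds; re-running with the same config reproduces identical bytes.

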