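# Methods

This note documents the statistical models the package implements, the
synthetic-data generators it is validated on, the defaults and why they were
chosen, and the numerical conventions that affect results.

## The analysis in brief

A gene signature for neuroblastoma prognosis is derived in four steps:
(1) find genes differentially expressed *only* when the NTRK1–PTPN6–TP53
module is active, using a cross-condition filtering algebra over a
temperature-switch cell-line design; (2) keep the genes individually
predictive of event-free survival (EFS) by univariate Cox screening with
Bonferroni control; (3) train a random survival forest on the surviving gene
z-scores plus three clinical covariates and use its ensemble mortality as a
prognostic score; (4) validate the score by median-split Kaplan–Meier /
log-rank analysis, time-dependent ROC, and Mann–Whitney stratification
against clinical markers, with qPCR fold changes as wet-lab confirmation.

## Differential expression and the filtering algebra

The internal caller operates on log₂-transformed, library-size-normalised
counts (columns scaled to the mean sequencing depth, pseudo-count 0.5) and
moderates the per-gene variance with an empirical-Bayes scaled-F prior: the
prior degrees of freedom d₀ and prior variance s₀² are moment-matched on the
log sample variances (trigamma inversion), the posterior variance is
(d₀s₀² + d·s²)/(d₀+d), and p-values come from the t distribution with d₀+d
degrees of freedom. Benjamini–Hochberg adjustment is applied over all genes
of a contrast; a gene is a DEG when adjusted p < 0.05 *and* the absolute
fold change is at least 1.5. Fold changes are stored canonically in log base
1.5, so the 1.5× threshold is |logfc| ≥ 1.

The algebra then proceeds per temperature: a DEG of the module-carrying line
(vs. the parental line) that also appears in the tsp53-only contrast is
discarded unless the sign of its log₁.₅ fold change differs or its magnitude
is **more than** 3× larger or **more than** 3× smaller (strict inequalities,
log scale; the symmetric "smaller" branch keeps genes the control condition
drives much harder than the module does). Genes surviving at both 32 °C and
37 °C are then removed — the module is only active at 32 °C, so genes
responding at both temperatures are temperature artefacts. Finally, per-caller
gene sets are combined by union with provenance (which callers contributed).
The default consensus uses the single moderated-t caller; an unmoderated
Welch-t caller and a CSV loader exist behind the same interface, but an
underpowered caller weakens the *exclusion* filters (a gene the caller misses
in the control contrast cannot be filtered out), so multi-caller unions are
opt-in.

## Cohort preparation

Samples must have all four prognostic fields (EFS time/event, age at
diagnosis, MYCN status, INSS stage); histology may be missing. Genes with
any non-finite value are dropped, duplicate gene rows (multiple
probes/isoforms) are averaged per sample *before* scaling, zero-variance
genes are dropped, and each remaining gene is z-scored across samples
(population SD by default; sample SD is an option). EFS is administratively
censored at 5 years: events after the horizon become censorings at the
horizon — the conventional fixed-horizon EFS definition. Multicollinearity
is checked by flagging gene pairs with |Pearson r| ≥ 0.9.

INSS stage is encoded as an ordered integer with 4S (the metastatic infant
pattern with favourable outcome) placed between stage 1 and stage 2:
1 → 0, 4S → 1, 2 → 2, 3 → 3, 4 → 4. One-hot encoding is available where the
ordering assumption is unwanted.

## Univariate Cox screen

Each feature is fitted alone by Newton–Raphson maximisation of the Cox
partial likelihood with Efron handling of tied event times (Breslow
optional), convergence when the step falls below 1e-9, step-halving to keep
the likelihood non-decreasing, and a monotone-likelihood guard (|β| capped
at 50 with a warning — perfect separation). Standard errors come from the
observed information; p-values are two-sided Wald. Selection is strict:
p < α/m with α = 0.05 and m the family size. The implementation is
vectorised (O(n) per Newton step after one sort) because the simulation
studies fit the model thousands of times; it agrees with lifelines'
`CoxPHFitter` to 1e-5 and with a brute-force grid maximiser to 1e-4 in the
test suite.

## Random survival forest

Trees are grown on bootstrap samples (with replacement, same n). At each
node, `max_features` features are drawn without replacement; every midpoint
between consecutive distinct values is a candidate threshold; the split
maximising the standardised two-sample log-rank statistic (hypergeometric
variance) wins, with ties broken by feature draw order then lower threshold.
A candidate is valid only if both children keep at least `min_node_size`
in-bag samples and the statistic's variance is positive; a node with no
events is terminal. Depth counts split levels below the root (root at depth
0; `max_depth=0` means single-node trees). Terminal nodes store the
Nelson–Aalen cumulative hazard of their in-bag members evaluated on the
forest-wide grid of unique training event times.

The prognostic score of a subject is the ensemble mortality: the sum over
that grid of the forest-averaged cumulative hazard. Only ranks of this score
matter downstream (median split, concordance, ROC).

Defaults — 200 trees, depth 3, node size 15, mtry 6 — are the configuration
the signature model is trained with. Randomness discipline: the master seed
spawns a bootstrap stream per tree and a feature-draw stream per (tree,
node), with features addressed by sorted name, so results are invariant to
tree order and input column order. Out-of-bag mortality averages each
tree's prediction over the samples it did not draw; OOB error is 1 minus
Harrell's concordance. Permutation importance is the mean OOB error increase
after permuting one feature among a tree's OOB samples (an identity
permutation gives exactly zero, which the tests exploit).

The bootstrap is with-replacement sampling because that is the default of
the survival-forest implementations this model family follows; subsampling
is not offered.

## Survival evaluation

* **Kaplan–Meier**: product-limit over distinct event times; censored
  subjects leave the risk set after their time; right-continuous steps.
* **Log-rank**: observed-minus-expected with hypergeometric variance,
  multi-group via the (k−1)-dimensional quadratic form (pseudo-inverse for
  degenerate covariance); p from the χ² upper tail. Risk-set singletons
  (n_t = 1) contribute no variance.
* **RMST**: the "mean survival time" reported for a risk group is the
  restricted mean — the area under S(t) on [0, 5] years — because with fewer
  than half the subjects experiencing events the median is undefined and the
  unrestricted mean is not estimable.
* **Median split**: validation subjects with mortality strictly above the
  *training* median are high-risk; ties go to low risk (arbitrary but fixed,
  configurable).
* **Time-dependent ROC** at horizon t: cumulative cases (event by t),
  dynamic controls (event-free past t), with sensitivity
  (1−S(t|X>c))·P(X>c)/(1−S(t)) and specificity S(t|X≤c)·P(X≤c)/S(t), each
  conditional survival estimated by the subgroup Kaplan–Meier — the
  KM-weighted estimator of the package the analysis follows (the
  nearest-neighbour variant would need a span parameter that is not part of
  the published configuration). AUC by trapezoidal integration over the
  cutoff sweep; with no censoring the estimator reduces exactly to the
  empirical ROC.
* **Per-gene KM**: z > 0 is the high-expression group, z ≤ 0 low; log-rank
  between the two, evaluated against the Bonferroni threshold of the gene
  family.
* Evaluation-level Bonferroni: the published model carries 20 features, so
  median-split log-rank results are called significant at 0.05/20 = 0.0025.

## Stratified association and module activation

A sample's module status is *active* iff TP53 z < 0, PTPN6 z < 0 and NTRK1
z > 0 (strict; boundary zeros inactive). Scores across a stratum are
compared with the two-sided Mann–Whitney U test: exact null distribution
when the pooled sample has at most 20 observations and no ties, otherwise
the normal approximation with midrank ties, tie correction and continuity
correction. Age stratification uses age < 18 months strictly.

## qPCR

Per replicate, ΔCT = target CT − arithmetic mean of the reference CTs
(dual references; the mean-CT convention equals geometric-mean normalisation
of expression). ΔΔCT pairs test and control replicates by label; the fold
change is 2^−ΔΔCT summarised by the arithmetic mean over replicates
(geometric optional). Significance is a paired t-test on the replicate ΔCT
values — pairing on the log (CT) scale, where the normality assumption is
conventional. Zero-variance difference vectors are degenerate: all-zero
differences report p = 1, constant non-zero differences report the smallest
positive float, both flagged with warnings.

## Synthetic-data generators

**Cell lines.** Counts are negative-binomial (Var = μ + φμ², φ = 0.05 by
default) around log-normal baseline means, with log-normal library-size
factors (σ = 0.1) — the standard bulk RNA-seq error model assumed by
moderated DE callers. Three planted, disjoint gene sets define the truth:
module genes shift their mean (by 2^±effect, sign drawn per gene) only in
the module-carrying line at 32 °C; tsp53 genes shift identically in both
tsp53-carrying lines at 32 °C (so the control filter must remove them);
temperature genes shift in the module-carrying line at both temperatures
(so the 32 °C-exclusivity filter must remove them). Default effect size is
|log₂FC| = 3 at 3 replicates per condition.

**Cohorts.** Expression is standard normal per gene, independent across
genes. Event times are exponential proportional hazards with linear
predictor Σ β_g x_g + covariate terms; censoring is independent exponential
plus an administrative horizon. Defaults chosen once as a realistic
paediatric-oncology shape: baseline hazard 0.1/yr (≈39 % cumulative event
probability by 5 years at the baseline), censoring rate 0.05/yr, horizon
10 years. Covariates share a latent standard-normal risk factor
(correlation 0.5), giving marginals MYCN amplified 20 %, age ≥ 18 months
55 %, INSS stages 1/2/3/4/4S = 20/15/20/35/10 % (a roughly uniform-leaning
mix with a stage-4 plurality, matching the character of the training cohort
the model family targets), favourable histology 50 %. Default covariate
log-hazard ratios: MYCN 0.7, age ≥ 18 months 0.5, 0.3 per ordered INSS step.

**What the generators do not emulate** — and hence what passing tests do not
show about real data: probe-level noise and annotation ambiguity, batch and
platform effects across cohorts, gene–gene correlation (real co-expression
would inflate screen collinearity), non-proportional hazards, informative
censoring, and read-level sequencing artefacts. Recovery rates measured here
are upper bounds on what identically parameterised real data would give.

A note on effect planting: hazards are non-collapsible, so planting many
per-gene effects jointly attenuates every *marginal* per-gene hazard ratio
below its conditional value. The screen-recovery study therefore plants its
per-gene log-HR of 0.5 on a 10-gene subset of the 35-gene family, where the
marginal effect stays near nominal; planting all 17 signature genes at once
would measure the screen under materially weaker marginal effects than the
stated condition.

## Numerical conventions and edge cases

* Strict inequalities throughout the decision rules (Bonferroni selection,
  3× ratio filter, median split, module activation) with documented
  boundary behaviour (ties to low risk; zero z-scores inactive).
* Log-rank ties: events at identical times are handled by the standard
  hypergeometric formula; Cox ties by Efron's approximation.
* All-censored inputs: forests refuse to fit; KM returns S ≡ 1; cohort
  generators warn (`DegenerateCohortWarning`).
* Determinism: every stochastic component takes an explicit seed;
  `numpy.random.SeedSequence` keying makes forests invariant to feature
  order and the pipeline manifest byte-reproducible.
* Problem sizes in the simulation studies (cohorts of 100–500, 20 seeds,
  1000 calibration replicates, 2000-gene count matrices) were chosen to keep
  Monte-Carlo error comfortably inside the asserted margins while remaining
  quick to re-run.

## Known limitations

* The DE caller is a single moderated-t implementation; it stands in for a
  multi-package consensus only through the pluggable caller/CSV interface.
* The time-dependent ROC estimator is the KM-weighted one; it can be locally
  non-monotone under heavy censoring (a known property of the estimator),
  and no nearest-neighbour smoothing is provided.
* The forest has no surrogate splits: prediction requires every training
  feature to be present.
* Cox fits are univariate by design (the screen's job); no multivariable or
  penalised models are included.
* The qPCR module assumes perfect amplification efficiency (no
  efficiency-corrected variant).
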