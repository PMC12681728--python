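# Methods

## The screening problem

Glucose-6-phosphate dehydrogenase (G6PD) deficiency is an X-linked
enzymopathy that shortens erythrocyte lifespan. Because HbA1c accumulates
over a red cell's life, carriers of the common African-ancestry variant
p.Val68Met (rs1050828-T) show HbA1c values systematically *below* what
their true glycemia would predict — a bias that can lead to diabetes
undertreatment. Almost no carriers have a clinical deficiency diagnosis,
so the package implements a screen built entirely from routine labs:

* **Estimated average glucose** eAG = 28.7 × HbA1c − 46.7 (mg/dL), the
  standard linear glycation relationship. Units are fixed at mg/dL and
  NGSP %; no mmol/L or IFCC conversion is attempted because the constants
  are scale-specific. Operations never round; rounding is left to report
  formatting so that the identity gap + eAG = glucose holds to 1e-9.
* **Glucose gap** GG = measured glucose − eAG. Short-lived red cells push
  the gap upward (HbA1c under-reports), so carriers cluster at less
  negative gaps.
* **RDW**, the red cell distribution width, is treated as a unitless
  numeric on the clinical RDW-CV scale (values ~13–14, threshold 12);
  thresholds are applied on that scale without conversion.
* The **glucose/HbA1c ratio** is retained as a published comparator score.

The decision rule combines `RDW ≤ 12` and `GG ≥ −15`:
**possible** deficiency is the inclusive OR (screening-oriented),
**likely** the AND (confirmation-oriented); likely ⊆ possible by
construction, and both comparisons are inclusive at the boundary.
Thresholds are parameters with these operating points as defaults.

## Cohort construction

A draw is one row with all three concurrent analytes; analytes are never
merged across dates. Draws missing any analyte are dropped (and counted)
first. When fasting is not assured, draws with glucose < 70 or > 200
mg/dL are excluded — strict inequalities, so 70 and 200 are retained;
a per-cohort `fasting_assured` switch bypasses the filter for cohorts
where participants were asked to fast (low values are then informative
rather than artefactual). The index draw is the eligible draw with the
lowest glucose (most likely fasting); ties break to the earliest date,
then input order, making selection deterministic. Every build emits an
exclusion ledger (`no_genotype`, `missing_labs`, `no_eligible_draw`,
`retained`) whose counts partition the input; `ExclusionLedger.check()`
enforces the reconciliation. Phenotype flags (diabetes, G6PD diagnosis)
are pre-computed booleans in the input tables; mapping diagnosis codes to
flags is the caller's concern.

## Genotypes and Hardy-Weinberg checks

Zygosity is a pure function of (sex, allele count): males {0,1} →
ref/var hemizygote, females {0,1,2} → ref homozygote / heterozygote /
var homozygote. The VCF reader accepts both haploid ("1") and
homozygous-diploid ("1/1") male encodings — both occur in the wild — and
rejects male heterozygous calls loudly with the sample id rather than
silently coercing, since such calls indicate data corruption. Allele
frequency is estimated by allele counting with X ploidy (males 1,
females 2). Under X-linked HWE at frequency q the expected class
frequencies are q (male hemizygotes), 2q(1−q) (heterozygotes) and q²
(female homozygotes); the q → q² identity doubles as a consistency check
on observed cohort frequencies. Heterozygote excess above HWE, which
real biobank frequencies hint at, is deliberately not modelled: there is
no generative account to implement, so HWE is both the simulator's law
and the only identity asserted.

## Threshold learning

The learner is an axis-aligned recursive partition (depth ≤ 2, Gini
impurity, exhaustive search over midpoints of consecutive sorted unique
values, ≥ `min_leaf` = 20 samples per side). Carriers are a ~10–15%
minority, so splits are scored with balanced class weights
(w = n/(2·n_class)) by default; unweighted Gini would favour trivial
splits. Ties in impurity decrease break toward the smaller threshold,
so the fit is deterministic given the input order and configuration.

Two design points deserve note:

* **Marginal threshold extraction.** The reported rule has one cut per
  feature. The root split is by definition the marginal balanced-Gini
  cut for its feature, but a second-level split is conditioned on the
  root cut, which skews the class mix inside the child and drags the
  second threshold away from its population-level operating point (in
  simulation, the conditional GG cut lands near −25 instead of the
  planted −15, or becomes unstable when the carrier-poor child wins on
  impurity). `learn_rule` therefore reports each feature's threshold
  from its own root-level balanced split. The depth-2 partition is still
  fitted: its leaf-wise training positive fraction is the model's
  continuous score, which feeds the AUROC.
* **The learner reports; it does not overrule.** Learned cuts are for
  inspection and sensitivity analysis; `LearnedRule.criteria()` only
  substitutes them for the published defaults when the caller opts in.
  The label set used in training (male hemizygotes only vs pooled
  carriers) is a flag, since either convention is defensible.

## Evaluation

Three detection tasks mirror the zygosity classes a screen could target:
male hemizygotes, female homozygotes, and females with ≥ 1 variant
allele. Per (task × cohort × criterion) cell: precision = TP /
test-positives, recall = TP / genotype-positives, prevalence =
genotype-positives / N. Empty denominators yield NaN plus an explicit
`*_defined = False` flag — never 0 or 1 — for audit safety. "Overall"
rows pool *counts* across cohorts (TPs add; rates do not), which keeps
the additivity invariant testable.

AUROC is the Mann-Whitney rank statistic with midrank tie handling
(delegated to `sklearn.metrics.roc_auc_score`; an independent brute-force
pairwise oracle backs it in the tests). Its uncertainty is the standard
deviation of the statistic over a seeded nonparametric bootstrap
(default 1000 resamples); single-class resamples are skipped. The score
for the two-lab model is the fitted partition's leaf positive fraction —
the natural score of a recursive-partitioning classifier.

## Survival stage

Time runs in years from diabetes diagnosis to incident retinopathy,
censored at death or end of follow-up. "20-year rates" are Kaplan-Meier
cumulative incidences 1 − S(20) (lifelines product-limit estimator), not
crude proportions; if follow-up ends before the horizon the last
estimate is carried forward with a warning. Each criterion (possible,
likely) is contrasted against its own complement in a separate Cox
proportional-hazards model — two two-level models, not one three-level
factor — adjusted for age, sex, smoking, diabetes duration, LDL and
hypertension. The reported "general population" incidence uses the
complement of the possible criterion, the broadest reference. The Cox
fit uses statsmodels' `PHReg` partial-likelihood maximiser with Efron tie
handling by default (year-resolution times tie often) and a Breslow
switch for comparison; Wald CIs and p-values are reported. A 1-D
brute-force partial-likelihood maximisation serves as the oracle in the
tests. The absolute risk difference between a stratum and its reference
converts to a number needed to harm, NNH = 1/RD, defined only for
RD > 0 and otherwise flagged.

## Synthetic cohort generator

No public data carry this structure, so the generator is first-class,
tested code. Per participant: sex ~ Bernoulli(0.5); allele count
Bernoulli(q) for males and Binomial(2, q) for females with q = 0.12
(inside the 0.088–0.154 range the cohort frequencies span); diabetes ~
Bernoulli(0.3); habitual mean glucose Normal(90, 8) for nondiabetics and
Normal(150, 30) for diabetics; "true" HbA1c from the inverse glycation
line plus the carrier shift plus Normal(0, 0.25) noise; RDW Normal(13.9,
1.1) plus the carrier shift plus Normal(0, 0.5) per-draw noise. 1–4
draws per participant; each draw is fasting with probability 0.6, and
non-fasting draws add a Gamma(shape 2, mean 40 mg/dL) post-prandial
bump plus Normal(0, 10) measurement noise.

Carrier effects: hemizygotes and homozygotes get the full shifts
(−0.75% HbA1c, −1.8 RDW units); each heterozygote gets both shifts
scaled by one Beta(2, 2) draw — a continuous X-inactivation fraction,
the share of her erythroid compartment expressing the deficient allele.
Using the *same* fraction for both analytes reflects their common cause
(the deficient-cell fraction) and produces the attenuated, heterogeneous
female signal the evaluation should struggle with. The shift magnitudes
are this package's calibration: the −0.75% HbA1c shift maps through the
28.7 slope to ≈ +21.5 mg/dL of glucose gap, enough that desk-scale
cohorts reproduce the qualitative evaluation pattern (high possible
recall and high likely precision for males, weak heterozygote
performance) without making the screen trivially perfect. They are
recorded in the fixture manifest and must not be read as observed
estimates.

Survival: diabetics only; time to retinopathy ~ Exponential with hazard
0.006/year, multiplied by 1.4 for deficiency-affected carriers;
censoring Uniform(5, 25) years. Covariates (age, smoking, duration,
LDL, hypertension) are drawn independently — they are adjustment noise,
not confounders — so the planted hazard ratio is recoverable. A
`cohort_label` column partitions one population into three
pseudo-cohorts to exercise the stratified grid without modelling four
distinct biobanks.

What the generator does **not** emulate: longitudinal glycemic
trajectories, treatment feedback (therapy intensification driven by the
biased HbA1c is implicit in the hazard ratio, not mechanistic),
heterozygote excess over HWE, and confounding between labs and survival
covariates. Passing tests therefore demonstrate internal consistency of
the pipeline under its stated generative assumptions, not performance on
real EHR data.

## Numerical and reproducibility choices

Everything stochastic flows from one `numpy` `default_rng` seed; equal
seeds give byte-identical fixtures. Default problem sizes (4,000–8,000
participants for end-to-end checks, 5,000 for hazard-ratio recovery, 10
seeds for learner recovery) are chosen so that planted-parameter
recovery is well inside sampling tolerance while the whole suite runs in
well under a minute of simulation time. Degenerate inputs fail loudly:
single-class labels, constant covariates, empty draw sets, male diploid
heterozygotes, out-of-range frequencies and rates all raise typed
errors rather than returning coerced values.

## Known limitations

* RDW is printed in "fL" in some sources at values that match the
  dimensionless RDW-CV scale; the package treats it as unitless and
  makes no attempt to reconcile units.
* The learner recovers thresholds only when the two classes are
  separated along each axis; heavily overlapping features return weak
  splits (small impurity decreases) that callers should prune.
* Bootstrap SD is one defensible uncertainty for the AUROC; it is not a
  cross-validated spread.
* The survival stage assumes proportional hazards and does not model
  death as a competing risk.

(The base hazard 0.006/year was chosen so the reference 20-year
incidence, 1 − exp(−0.12) ≈ 11.3%, sits in the low-teens range typical
of diabetic-retinopathy cohorts.)
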