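# Methods

This note documents the generative model, the fixed analysis pipeline, the
calibration and numerical choices, and what the synthetic setting does and
does not demonstrate.

## The synthetic cohort model

The generator emulates a **high-risk antenatal clinic population** assessed
in the first trimester. It is hierarchical; each stage draws from an
independent named substream of one root seed, so adding draws to one stage
never perturbs another.

**Demographics.** Age ~ Normal(28, 5) years clipped to [18, 45]; BMI ~
Normal(24, 4) kg/m² for age < 30 and Normal(26, 4) for age ≥ 30, clipped to
[16, 45]; booking gestational age ~ Normal(10.2, 2.3) weeks clipped to a
[6, 14]-week first-trimester window; ethnicity categorical with
probabilities (Caucasian .40, Asian .25, Hispanic .15, African .12,
Other .08). Truncation is by **clipping**, not resampling: the bounds sit
≥ 2 SD from every mean, so the boundary point mass is small (≈2% at the
tightest bound) and the means move by < 0.05 units, while the sample SD
shrinks slightly (age SD ≈ 4.9 rather than 5) — both effects are part of the
emulated statistics. Resampling was rejected because it shifts the mean of
asymmetrically bounded variables by several tenths.

**Composite risk score.** `S = 0.1(age−25) + 0.15(BMI−23) + 1.5·family_hx +
2.0·prev_gdm + 1.0·PCOS + 1.2·prev_macrosomia + 0.8·[Asian or Hispanic]`.
All weights are config fields. S may be negative for young, lean patients.

**Risk factors.** Each binary factor is Bernoulli with individual
probability `expit(a + τ(s_i − s̄))`, where `s` is the demographic portion
of the score and τ (`flag_tilt`, default 0.3) makes high-risk demographics
more likely to carry the factor. The intercept `a` is solved per cohort by
root-finding so the **marginal prevalence equals the configured value**
(family history 25%, previous GDM 12%, PCOS 15%, previous macrosomia 10%)
regardless of τ; τ = 0 recovers independent flags. Parity is not modelled:
previous-GDM and previous-macrosomia prevalences are treated as marginal
over the whole cohort rather than conditional on multiparity.

**Laboratory values.** Each analyte is `Normal(μ₀ + β·S, σ₀)` clipped to
its clinical range. The shift coefficients β (RBS 4.0, PPBS 5.0, HbA1c
0.15, OGTT fasting 2.0, 1-h 5.0, 2-h 4.0 per score unit) are fixed design
constants giving moderate score–lab correlations (r ≈ 0.3–0.4); μ₀ and σ₀
are **calibration constants** solved by fixed-point iteration at n = 400,000
so the realized cohort marginals match the target statistics: RBS
109.1 ± 18.8, PPBS 142.5 ± 24.2 mg/dL, HbA1c 5.72 ± 0.58%, and OGTT means
98.5 / 181.4 / 156.3 mg/dL **among the tested subset**. The OGTT is
administered selectively: the top 29.5% of patients ranked by risk score
plus Gumbel(0, 1) selection noise are tested (softening the hard cutoff);
everyone else carries missing OGTT values, all three or none per patient.

**Outcome.** GDM ~ Bernoulli(p) with
`p = clip(0.10 + c·S + ΔRBS + ΔPPBS + ΔHbA1c + 0.40·[any OGTT criterion], 0, 0.95)`.
Threshold increments are read as **absolute probability additions**, and
within one analyte only the single highest crossed tier applies (otherwise
an HbA1c of 6.6% would add 0.85 alone); increments across analytes sum.
A multiplicative reading was rejected because the documented risk model is
a sum. The score-to-probability coefficient `c` is the one remaining free
parameter; it is calibrated (secant iteration at n = 400,000) to
`c = 0.2628` so the enriched cohort lands at ≈ 65% GDM-positive. A
general-population profile (≈10–35% positive) is a config change, not a
code change.

**Consequence of the calibration.** Since p is a deterministic function of
observable features, the Bayes accuracy of the outcome model is
`E[max(p, 1−p)] ≈ 0.82`, with ≈ 38% of records at the 0.95 cap. Benchmark
accuracies must sit below this ceiling; observed test F1 scores
(0.69–0.79 on the top-10 feature space) are consistent with it.

## Fixed pipeline order and preprocessing

encode → impute → split → standardize → SMOTE(train only).

- One-hot ethnicity with **drop-first**: African is the all-zeros reference;
  four indicators (Asian, Caucasian, Hispanic, Other).
- Missing OGTT cells are zero-imputed **before** scaling, deliberately
  creating a three-state encoding (elevated / normal / not tested ≙ 0);
  zero-imputed columns are then scaled together with the other continuous
  features. Mean/median or multiple imputation would erase the clinically
  meaningful "not tested" signal.
- Stratified 80/20 split with the fixed seed 42; per-class allocation uses
  largest-remainder rounding (ties broken by class label order), so a
  10,000-row cohort always splits 8,000/2,000 with class proportions
  preserved within one record.
- Standardization (z-scores, population moments) is fitted on the training
  partition only; binary flags and ethnicity indicators are excluded to
  preserve their 0/1 semantics.
- SMOTE (in-package) oversamples the minority class to exact parity:
  `x_new = x + u(x_nn − x)`, u ~ U(0,1), x_nn one of the k = 5 nearest
  minority neighbours (Euclidean, post-scaling space). It runs on the fully
  encoded matrix, so synthetic rows may carry fractional flag values — an
  accepted artefact; a categorical-aware variant is out of scope. Original
  rows are preserved verbatim.

## Consensus feature importance

Seven methods, each min–max normalized to [0, 1] per method for
comparability (an all-equal raw vector maps to all ones): forest and
extra-randomized-trees Gini importance (100 trees each), ANOVA F-score,
mutual information (k-NN estimator, k = 3, seeded), permutation importance
(accuracy decrease, 10 seeded repeats, random-forest base model), recursive
feature elimination (logistic base estimator), and absolute Pearson
correlation (point-biserial for binary features; a constant feature scores
0 with a warning). Importance is computed on the SMOTE-balanced training
matrix by default; passing the pre-SMOTE partition is a one-argument
switch.

Numerical choices: RFE is run down to a single feature so every feature has
a distinct elimination position, scored `(p − position + 1)/p`; permutation
shuffles are evaluated on a seeded subsample of ≤ 2,500 training rows (the
estimator stays unbiased, the cost drops ~4×); rank SDs use fractional
(average) ranks so ties are shared; the consensus table sorts by average
importance with ties broken by lower rank SD, then name. Consensus is
invariant to method order and to any uniform monotone rescaling applied
before normalization.

**Stability caveat.** The top-2 consensus features (HbA1c, BMI) are stable
across seeds. The third slot is a near-tie by construction: the stated
weights and prevalences give family history and previous GDM *identical*
linear effect sizes (w²·p(1−p) = 0.422 for both) and maternal age a
comparable aggregate effect through its direct weight, the BMI
stratification and the flag tilt. Across 20 seeds the third slot usually
goes to age (13/20) and otherwise to family history (7/20). Any analysis
that depends on the identity of rank 3 should treat it as unresolved.

## Benchmark

Eleven models with fixed architectures: forests (≤ depth 15), boosting
(≤ depth 6, learning rate 0.1), tree counts in [100, 200]; logistic
regression; k-NN; Gaussian naive Bayes; RBF-SVM with sigmoid (Platt)
probability calibration fitted on training folds; an MLP with hidden
layers (100, 50); and a deep network 128→64→32→16→1 implemented as a
five-layer perceptron with L2 regularization (α = 10⁻³) in place of
dropout/batch-norm. Neural models use a 20% internal validation split,
early-stopping patience of 20 epochs, batch size 32, and adam's adaptive
step sizes. Grid search (weighted F1, 10-fold stratified CV, training
partition only) is optional: the default grids are small and data-driven
(`DEFAULT_GRIDS`), and a singleton/empty grid is exactly plain training, so
both the "fixed hyperparameters" and the "search for all algorithms"
protocols are supported.

Models are trained on the balanced top-10 consensus feature space and
evaluated once on the untouched imbalanced test partition at a fixed 0.5
threshold. Metrics: per-class precision/recall/F1 from hand confusion
arithmetic (zero denominators reported as undefined, never 0),
support-weighted aggregates, and AUC-ROC by the rank/trapezoid method with
midrank ties. Support-weighted recall ≡ accuracy in the binary case; this
identity is asserted on every `MetricsRow`. Leaderboard order: weighted F1
desc, then AUC-ROC, then name.

## Attribution

Shapley values under the **background-marginal value function**: v(S) is the
mean model output with coalition features from the instance and the rest
filled row-wise from a 100-row background sample (plain rows, no
clustering). Estimation is the kernel weighted-least-squares formulation
with the additivity constraint eliminated exactly, so **local accuracy is
exact by construction** (observed gaps ~1e-16; the contractual tolerance is
1e-2). With a coalition budget ≥ 2^p − 2 the coalitions are enumerated and
the result equals the exact Shapley value; under a budget, coalition sizes
are enumerated outside-in while they fit and the remainder is sampled in
proportion to kernel mass (default budget 2,048 per instance; a budget
below p + 2 raises, as the regression is underdetermined). A brute-force
2^p enumerator (`shapley_brute_force`) serves as the independent oracle in
tests for linear closed forms, dummy/symmetry axioms and p ≤ 4 toy models.
Explain sets: background = simple random sample; explained instances =
stratified sample with exact per-class counts (default proportional to the
test class mix; the 33/66% positive-heavy profile is a parameter).

## Clinical tiers

One shared constants table defines, per analyte, the ordered inclusive
boundaries (RBS 125/140; PPBS 160/180; HbA1c 5.7/6.0/6.5; OGTT fasting 92,
1-h 180, 2-h 153) used by both the tier classifier and the simulator's
increments, so "increment fires ⇔ tier reached" holds identically — this is
tested on a dense grid. Classification is total over each valid range and
monotone in the value; out-of-range or missing values raise rather than
silently tier.

## What passing tests do and do not show

The simulator reproduces the *marginal* statistics and the threshold
structure it was calibrated to; models recover relationships the generator
put in. Passing tests therefore demonstrate correctness of the machinery —
leakage-safe preprocessing, metric arithmetic, attribution axioms,
calibration fidelity — not clinical validity. Real cohorts have
measurement error, correlated missingness, parity structure, longitudinal
drift and unknown outcome mechanisms that this generator deliberately lacks;
relative feature importances and absolute performance numbers must be
revalidated on real data.

## Problem sizes and determinism

Default study profile: n = 10,000 (8,000/2,000 split; ~10,300 rows after
SMOTE). The full fixed-hyperparameter pipeline runs in ~2 minutes on one
CPU; grid-searched 10-fold CV is several-fold slower and intended for
scripted runs. Statistical test batteries use 20 seeds at n = 10,000 for
simulator marginals and consensus stability, and a 1,000-patient smoke
profile (examples/07) that completes in under a minute. Every stochastic
component is seeded; identical configs yield byte-identical artifacts and
manifest checksums.
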