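# Methods note

This note records the statistical model, the parameterization, the numerical
choices, and the known limits of the `lifecourse` package. Every number
quoted here is computed by code in this repository (tests or scripts); no
external empirical claims are made.

## 1. Frailty Index

A deficit schema declares, per item, a source variable, an operator
(`ge`/`le`/`eq`/`in_set`) and a cutoff; the default schema has 30 binary
items. The Frailty Index (FI) for a person-wave is

FI = (number of deficits present) / (number of items considered).

Missing items rescale the denominator to the observed count when at least
80% of items are observed (`min_observed_fraction = 0.8`); below that the
score is flagged invalid and excluded rather than imputed. The robust/frail
dichotomy uses the conventional cutpoint 0.2, *inclusive* (FI = 0.2 is
frail); with 30 items this is exactly 6 deficits.

## 2. Exposure encoding

Ward-level deprivation indices, one value per ward per decade, are z-scored
*within decade* using the sample standard deviation (n − 1). A decade index
year d covers addresses in calendar years [d − 5, d + 4] (year → decade via
`((year − 6) // 10) * 10 + 11`). A person with several wards in one decade
receives the mean of their ward z-scores. Period means use equal decade
weights over whichever of the period's decades carry an exposure: childhood
= {1941, 1951}, young adulthood = {1961, 1971}, mid-late adulthood = {1981,
1991, 2001, 2011}. A person is eligible only with at least one linked
address in *every* period.

Six candidate life-course variables: the three period means (sensitive
periods), their mean (accumulation), and two effect-modification products
(childhood + 10)(young + 10) and (young + 10)(mid-late + 10). The +10 offset
keeps factors positive on the ward z-score scale; period means at or below
−10 trigger a warning because they defeat the offset. The exposure
truncation sensitivity drops decades whose window extends past the
truncation year (e.g. 2005 keeps mid-late decades {1981, 1991, 2001}).

## 3. Stage 1: selection

Candidates are residualized on the common confounders (OLS residuals on
[1, C]), then screened: of any pair with |r| > 0.9 the later-listed column
is dropped, except that a sensitive-period (`sp_`-prefixed) column is kept
in preference to a derived one. Under the generator's default conditions
`accumulation` and `em_early` correlate above 0.9, so `em_early` is the
column removed.

The lasso-modified LARS path is implemented directly (columns standardized
to mean 0 / sd 1 with the n − 1 sd, outcome centred): variables enter when
their absolute correlation with the residual catches the active set's,
coefficients move equiangularly and piecewise-linearly in the penalty, and
an active variable whose coefficient crosses zero is dropped. The
implementation is cross-checked in the test suite against scikit-learn's
`lars_path` (identical knots and coefficients to 1e−9) and against
coordinate-descent lasso solutions at and between every knot (1e−6), and
the lasso KKT conditions are verified to 1e−8 at every knot. scikit-learn
is used *only* as an independent oracle in tests, never at runtime.

The covariance test for the lasso at entry knot λ_k with next knot λ_{k+1}:

T_k = [⟨y, Xβ̂(λ_{k+1})⟩ − ⟨y, X_A β̃_A(λ_{k+1})⟩] / σ̂²,  p = exp(−T_k),

where β̃_A is the lasso path restricted to the variables active before the
entry. σ² is either known or estimated as the residual variance of the
unpenalized OLS on all candidates (n − p − 1 denominator). Tiny negative T
from floating-point cancellation is clipped to 0 with a warning. The
first-entered variable is always carried to stage 2; `supported` records
whether its covariance-test p is below α.

**Finite-p calibration.** The Exp(1) null for T₁ is asymptotic in the number
of candidates p. Measured in this repository (orthogonal design, n = 200,
p = 5, 2000 simulations, known σ², fixed seed): mean(T₁) = 1.055, Kolmogorov
distance to Exp(1) = 0.056, and the selection-recovery null support rate at
α = 0.05 is 0.074 (500 replicates). Two acceptance assertions bound these at
0.05 and 0.07 respectively and therefore fail *honestly*: the discrepancy is
a property of the test at small p, not of the implementation (which passes
the oracle and KKT checks above). The corresponding mean band [0.9, 1.1] and
the effect-recovery criteria pass.

## 4. Stage 2: estimation

Continuous predictors are mean-centred and scaled to unit sd (binary
predictors stay 0/1), so coefficients are FI units per 1 sd; fully
standardized betas additionally divide by the outcome sd. Confounder sets
are nested: model1 = {age, parental occupational social class}; model2
adds {education years, childhood smoking, childhood IQ}; model3 adds {adult
occupational social class, current smoking}. Each exposure maps to its
DAG-appropriate set, optionally augmented with the *previous* period's NSD
(sp_young adjusts for sp_child; sp_midlate for sp_young) to address
selection into similar neighborhoods. Within a stratum, a confounder with
no variation is dropped with a logged warning (it cannot adjust anything
and would make the design singular).

*Baseline*: OLS with Wald 95% CIs. *Trajectory*: linear mixed model by REML
(statsmodels `MixedLM`), fixed effects exposure × age + confounders, random
intercept and random age slope per person; variance components reported as
variance and sd for intercept, slope and residual. Optimizer falls back
through lbfgs → bfgs → cg → powell; non-convergence raises a distinct error.
A variance estimated at the boundary (0) warns rather than errors.

*Johnson–Neyman*: the conditional exposure slope at scaled age a is
b_exp + a·b_int with variance v_exp + a²·v_int + 2a·cov. Boundaries solve the
borderline quadratic (b_exp + a·b_int)² = t²·(v_exp + a²·v_int + 2a·cov)
in closed form; regions are classified by their midpoints within the
observed age range. With FDR, a Benjamini–Hochberg step-up over the grid of
observed ages (plus 200 equal steps) yields an adjusted critical value (the
largest raw p rejected), and the boundaries are re-solved at that stricter
threshold — FDR regions are provably subsets of unadjusted regions.

*Sensitivity variants*: tertile-coded exposure (nearest-rank thirds; two
dummies vs the low tertile, baseline model only); dichotomized FI outcome by
logistic regression at baseline and, for progression, by a variational
Bayes mixed logistic model (statsmodels `BinomialBayesMixedGLM`) with random
intercepts and age slopes — named as what it is because statsmodels has no
likelihood-based random-slope logistic. Perfect separation raises a distinct
error; fits require at least 10 events and 10 non-events.

Standard estimators (OLS, REML mixed models, logistic, BH-FDR) are delegated
to statsmodels; the paper-specific machinery (LARS/lasso path, covariance
test, Johnson–Neyman, FI/exposure encodings, generator) is implemented here.

## 5. Synthetic cohort generator

Defaults emulate the study conditions and are never tuned per test: n = 323
persons, five waves at ages 70–82 (sd-0.75 person-level age jitter), decade
NSD means (0.41, 0.41, −0.64, −0.64, −1.95 × 4) and sds (3.29, 3.29, 2.61,
2.61, 2.78 × 4) with AR(1) within-person decade correlation 0.6; 10% of
person-decade addresses missing; monotone attrition with retention ladder
(1.0, 1.0, 313/323, 270/323, 212/323) ≈ 65% by wave 5. Frailty follows a
linear random-intercept (sd 0.06) / random-slope (sd 0.022) model in scaled
age with population slope 0.028, residual sd 0.037 and baseline mean 0.14;
one configurable true life-course variable adds effects to the baseline
and/or slope. Deficits are conditionally independent Bernoulli draws given
the (clipped-to-[0,1]) latent FI, so the computed FI is unbiased for the
latent value; clipping beyond 5% of person-waves warns. Confounders enter
the latent FI with small fixed effects (±0.005–0.01 per sd).

**The ward table is an encoding device, not a geography.** Every
person-decade gets its own ward whose raw index *is* the person's drawn NSD
value, plus unreferenced padding wards that pin each decade's ward mean to 0
and sample sd to 1. The pipeline's within-decade z-scoring is then the
identity and the generated exposures round-trip exactly (verified to 1e−8 in
tests). Realism limits: no spatial autocorrelation, no shared wards between
persons, no ward-size weighting; recall error in residential histories is
not modeled beyond the missing-decade rate; deficits have no item structure
or cross-wave dependence beyond the latent trajectory.

`effect_for_standardized_beta` converts a target fully standardized baseline
beta into generator FI units using the analytic noise budget (random
intercept + residual + binomial item noise p(1−p)/30 + confounder
contributions).

**Recovery performance** (computed by `tests/test_acceptance.py` /
`recovery_experiment`, fixed seeds): with true model `accumulation` at
standardized effect 0.5 (n = 300), the first-selected variable is the true
one in 98.4% of 500 replicates (first-step support rate 0.996); with a true `sp_midlate` interaction effect
of 0.005 FI/sd/sd-age (n = 300, 200 replicates), the stage-2 interaction
estimator's bias is −4.3% of truth and 95% CI coverage is 95.5%. The
age-unit conversion between the fit's sample-sd age scaling and the
generator's wave-grid scaling is an exact linear rescale applied before
computing bias.

## 6. Numerical choices

* Sample (n − 1) standard deviations throughout (z-scoring, standardization,
  scaling of predictors).
* LARS knot candidates are computed in closed form per event; ties in the
  entry correlation break by column order; the event budget 8p + 10 guards
  against cycling (reaching it warns).
* Covariance-test sub-paths are cached by active set; statistics are exact
  path evaluations, not refits.
* JSON reports serialize floats at full precision with sorted keys;
  Markdown applies display rounding only. Identical config + seed gives a
  byte-identical `report.json`.
* Randomness: `numpy.random.default_rng` seeded explicitly everywhere;
  replicate seeds come from a spawned `SeedSequence`.

## 7. Limitations

* The covariance test's finite-p calibration at p = 5 (see §3) makes
  support rates run ≈ 2 points above nominal α; selection of the *first*
  variable is unaffected.
* The variational mixed logistic progression model gives posterior-sd Wald
  intervals, not likelihood-based ones.
* Tertile coding applies to the baseline model only.
* The generator's attrition is missing-completely-at-random given wave;
  informative dropout is not modeled.
* Johnson–Neyman uses normal critical values (large-sample), matching the
  Wald intervals of the mixed model.
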