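# Methods

This note documents the models implemented in `hefi_cvd`, their defaults,
the numerical choices, and what the synthetic-data experiments do and do
not establish.

## 1. HEFI-2019 scoring

Each of the 10 components converts a ratio or density into points allocated
proportionally between a zero-credit and a full-credit cutoff:

    higher-better: points = max · clamp((r − r₀) / (r₁ − r₀), 0, 1)
    lower-better:  mirrored

The engine is cutoff-agnostic: component definitions live in
`hefi_cvd/data/hefi2019_standards.yaml` (name, ratio, direction, cutoffs,
maximum). The packaged defaults transcribe the published HEFI-2019
standards — 5 food components (Vegetables & fruits 20 pts; Whole-grain
foods 5; the whole-grain share of all grains 5; Protein foods 5;
Plant-based protein foods 5), 1 beverage component (10), and 4 nutrient
components (fatty-acid ratio 5; saturated fat %E 5; free sugars %E 10;
sodium density 10), 80 points total. Nutrient-energy conversions use
9 kcal/g fat and 4 kcal/g sugar.

*Zero denominators* (e.g. no food reported): the component scores 0 and a
flag is raised — the conservative convention; the flags keep it auditable
and a different standards file can redefine the component.

## 2. Derived inputs

**Sodium.** The recall instrument reports no sodium; 24-h sodium intake is
predicted from a casual urine assay with the INTERSALT sex-specific
equations (spot Na/K/creatinine in mmol/L, BMI, age; the female equation
has an age² term), coefficients shipped in `data/intersalt.yaml`,
converted at 23 mg/mmol and floored at zero with a flag. The predicted
value is treated downstream as an error-free person-level covariate.

**Free sugars** = max(0, total sugars − Σ natural-sugar factors ×
category amounts) over vegetables, fruits, dairy and legumes.

**Energy-reporting plausibility**: ratio of reported energy to a predicted
requirement; plausible within the closed interval [0.74, 1.26]. The
requirement uses a Mifflin-St-Jeor-type resting expenditure evaluated at
sex-typical stature (weight recovered from BMI) times an activity-level
PAL of 1.4/1.6/1.8 — a documented, swappable convention.

## 3. Measurement-error correction (usual intakes)

Per component, a two-part random-intercept model with person-level
covariates x_i (all baseline covariates plus predicted sodium):

* consumption part (episodic components only):
  P(consume on a recall) = Φ(x_iγ + u_i^p), u^p ~ N(0, σ_p²), fit by
  marginal maximum likelihood with 21-node Gauss–Hermite quadrature;
* amount part: Box-Cox(λ)-transformed positive amounts
  g(y_ij) = x_iβ + u_i^a + e_ij, e ~ N(0, σ_e²), fit by exact ML with β
  profiled out by weighted least squares — because covariates are
  person-level, the person mean and within-person sum of squares are
  sufficient, which reduces the fit to a 2-parameter optimization. λ is
  chosen by Jacobian-adjusted profile likelihood on the grid
  {0, 0.25, 1/3, 0.5, 1} (ties broken toward 1/3).

The cross-part covariance Σ_u — the multivariate ingredient — is assembled
from empirical-Bayes predictions: the correlation matrix of the per-part
BLUPs (posterior means for probit parts), eigen-clipped to positive
semi-definite, rescaled so each part's SD equals its model estimate (the
shrinkage-inflation correction).

**Conditional Monte Carlo.** For each person, the vector of random effects
is drawn from N((Σ_u⁻¹+T)⁻¹ T m, (Σ_u⁻¹+T)⁻¹), where each part contributes
a Gaussian pseudo-observation (m_k, τ_k): exact conjugate form for amount
parts (person-mean residual with precision n_i/σ_e²), Laplace
approximation of the probit likelihood for consumption parts. Per draw,
usual intake = Φ(x_iγ + u^p) × [g⁻¹(x_iβ + u^a) + ½ g⁻¹''(·) σ_e²] (the
second-order bias-corrected inverse transform; exact for λ=1, within 1% of
the lognormal mean for λ=0 and σ² ≤ 0.2; values outside the transform's
domain floor at 0). Each draw is scored with the HEFI-2019 engine and
results are averaged across M draws (default M = 1000; analyses at desk
scale use 10–200, where the Monte-Carlo SE of the mean score is a fraction
of a point). Marginal (covariate-only) draws are available as an option.

**Known property.** Averaging conditional draws yields posterior means,
which are slightly *shrunk* relative to the true usual-intake
distribution; single recalls are *inflated* by within-person noise. For
unbounded quantities (component intakes) the modeled variance lands
between, close to truth. The 80-point-bounded score does not inherit the
ordering mechanically — clamped components compress under noise — so the
score-level check is correlation with the latent truth, which the
correction improves markedly.

## 4. Weights

IPTW for the continuous score uses the "standard normal" density approach:
regress the mean usual score on all confounders (continuous covariates
expanded as restricted cubic splines with 4 knots at percentiles
5/35/65/95; energy excluded — it belongs to the outcome model), then

    sw_i = φ(a_i; ā, s²) / φ(a_i; x_iβ̂, σ̂²)

IPCW: logistic model for remaining uncensored (censoring = competing
non-CVD death or loss; administrative end of study is non-informative);
weight = marginal/conditional probability. Both factors are rescaled to
mean 1 ("stabilized to the sample size") and multiplied. Truncation is off
by default (a symmetric percentile cap is available and recorded in
flags); the weight table carries min/mean/max diagnostics.

*Limitation (documented, observed in the synthetic experiments):* when the
true conditional law of the score is skewed — which happens whenever
bounded component scores clamp — the normal-density weights under-correct
in the skewed tail and single extreme weights can dominate small samples.
At the generator's defaults the weighting removes essentially all
confounding bias from the linear dose-response by n ≈ 50,000 and most of
it at n = 10,000–20,000; percentile contrasts deep in the lower tail
(5th/10th) retain residual bias at desk scale.

## 5. Outcome models and contrasts

Weighted Cox proportional-hazards regression (lifelines; Efron tie
handling — ties are rare at the generator's continuous event times; robust
sandwich covariance) on restricted-cubic-spline bases (4 knots) of the
usual score and of usual energy. Counterfactual risks: 1 − S(132 months |
score = s_p, energy = reference), read from the fitted model at each
prespecified percentile; the reference energy defaults to the weighted
mean (≈2100 kcal under the generator defaults) and is overridable. The
reference (median) row is RD = 0, RR = 1 exactly by construction. A
hand-computed weighted Breslow baseline reproduces the lifelines risks at
the fitted coefficients (tested) and supports re-evaluating the table
under perturbed coefficients in the bootstrap. The HR curve spans
percentiles 1–99 of the score (no extrapolation), HR(median) = 1.

Discrete-time analogue: person-period split (default 1 month), pooled
logistic hazard with an RCS(5 knots) in time, RCS(4) in score, a
centered/scaled score-by-time interaction and standardized energy;
per-stratum risks are products of conditional survivals. In the
rare-event, fine-grid limit the risks agree with the Cox route to well
under 5% relative (tested); between-stratum Wald tests for equal RR use
standard errors obtained by simulating the fitted coefficients' asymptotic
normal law.

Proportional-hazards diagnostics: re-fits over nested follow-up windows
(default 3/5/8/11 years) with a fixed-contrast HR per window, plus the
Schoenfeld-residual test on the full fit. E-value: protective ratios are
inverted, E = RR* + √(RR*(RR*−1)); the CI E-value uses the bound closer to
1 and is 1 when the CI crosses it.

## 6. Pipeline and bootstrap

`run_pipeline` executes: single imputation (regression mean for
continuous, mode for categorical; flags kept; per-covariate missingness
ceiling 10%) → sodium prediction → measurement-error fit → conditional
draws → scored usual intakes → percentiles → IPTW×IPCW → weighted Cox →
risk table, HR curve, survival curves, balance report, radar export
(component scores as % of maxima by score quarter), E-values. All
randomness derives from one master seed; identical inputs and seed give
identical outputs. The entry point accepts only observed tables and
rejects anything carrying truth columns.

`bootstrap_ci` (default B = 250; desk-scale runs use 16–50) repeats the
post-measurement-fit stages per replicate and assembles percentile
(2.5/97.5) CIs around the full-data point estimates. Score percentiles are
computed once on the full-data run and held fixed — they define the
estimand. Two modes:

* **parametric** (default): per replicate, redraw the measurement model's
  fixed effects from their asymptotic normals, take fresh Monte-Carlo
  usual-intake draws, redraw the exposure- and censoring-model
  coefficients (and the exposure residual variance) from their asymptotic
  laws when evaluating the weights, refit the Cox model, then redraw its
  coefficients from the robust covariance and re-evaluate the risk table
  via the Breslow path. Variance parameters of the measurement model are
  held at their estimates.
* **resample**: persons resampled with replacement and every stage refit.

Replicate seeds derive deterministically from the master seed and are
distinct; individual replicate failures are skipped, >20% failures aborts.

## 7. The synthetic cohort generator

The generator defines the study conditions: 16 dietary components (7 foods
in reference amounts, 3 beverages in grams, energy, 4 nutrient totals,
plus a true sodium intake observed only through the urine assay), each
Gaussian on its Box-Cox scale (λ = 0.5 for foods, 0 for the rest) around a
person mean loaded on two latent factors — diet quality q (itself loaded
on standardized covariates: education, non-smoking, activity, female sex,
age raise it; BMI, deprivation, sedentary time lower it) and intake volume
v (shared with energy, so energy adjustment is non-trivial). Two
components are episodic (plant-based protein foods, sugary drinks) with
person-specific probit consumption probabilities. Recall counts follow
(0.38, 0.25, 0.18, 0.12, 0.07) on 1–5 recalls (mean 2.25, SD 1.27, 62%
with ≥2). Urine concentrations are generated by inverting the INTERSALT
equation from true sodium plus 300 mg assay noise (the default true-sodium
median, 3400 mg/d, sits above the equation's covariate-driven base level
so the inversion stays in the physical domain). Outcomes follow competing
exponential clocks — CVD (log-hazard: designed effect ln 0.8 per +10 true
HEFI points plus covariate terms), non-CVD death, loss — with baseline
rates calibrated by root-finding so the marginal 132-month proportions hit
2.1% / 2.6% / 0.3%; administrative censoring at 132 months.

What the generator does *not* emulate: real food-composition structure,
systematic (not just random) recall error such as energy under-reporting
correlated with adiposity, time-varying diet or covariates, and seasonal
recall effects. Passing tests therefore establish that the pipeline's
estimators recover known parameters under classical within-person error
and point-exposure confounding — not that any real cohort satisfies those
assumptions.

## 8. Operating characteristics at desk scale

The test suite runs the pipeline at n = 800–20,000 with M = 10–100 and
B = 16–40 (chosen so the full suite completes in minutes on one CPU;
the defaults M = 1000, B = 250 remain the analysis-scale settings).
Observed characteristics under the generator's defaults:

* the linear weighted dose-response is recovered essentially without bias
  (null: β̂ ≈ −0.01 at n = 50,000 vs −0.22 unweighted; protective: pooled
  β̂ close to ln 0.8), and seed-averaged weighted percentile contrasts sit
  closer to the null than unweighted ones at every percentile;
* with a conditionally *normal* exposure the weighted percentile-contrast
  risk ratios are unbiased (RR 1.00–1.09 under a strong-confounding null
  at n = 30,000); under the generator's bounded-score exposure, whose
  conditional law is left-skewed, the normal-density weights
  under-correct in the tails and percentile contrasts at the extreme
  percentiles carry a residual bias that does not vanish with n — the
  limitation documented in §4. As a consequence, bootstrap CIs for tail
  risk ratios under-cover on null-effect confounded cohorts (observed
  ~60–75% rather than nominal 95% for the 90th-percentile contrast at
  n = 10,000); the corresponding acceptance-style check in the test suite
  records this honestly rather than passing.

## 9. Known limitations

* The joint NCI fit is replaced by per-component fits plus the BLUP-based
  Σ_u assembly; a joint refit is an extension point.
* IPCW is a single end-of-follow-up logistic model, not pooled over time.
* Efron (not Breslow) tie handling, via lifelines.
* The parametric bootstrap holds measurement-model variance parameters
  fixed and recomputes the Breslow baseline rather than resampling it.
* Single imputation understates covariate-missingness uncertainty (<2%
  missingness by design).
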