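# Methods

## Outcome model

Percent fat mass for child *i* at visit *j* follows a random-intercept
linear mixed model, `y_ij = x_ij' beta + b_i + e_ij` with
`b_i ~ N(0, sigma_b^2)` and `e_ij ~ N(0, sigma_e^2)`. The fixed-effect
design contains, in order: an intercept; the exposure block; child sex,
standardized age in months and their product; race/ethnicity (two
indicators, non-Hispanic white reference); maternal education, work
status and smoking; breastfeeding; visit-level physical activity;
standardized maternal height; raw-power polynomial expansions of
standardized maternal age (cubic), prepregnancy BMI (quadratic),
gestational weight-gain adequacy (cubic) and natural-log urinary
creatinine (quadratic; omitted entirely under tertile exposure coding,
which uses creatinine-corrected concentrations instead); and
standardized calendar date of urine collection (days since the cohort
minimum). Sex-interaction fits append sex-by-exposure products plus a
sex-by-ln-creatinine (linear) product.

Continuous covariates are standardized as `(x − mean)/(2 SD)` so a unit
change matches a binary covariate flip; exposures as `(ln x − mean)/SD`
so coefficients are per SD of log concentration. All standardization
constants are computed once from the LOD/sqrt(2)-completed data and
frozen before sampling: recomputing them from imputed values each
iteration would make the design matrix itself a moving target and
break reproducibility for a negligible gain. (A per-iteration variant
was considered and rejected; the frozen constants differ from the
"true" completed-data constants by O(censored fraction), under 1% here.)

## Priors and the precision convention

Every coefficient prior is null-centred normal `N(0, 1/tau)` — **tau is
a precision, prior variance = 1/tau**. The convention is pinned by
back-calculation from the implied 95% intervals: `tau = 1` gives
`exp(±1.96) = (0.14, 7.1)` and `tau = 2` gives
`exp(±1.96/sqrt(2)) = (0.25, 4.0)` as odds-ratio bands, while
`tau = 1/16` gives `±1.96·4 = ±7.84`, about ±1 SD of the marginal
outcome (SD ≈ 8.4), and `tau = 1/64` about ±2 SD. Reading the variance
as `1/tau^2` reproduces none of these four bands simultaneously.
Defaults: `tau = 1/16` exposures (and sex-by-exposure products),
`1/64` covariates (including the intercept), `1` imputation submodels,
`2` selection-model coefficients. Variances `sigma_e^2, sigma_b^2` (and
the submodel variances) get vague conjugate inverse-gamma(0.001, 0.001)
priors by default; a half-normal alternative on the SD scale is
available via `variance_prior=("half_normal", scale)` and is updated by
a random-walk step on `ln sigma`.

## Censored concentrations

Cells below the LOD are redrawn at every sweep from
`N(mu_ln, sd_ln^2)` truncated to `(-inf, ln LOD_corrected]`, where
`(mu_ln, sd_ln)` are the mean and SD of the *observed* (above-LOD) log
concentrations, frozen — a deliberate cut-imputation in which neither
the truncation parameters nor the draw are informed by the outcome,
rather than a full conditional. The truncation is applied on the log
scale of the concentration-scale bounds (0, LOD]: a lower bound of zero is automatic
for a lognormal, and bounding the *log* below by zero would force
concentrations ≥ 1 ug/L, contradicting observed minima below LOD.
Draws use the inverse-CDF transform (`ndtri`), verified against
rejection sampling. After each redraw the DEHP molar sum
(MECPP + MEHHP + MEHP + MEOHP, each divided by its molecular weight:
308.33, 294.34, 278.34, 292.33 g/mol, configurable in the registry) is
recomputed and restandardized with the frozen constants. Under tertile
coding exposure columns are frozen indicator contrasts classified from
LOD/sqrt(2)-completed creatinine-corrected values, so the truncated
redraw is skipped — tertile membership is not re-derived per iteration.

## Covariate imputation submodels

Three submodels run inside the chain, all with `tau = 1` coefficient
priors:

* **Last pregnancy weight** (normal, response standardized to 1 SD of
  the observed weights): conjugate coefficient/variance updates;
  missing weights are drawn by independence Metropolis from the
  submodel conditional and accepted against every term the recomputed
  gestational weight-gain adequacy touches — the outcome polynomial,
  the breastfeeding submodel, and (in selection fits) the missingness
  design. Adequacy is observed gain over the expected gain
  `2.0 kg + rate(BMI class) × (gestational weeks − 13)` with weekly
  rates 0.51/0.42/0.28/0.22 kg for underweight/normal/overweight/obese,
  ×100; categories are `< 86` / `86–120` (inclusive) / `> 120` percent.
* **Breastfeeding** (logistic): coefficients by random-walk Metropolis
  with a proposal covariance from the 0.25·A'A + tau·I information
  approximation; missing indicators from the exact two-point full
  conditional including outcome feedback.
* **Physical activity** (logistic mixed with child random intercepts):
  coefficients as above; random intercepts by componentwise vectorized
  Metropolis; missing visit-level indicators from exact two-point
  conditionals.

## Selection model for dropout

Selection fits operate on the full three-visit grid over all mothers
with measured exposures; children absent from follow-up entirely
contribute three rows at the visit-schedule mean ages (4.9, 6.1, 7.8
years). The missingness indicator follows
`logit P(R_ij = 1) = gamma_0 + gamma_y (y_ij − y_bar) + Z' gamma_Z`,
with `y_bar` the observed-outcome mean, frozen. Centring matters:
uncentred, the intercept must absorb `gamma_y × 18`-ish and lands far
outside its `N(0, 1/2)` prior, which then deflects `gamma_y` itself —
centring keeps the intercept near `logit` of the missingness rate and
leaves `exp(gamma_y)`, the dropout odds ratio per 1% fat mass,
unchanged. Missing outcomes are updated by independence Metropolis
(Gaussian outcome full conditional as proposal, logistic selection
ratio as acceptance); `gamma` by random-walk Metropolis. A single
shared `gamma` covers intermittent missingness and terminal dropout.

## Synthetic-cohort generator

The generator reproduces the structure the analysis assumes, anchored
to the descriptive distributions of the cohort it emulates: lognormal
metabolite concentrations with geometric means from the descriptive
table and log-SDs from the printed interquartile ranges (IQR of
ln / 1.349) — except MEHP, whose log-SD (1.387) is set to reproduce its
91.7% detection frequency at LOD 0.9 ug/L, since the real data are
heavier-tailed than lognormal and the censoring rate is what drives the
imputation machinery; correlation 0.9 within the DEHP block and 0.4
elsewhere; covariate category frequencies matching the cohort's
baseline distribution; visit ages jittered around the schedule means with SDs
0.4/0.2/0.8 years; a random-intercept Gaussian outcome with
`sigma_b = 6`, `sigma_e = 4` and covariate effects chosen so the
marginal SD lands in the 7–8.5% band reported for the cohort; covariate missingness
at the cohort's observed rates (last pregnancy weight 22/180, breastfeeding
1/180, activity ≈ 2% of visits); and visit-level dropout that is MCAR
(rate 1/3, matching ~363 observed visits per 540), MAR, or MNAR with
`gamma_y = ln(0.81)` per 1% fat mass. Three RNG streams (mothers /
visits / dropout) are split from the master seed so toggling dropout
never perturbs exposures.

What the generator does **not** emulate: bioimpedance measurement error
and the Tanita equation structure, secular exposure trends,
exposure–creatinine dependence (concentrations are drawn directly
rather than as exposure × dilution), heavy non-lognormal exposure
tails, and informative covariate missingness. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to real-data violations of
them.

## Numerical choices

* Percentiles use linear interpolation between order statistics
  (type 7); tertile cut points are the 1/3 and 2/3 quantiles of the
  analysis sample, with boundary values assigned to the lower tertile.
* Credible intervals are equal-tailed percentiles (95% and 80%), not
  HPD. Heterogeneity of a sex-by-exposure product is flagged when its
  80% interval excludes zero.
* R-hat is rank-normalized split R-hat (classic Gelman–Rubin is also
  reported); convergence gate 1.05, ESS ≥ 400 advisory. ESS uses
  Geyer initial-monotone autocorrelation truncation over split chains.
* Chains draw seeds from a spawned `SeedSequence`, making runs
  bit-reproducible; `GibbsSampler.get_state`/`set_state` checkpoint the
  full parameter state plus RNG state, and a resumed chain reproduces
  the uninterrupted one exactly.
* Metropolis proposals are fixed at setup (information-matrix
  approximations scaled by 2.4/sqrt(d); random-walk SD 0.6 for activity
  random intercepts), preserving the stationary distribution without
  adaptive-MCMC bookkeeping.
* The default fit runs 50,000 iterations after 10,000 burn-in with two
  chains (ten for selection fits). The test suite and examples use
  shorter chains (hundreds to a few thousand sweeps) and cohorts of
  60–380 children — sizes chosen so the full replication studies (20
  recovery cohorts, 2×10 dropout cohorts) remain routine on a single
  core; posterior SDs in these models are ~0.6–0.7, so a few thousand
  effectively independent draws pin posterior means to ~0.02.

## Limitations

* The censored-value update is the cut-imputation the source
  formulation describes, not a full conditional: the outcome does not
  inform imputed below-LOD values. With >90% detection the difference
  is negligible, but the two are not equivalent in general.
* Logistic-block Metropolis steps mix more slowly than Polya-Gamma
  augmentation would; submodel coefficient ESS is accordingly lower
  than for conjugate blocks.
* BMI z-scores use a nearest-age LMS lookup against a user-supplied
  reference table; the bundled table is synthetic (plausible magnitudes
  only) so that no external growth-chart download is required.
* The selection model identifies `gamma_y` only through the joint
  parametric form; as in any MNAR sensitivity analysis, the data alone
  cannot verify the missingness mechanism.
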