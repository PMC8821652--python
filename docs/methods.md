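# Methods

This note documents the statistical machinery, the synthetic-data
generator and the design choices behind `prescore`.

## 1. The risk model

Marker → outcome relationships are estimated by Cox proportional
hazards regression on a background cohort, maximizing the partial
likelihood with Newton iterations (step-halving; convergence at a
coefficient change < 1e−9 within 100 iterations; the gradient norm is
verified < 1e−8 at the optimum).  Efron's tie correction is the default
because generated event times are day-granular and therefore tied;
Breslow is selectable and identical when no ties exist.  Covariates are
standardized internally for conditioning and mean-centered; centering
means are stored with the model so predictions are invariant to the
convention.  Standard errors and the coefficient covariance come from
the inverse observed information.  The test suite cross-checks
coefficients, standard errors and the log partial likelihood against
lifelines to ≤ 1e−5.

UACR enters as natural log — its distribution is strongly right-skewed
— and all other markers untransformed.  The baseline survival is the
Breslow estimator at the centering means, S0(t) = exp(−H0(t)) with
H0(t) = Σ_{t_k ≤ t} d_k / Σ_{R(t_k)} exp(lp_i), a right-continuous step
function that refuses to extrapolate beyond the last observed follow-up.
Absolute risk at horizon T is 1 − S0(T)^exp(lp).  T defaults to the
background cohort's median follow-up; no horizon is canonical for this
method and the choice is configurable.

Models serialize to JSON (coefficients, SEs, covariance, centering
means, S0 knots/values, horizon, transform map) and round-trip
bit-exactly.

## 2. The PRE score

Both published readings of "mean difference in predicted risk …
adjusted for the placebo arm" are implemented:

* `ratio_of_ratios` (default): RRR = 100·(1 − [r_T(m6)/r_T(base)] /
  [r_P(m6)/r_P(base)]).  Unitless, invariant to the baseline risk
  scale, and the form under which predicted and observed hazard-ratio
  RRR coincide in the rare-event limit.
* `adjusted_difference`: RRR = 100·(−[(r_T(m6)−r_T(base)) −
  (r_P(m6)−r_P(base))]/r_T(base)).

The two agree to first order when risks are small; tests bound the
divergence.  The CI draws each coefficient independently from
Normal(β̂_l, SE_l²) (covariance deliberately ignored, matching the
method's published description), recomputes the RRR per draw with S0
held fixed, and reports percentile bounds; n_draws defaults to 100.

**What the interval does and does not cover.**  The resampling models
*coefficient* uncertainty only.  Across replicate background cohorts
with a fixed trial, the CI covers the RRR evaluated at the true
generating coefficients at roughly its nominal level (verified by
simulation).  It does **not** cover trial-level sampling noise: under
replicate trials the point estimate scatters more than the interval
width.  Users comparing predicted with observed RRRs should rely on the
observed interval for trial noise.

Single-marker scores reuse the full multivariable β̂, advancing only the
chosen marker to month 6.  This attributes the joint prediction rather
than refitting univariable models, so in the rare-event limit the
single-marker log relative risks add up to the full-model log relative
risk (tested).  The observed RRR is 100·(1 − HR) from a Cox fit on a
single treatment indicator, with a Wald CI on the log-HR scale.

## 3. The synthetic-data generator

The generator emulates two populations whose printed summary statistics
parameterize all defaults:

* **Trial cohort** — n = 7020, 2:1 treated:placebo.  Baseline markers:
  HbA1c 8.1 (0.9) %, SBP 135.4 (17.0) mmHg, hemoglobin 137.2 (14.7)
  g/L, weight 86.3 (19.0) kg, HDL 1.15 (0.30), LDL 2.2 (0.9) mmol/L,
  uric acid 357 (98.5) µmol/L, potassium 4.55 (0.5) mmol/L; UACR
  log-normal with log-location ln 17.7 and log-scale
  (ln 74.3 − ln 17.7)/0.6745 (median and upper quartile), which places
  ≈40% of patients at ≥30 mg/g analytically.  Six-month
  placebo-corrected effects: HbA1c −0.6%, SBP −4.2 mmHg, UACR −13% (as
  +ln 0.87 on the log scale), weight −2.1 kg, uric acid −20.4 µmol/L,
  hemoglobin +6.6 g/L, HDL +0.04, LDL +0.1 mmol/L, potassium 0.
* **Background cohort** — n = 6355, higher albuminuria (UACR median
  276.9, Q3 1193.9 mg/g), lower eGFR and hemoglobin; event fractions
  calibrated to 12.5% (CV) and 17.8% (kidney).

Choices the sources do not constrain, fixed once as field-plausible
values: within-subject six-month change SDs (HbA1c 0.9%, SBP 10 mmHg,
log-UACR 0.8, weight 3 kg, hemoglobin 8 g/L, HDL 0.12, LDL 0.6
mmol/L, uric acid 45 µmol/L, potassium 0.35 mmol/L); zero placebo
drift; a Gaussian copula with a modest equicorrelated block (ρ = 0.2)
on the transformed scales; demographics (age, sex, eGFR) drawn
independently of the markers; and the generating coefficient vectors,
chosen so albuminuria dominates the kidney endpoint and blood
pressure/lipids/glycemia carry more of the CV endpoint, with
magnitudes in the range epidemiological studies report.  With these
defaults the eGFR/UACR joint distribution retains ≈17% of trial
patients under the CKD-style filter (eGFR 20–45, or 45–90 with UACR
≥ 200 mg/g).

Event times are exponential with rate λ0·exp(β*·(x − μ)), administrative
censoring at 3.1 years (optional random censoring), rounded **up** to
whole days — real trial databases are day-granular, and the rounding
produces the ties that justify Efron's correction.  λ0 is solved by
bisection of E[1 − exp(−λ0 e^lp C)] = target event fraction over a
Monte-Carlo draw of linear predictors.

Trial outcome hazards use **month-6** marker values in both arms, so the
simulated treatment effect is wholly marker-mediated — the regime where
the PRE score should be unbiased.  `OutcomeConfig.direct_log_hr` adds a
treated-arm log hazard ratio that bypasses the markers, reproducing the
qualitative underestimation seen when real drugs act through unmeasured
pathways.  The `true_rrr` oracle evaluates each simulated subject's
exact exponential risk at the horizon (no event-time noise) and returns
100·(1 − mean risk_T / mean risk_P).

What the generator does **not** emulate: visit schedules, dropout
dynamics, competing risks, marker–demographic correlation,
non-proportional hazards, or measurement error distinct from biological
change variance.  Passing tests therefore show that the *method* is
internally correct under its own assumptions, not that any real drug's
effect will be predicted accurately.

### A note on estimands

The PRE score is a risk-ratio contrast evaluated on the background
model's risk scale, while `true_rrr` is a risk-ratio at the generator's
own risk level and the observed RRR is a hazard-ratio contrast.  Because
risk ratios are not collapsible, the three coincide only when the risk
scales match (background drawn from the same marker distribution as the
trial) or events are rare.  The parameter-recovery tests use matched
populations for exactly this reason; with the default mismatched
populations (background at far higher albuminuria) the predicted RRR
sits a few points above the saturated risk-scale truth while still
matching the observed hazard-ratio RRR closely.

## 4. Imputation

Chained-equation predictive mean matching: variables visited in
ascending missingness order; blanks initialized by draws from observed
marginals; each target regressed by OLS on all other modelling
variables; each missing entry filled with the observed value of a donor
drawn uniformly from the k = 5 nearest observed cases by predicted
mean; 10 sweeps; m = 5 completed datasets on independent RNG streams.
UACR is imputed on the log scale, consistent with its model entry.
Pooling follows Rubin's rules (total variance = within + (1 + 1/m) ·
between).  The pipeline scores each completed dataset and averages
points and CI bounds — a pragmatic choice, stated here because no
pooling rule is canonical for a resampling percentile interval.

## 5. Enrichment simulations

The responder threshold is the treated-arm median change (log scale for
UACR), inclusive: ties at the median respond.  The default shift is a
stratified bootstrap — each treated patient's change is re-drawn from
the empirical responder stratum with probability p, the non-responder
stratum otherwise; a parametric location-shift mode is available behind
a flag.  When the inclusive rule classifies the whole arm as responders
(degenerate constant changes) resampling falls back to the single
stratum, making the curve flat rather than erroring.  `required_effect`
bisects uniform treated-arm shifts (additive; multiplicative on the
natural scale for UACR) until the predicted RRR meets the target within
0.1 percentage points, and reports the implied total mean
placebo-corrected effect.

## 6. Numerical and reproducibility choices

* One user seed per operation; internal sub-streams are derived
  deterministically from (seed, operation label) so adding an operation
  never perturbs another's draws.  Identical seeds give byte-identical
  cohorts, reports and serialized models.
* Monotone-likelihood (separation) is diagnosed when standardized
  coefficients exceed 80 or step-halving fails; constant and collinear
  covariates are rejected before iteration.
* Problem sizes in the test suite: background cohorts of 1.2k–6.4k,
  trials of 0.6k–7k, oracle simulations of 50k–200k subjects; the
  parameter-recovery checks run at the full n = 6355 / n = 7020 of the
  emulated studies.

## 7. Known limitations

* The resampling CI understates total predictive uncertainty (see §2).
* Coefficient draws ignore the off-diagonal covariance by construction;
  with correlated markers this typically widens the interval.
* S0 is held fixed across coefficient draws; baseline-hazard
  uncertainty is not propagated.
* The adjusted-difference form divides by the treated arm's baseline
  risk and is sensitive to near-zero baseline risks; the ratio form is
  preferred and is the default.
* PMM is linear-Gaussian in spirit; strongly non-linear marker
  relationships would need a richer imputation model.
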