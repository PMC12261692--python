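# Methods

## Problem and design

Given tidy longitudinal Hb records (patient, date, value in mmol/L, gender,
birth year), the package (1) cleans and filters the cohort, (2) fits a
penalized-spline additive model to predict each patient's held-out most
recent Hb value from strictly earlier data, (3) constructs personalized
normal ranges from each patient's history, and (4) evaluates both the
numeric predictions and the normal/out-of-normal classification.

Evaluation is hold-out-last: per patient, the most recent usable measurement
is the single test point; everything earlier is training data. Patients
contributing no training row are dropped from both partitions.

## Preprocessing

* **Same-day duplicates**: at most one measurement per (patient, day); the
  first record in file order survives (deterministic, order-stable).
* **Inclusion filters** (whole-patient exclusion, in order): age at first
  measurement below `min_age` (default 16); any Hb value outside
  [`hb_min`, `hb_max`] (defaults 6.0–16.5 mmol/L; per-gender bounds
  configurable for refined subsets such as 6–12 F / 7–13 M); measurement
  count outside [`min_measurements`, `max_measurements`] (defaults 3–100).
  One out-of-range value removes the *patient*, not the row: the analysis
  targets people with predominantly stable in-range histories. Each stage
  logs an attrition record; counts never increase.
* **Model rows**: per measurement with at least one earlier observation —
  response `y`; `time_since_first_days`; `past_mean`, the arithmetic mean of
  all strictly earlier values (default `expanding_strict`; a
  `train_constant` mode uses the patient's constant pre-holdout mean
  instead); `age` from birth year and measurement date; gender. The first
  measurement of each patient has no history and is dropped rather than
  imputed with its own value — this preserves the no-lookahead contract that
  mutating or deleting any future measurement leaves earlier rows unchanged.

## The additive model

Gaussian response, identity link:

    y_i = beta0 + beta_g * male_i + sum_j f_j(x_ij) + b_patient(i) + e_i.

* **Bases**: each smooth is a cubic B-spline basis on equally spaced knots
  over the training range (basis dimension 10 by default), with a
  second-order difference penalty on coefficients. Equally spaced knots make
  the penalty null space correspond exactly to straight lines, so an
  infinite penalty collapses the smooth onto the least-squares line (a
  property the tests assert). Each basis is reparameterized onto the null
  space of the "mean of f over training rows = 0" constraint, so fitted
  smooths are centered and the intercept is identifiable. Evaluation outside
  the training range clips to the boundary (constant extrapolation) — the
  conservative choice for clinical covariates.
* **Random intercept**: a per-patient indicator block with a ridge penalty
  whose weight is selected together with the smooth penalties; the implied
  ridge weight is the within/between variance ratio of a classical random
  intercept. Patients unseen in training get offset 0 (with a warning).
  Its effective degrees of freedom can legitimately be ~0 when the
  past-mean smooth already absorbs patient-level variation.
* **Smoothing selection**: REML by default — the profiled Gaussian
  restricted likelihood
  `(n - M_p) log(RSS + penalty) + log|X'X + S| - log|S|_+`
  minimized over log penalty weights with a Nelder–Mead simplex
  (convergence tolerance 1e-7, iteration cap 200 per parameter + 1; the cap
  occasionally bites with many penalties, which affects the selected weights
  negligibly and is logged). GCV (`n·RSS / (n - edf)^2`) is available.
* **Degrees of freedom and uncertainty**: with `M = (X'X + S)^{-1} X'X`,
  per-term edf are sums of `diag(M)`; the residual variance is
  `RSS / (n - tr M)`; coefficient uncertainty uses the Bayesian posterior
  covariance `sigma^2 (X'X + S)^{-1}`, whose intervals account for smoothing
  bias. Per-smooth F statistics are Wald-type approximations on that
  covariance with reference df `tr(2M - M^2)` restricted to the term — they
  judge whether a term carries signal, not an exact finite-sample test.
* **Prediction intervals** (default): `y_hat ± z * sqrt(se_fit^2 + sigma^2)`,
  an interval for the next *observation*, since the package evaluates
  whether the next measurement falls inside; a mean-only interval mode
  exists. Which construction the field's published analyses use is usually
  unstated; both are provided and the default is the one whose empirical
  coverage is testable against held-out observations.
* **Model selection utilities**: AIC/BIC on the Gaussian likelihood with
  edf + 1 parameters; `deviance_explained = 1 - RSS/TSS`.
* **Mixed-effects baseline**: same response and covariates with all effects
  linear (edf = 1 each) plus the REML-selected ridge random intercept, fit by
  the same penalized machinery so it returns the identical fitted-model
  shape. A test cross-checks its fixed-effect slopes against statsmodels
  MixedLM; another cross-checks the smooth fit itself against R mgcv's
  REML P-spline fit.
* **Nested comparison** (`compare_models`): ΔAIC/ΔBIC, residual deviances,
  and an approximate F test. The numerator df is the *difference of
  `tr(2M - M^2)`* between models, not of edf: for a shrinkage smoother the
  expected RSS drop per unit under the null is `sigma^2 tr(2M - M^2)`, and
  using plain edf makes the test anti-conservative (observed in simulation:
  null retention rose from ~0.74 to ~0.98 at alpha = 0.05 with the
  corrected df).

## Personalized ranges and classification

`mean ± k·SD` of the patient's historical values (sample SD, n−1
denominator; at least 2 values required), history excluding the held-out
measurement. Default `k = 2.5`; robustness sweep over
{1.5, 1.75, 2.0, 2.25, 2.5}. Boundaries are inclusive — a value exactly on a
bound counts as normal (conservative toward not flagging); published
conventions rarely state this, so the package states its own. A zero-variance
history yields a zero-width range rather than an error; an optional
analytical floor (half-width ≥ CVa·mean) exists but is off by default so the
formula is exact.

Classification convention: the *positive* class is "within personal normal
bounds" (so TP = actual and predicted both normal, and FPR is the fraction of
truly out-of-normal patients predicted normal). This matches how such
confusion matrices are reported in the individualized-reference-interval
literature; the report also carries specificity and NPV for clinical
readability. ICC uses the one-way random-effects ANOVA estimator with the
unbalanced-design group-size correction, truncated at 0; post-model ICC is
computed on training residuals grouped by patient (one defensible reading of
"residual ICC"; others exist).

MSPE is reported in mmol²/L² together with RMSE in mmol/L, since reports in
this area sometimes print MSPE with linear units.

## Synthetic cohorts

`generate_cohort` simulates, per patient: gender (59.23% female), age at
study start from a normal (mean 65.79, SD 18.34) truncated at 17, a setpoint
from gender-specific normals (7.80 F / 8.50 M, giving pooled mean ≈ 8.09;
between-patient SD 0.95), a visit count from a rounded log-normal (median 13,
log-SD 0.8 → count SD ≈ 16, floor 3, cap 100), and visit dates uniform over a
2,556-day window. Observed values add a fixed smooth age effect (full-period
cosine over ages 17–100, amplitude 0.15 mmol/L — small but clearly
non-linear, with closed-form truth for recovery tests), a sinusoidal effect
of days since the patient's first measurement (same amplitude, one cycle per
span), an optional linear drift of −0.5 mmol/L per follow-up year for a
configured fraction of patients, additive biological noise (SD 0.26 mmol/L,
~3.2% within-subject CV, a standard figure for Hb), and multiplicative
analytical noise (CV 1.43%). The within/between SD split (0.26/0.95) plus the
gender-mean spread reproduces the pooled SD ≈ 1.04. Ground truth (noiseless
trajectory, setpoint, drift label) is recorded per measurement.

Two caveats the tests respect: (1) the nonlinear age effect has a nonzero
mean under the age distribution (≈ −0.13 mmol/L at defaults), so the
moment-control check sets `trend_amplitude = 0` when verifying the pooled
mean against its configured target; (2) the generator emulates statistical
structure only — no comorbidities, medications, seasonality, hospitalization
episodes, or informative visit timing. Passing tests therefore demonstrate
correctness of the machinery and calibration *under the stated data-generating
process*, not clinical performance on real registries.

## Problem sizes used by the test suite and acceptance script

Curve recovery uses a ~1,900-row cohort (130 patients); interval calibration
uses 1,150 patients (~1,080 test points); the threshold sweep uses 400
patients with 10% drifters; the deviance-test behaviour check runs 50
replicates per scenario at 60 patients each; the acceptance script runs the
full pipeline on 800 patients with 10% drifters — chosen so each check has
enough data to be informative while the whole suite stays comfortably
interactive. The 10% drift fraction gives an out-of-normal prevalence near
the ~13% seen in routine primary-care monitoring populations.

## Known limitations

* The smooth-term F/p-values are approximations; for publication-grade
  inference on individual terms, refit with a dedicated GAM package and
  compare.
* The random-intercept block is dense; cohorts beyond ~5,000 patients per
  fit will want a sparse or backfitting implementation.
* Personal ranges assume a stable setpoint; for patients with genuine trends
  the mean ± k·SD construction widens rather than tracks (percentile,
  Bayesian-credible, or Gaussian-process ranges are deliberate non-goals).
* Calendar seasonality and covariate interactions beyond gender-specific
  past-mean smooths are not modelled.
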