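# Methods

## The multistate model

Patients enter at day 0 (day of cystectomy) in the *hospitalized* state.
Three transitions are possible: discharge (A), inpatient death (B) and
post-discharge death (C); death is absorbing and the horizon is 90 days,
treated as a closed bound (events on day 90 count).  Each transition has a
cause-specific Cox model on the days-since-surgery timescale.  Competing
events are handled by risk-set censoring: discharge and inpatient death
share the hospitalized-phase rows with complementary status, and the
post-discharge model uses delayed entry (left truncation) at the discharge
day, so a subject discharged on day `d` contributes to the C risk set only
for event times strictly after `d`.

Outcome coding on day-resolution data is total and mutually exclusive:
a death with `t_last ≤ t_discharge` (including a death recorded on the
discharge day) is an inpatient death; a death with `t_discharge < t_last`
is post-discharge; everything else is censored at the earlier of last
contact and day 90.  Same-day discharge (`t_discharge = 0`) is allowed and
opens the post-discharge risk window at time 0.  Zero-length post-discharge
windows (discharge at the censoring day) carry no information and produce
no C row.

## Cycle mechanics

The prediction engine is a deterministic cohort-expectation recursion over
90 one-day cycles.  Individualized daily hazards are
`h_k(t) = h0_k(t) · exp(x'β_k)`.  Within a cycle, the two competing exits
from the hospitalized state share the joint exit probability
`1 − exp(−(h_A+h_B))` proportionally to their hazards; the alternative of
independent per-cause probabilities `1 − exp(−h_k)` is rejected because the
pair can sum above 1.  From the discharged state the death probability is
`1 − exp(−h_C)`.  Occupancy rows therefore remain on the probability
simplex by construction — conservation is asserted to 1e-12 in tests, never
patched by renormalization.

Time in the living states is accrued trapezoidally (half-cycle convention:
events occur mid-cycle), so a patient certain to die in cycle 1 accrues 0.5
hospitalized days.  QALDs weight those days by utilities 0.67 (hospitalized)
and 0.77 (discharged); death contributes 0.  The 90-day mortality
probability is read at the horizon boundary without half-cycle adjustment.
Setting `ModelConfig(half_cycle=False)` switches to end-of-cycle accounting.
No discounting is applied (the horizon is 90 days).

## Fitting choices

* **Ties.**  Day-resolution data are heavily tied (the discharge transition
  can see >20% of the risk set exiting on a single day).  The partial
  likelihood uses the Efron approximation; Breslow tie handling would
  attenuate coefficients noticeably at this tie density.
* **Baseline hazard.**  Breslow estimator evaluated at the reference
  pattern: female, CCI 0, cT2, low volume, age at the centering constant
  (the training-cohort mean by default; stored in the model artifact).
  Daily hazards are the increments of the cumulative baseline on the
  integer-day grid.
* **Selection.**  Backward stepwise by AIC (−2 logPL + 2k) on whole
  categorical blocks, so a 3-level factor enters or leaves as its pair of
  indicators.  Ties in AIC favour the smaller model, in candidate order,
  making selection deterministic.  With multiply imputed data, selection
  runs once on the first completed dataset; the selected model is refit on
  every imputation and pooled.  The null model's partial likelihood is
  computed directly from the risk sets.
* **Pooling.**  Coefficients and variances pool by Rubin's rules.
  Cumulative baseline hazards are not coefficient-like and are averaged
  pointwise on the daily grid, which preserves monotonicity.

## Missing data

Chained-equations imputation, five sweeps, m = 20 by default.  Every
imputation model conditions additively on all other predictors, the
discharge and 90-day death status indicators, and the Nelson–Aalen
cumulative-hazard estimates for discharge and death evaluated at the
subject's own time.  Continuous targets use predictive mean matching with
five donors (values stay in the observed support); categorical targets are
drawn from multinomial logistic fits.  Observed cells are never altered.
Imputation is deterministic given its seed.  By default the full cohort is
imputed once; the cross-validation runs in strict mode, re-imputing inside
each training fold and imputing the held-out region separately, so no
held-out row influences imputation, selection or fitting for its own split.

## Validation

Internal–external cross-validation over the six US geographic regions:
refit on five, score the sixth.  Discrimination uses Harrell's C adapted to
delayed entry: a pair is usable when the earlier event time lies inside
both subjects' at-risk windows (`entry_j < t_i ≤ t_j`), predictor ties count
1/2.  Calibration is the coefficient of the frozen development linear
predictor (x'β only, baseline excluded) in a validation Cox refit with
delayed entry; 1 is optimal.  Per-region metrics use the pooled
coefficients.  A held-out region with zero events for a transition reports
NaN for that cell rather than aborting.

Calibration-slope self-consistency is tested on validation data simulated
from the fitted development model itself (`simulate.truth_from_models`).
Validating against fresh *truth*-generated data instead mixes in the
estimation error of the development coefficients and attenuates the slope —
visibly so for the discharge transition, whose linear predictor has small
variance — which is a property of noisy predictors, not a model defect.

## The synthetic cohort generator

The generator emulates the registry cohort the models were designed for:
covariates drawn independently from the published marginals (age truncated
normal 69 ± 10.4 on [30, 95]; 77% male; CCI 69/24/7%; cT2/3/4
81.6/12.4/6.0%; volume tertiles 24/37/39%; six regions uniform), and event
histories simulated by the exact discrete-time mechanism the prediction
engine assumes — daily competing Bernoulli exits with proportional cause
allocation — so generator and estimator share one data-generating grammar.
Ground-truth log hazard ratios are the published multivariable estimates
for all three transitions.

Baseline hazards are not published, so they are calibrated (once,
numerically: `calibrate_baselines`, a fixed-point loop of Brent root finds
on the analytic cohort-average recursion) and frozen in the shipped
defaults:

* discharge: discrete hazard of the length-of-stay mixture
  `0.67·LogNormal(ln 7.2, 0.16) + 0.33·LogNormal(ln 16.5, 0.55)` scaled by
  0.93329 — reproduces median LOS 8 days, IQR 7–12;
* inpatient death: 2.1857e-3/day through day 21, halved after;
* post-discharge death: 5.9251e-4/day through day 45, ×0.6 after —
  together yielding 7.6% overall 90-day mortality.

The split of that mortality — one third in hospital, two thirds after
discharge — is a modelling choice; the registry publication reports only
the total.  Follow-up is administratively censored at 365 days so horizon
censoring dominates.  Optional missingness is MCAR or MAR-on-age (blanking
probability increasing linearly with age around the configured rate).

What the generator does **not** emulate: covariate correlation (an age–CCI
association exists in real cohorts; covariates are independent here),
facility-level clustering, regional heterogeneity, calendar-year trends,
and cause-of-death structure.  Passing tests therefore demonstrate that the
pipeline recovers a truth of exactly this functional form at these sample
sizes — not that the fitted registry model is clinically transportable.

## Problem sizes and numerical tolerances

Tests and the acceptance script use n = 50 000 cohorts for parameter
recovery and calibration anchors (every true log hazard ratio recovered
within ±2 SE; mortality within ±0.7 percentage points), 500 000 Monte Carlo
paths for trace/microsimulation equivalence (each occupancy cell within 3
binomial SEs at days 30/60/90), and n = 30 000 for the six-region
cross-validation.  Hazards are converted with `expm1`/`log1p` for accuracy
at small rates; discrete conditional exit probabilities are capped at 0.999
and daily hazards at 3.0 when inverting the length-of-stay distribution
(relevant only deep in the right tail).  The Rubin degrees-of-freedom ratio
is clamped to infinity when the between-imputation variance underflows.

## Known limitations

* Proportional hazards are assumed and not diagnosed; no frailty or
  cluster terms for facility.
* The C-statistic variant for left-truncated data restricts usable pairs to
  overlapping risk windows; other concordance conventions exist and give
  slightly different values at heavy truncation.
* The granular-volume refit is available only as a configuration of the
  covariate blocks, untested against published estimates.
* QALD utilities are fixed weights; sensitivity is by configuration only.
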