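# Methods

This note documents the statistical model, the synthetic data-generating
process, the numerical choices, and the limitations of `cvsched`.

## Two-stage landmark model

**Stage 1 — longitudinal model.** The five longitudinal risk factors
(smoke, HDL, SBP, TCHOL, BMI) are stacked into a single response with a
factor-indicator design: factor-specific intercepts and centered-age slopes,
a blood-pressure-medication shift entering SBP rows only, and a statin shift
entering TCHOL rows only. Each person carries a 10-vector of random effects
(intercept + slope per factor) with a *full* 10×10 covariance Σ, so
deviations are correlated across factors. Residuals are independent with
**factor-specific** variances: the factors live on wildly different scales
(SBP in tens of mmHg, HDL in fractions of mmol/L), so a shared residual
variance is not a sensible estimand; this is a deliberate design choice.

Fitting is maximum likelihood via an ECM algorithm rather than direct
quasi-Newton on a covariance parameterization: given (Σ, σ²), the fixed
effects are the exact GLS solution; the E-step computes each person's
posterior random-effect mean and covariance through the Woodbury identity,
so all per-person linear algebra is on 10×10 matrices regardless of how many
measurements the person has; the M-step averages posterior second moments
(keeping Σ positive semi-definite by construction) and pools squared
residuals per factor. Persons are padded into equal-length buckets so each
iteration is a handful of batched `einsum` calls — one iteration is O(total
rows), and 20–40 iterations typically reach a 1e-8 relative log-likelihood
change on cohorts of a few thousand. An eigenvalue floor (1e-12 of the
largest eigenvalue) guards Σ inversion at the boundary. The fit is
cross-checked against statsmodels `MixedLM` on single-factor data in the
test suite (agreement ~1e-4); a fixed-effects covariance from the
accumulated GLS information matrix supplies standard errors.

Design columns with no support in the data (e.g. the statin shift when
nobody is ever on statins) are dropped and reported as *aliased*, with NaN
coefficients, rather than silently producing a singular fit.

The fit uses **all** measurements of landmark-cohort members — before and
after the landmark age — because it estimates population parameters.
Forecasting is strictly *past-only*: BLUPs condition on measurements at or
before the information age, so a person with no history gets the population
trajectory, and predictions are exactly affine in age (random-slope model).
When forecasting for a statin-free landmark cohort, statin status is fixed
at 0 and medication status is carried forward from the landmark age.
Predicted smoking is left on its continuous scale (it may leave [0,1]);
the downstream Cox model consumes it as-is.

**Stage 2 — landmark survival.** Cox proportional-hazards models are fitted
on time since the origin with administrative censoring at the window end:
a 10-year-window model at the landmark age (supplying the statin-free
survival curve for the net-benefit integrals) and an 5-year-window model at
each prediction time `s` on the sub-cohort still alive and CVD-free at `s`.
Covariates are the landmark-age indicator values and Townsend dummies
(reference = lowest level, constant columns dropped and recorded) plus the
five BLUP forecasts at `s`. BLUPs condition on data up to the landmark age
for both fitting and prediction, keeping the covariate definition identical
in training and deployment. Coefficients come from lifelines' partial
likelihood (Efron tie handling — immaterial here, since simulated event
ages are continuous); the baseline cumulative hazard at covariates = 0 is
the in-package Breslow step estimator, which reduces exactly to
Nelson–Aalen under a null model. Death is treated as censoring everywhere;
there is no competing-risk adjustment.

**Crossing time.** The 5-year risk profile is scanned along the available
(non-NaN) prefix of offsets 0..10; the *first* strict exceedance of the
threshold defines `t*` by linear interpolation from the previous year.
Risk exactly at the threshold does not count as an exceedance. A profile
already above the threshold at the landmark is flagged `very_high`; these
people should initiate statins immediately and are excluded from schedule
optimization. Risk categories use the cut-points >5%, (3.75%, 5%],
(2.5%, 3.75%], (1.25%, 2.5%], ≤1.25%, upper boundaries inclusive.

## Net benefit

Candidate schedules have intervals `f ∈ {1,…,10}` years, first visit at the
landmark, last visit within the 10-year horizon. Statins start at the first
visit **at or after** `t*` — a visit coinciding with the crossing triggers
initiation. Visits stop at initiation, so crossers expect exactly `k*`
visits; never-crossers use the continuous formula `1 + 10/f` (4.33 for
`f = 3`), matching the framework's published arithmetic rather than the
integer count of scheduled visits. When a schedule has no visit after `t*`
(possible for `f = 7, 8, 9` with a late crossing), the person never initiates
under that schedule and is scored as a never-crosser.

Both EFLY integrals are evaluated **exactly** on the step grid of the
Breslow baseline — the survival curve is genuinely piecewise constant, so
no quadrature error enters. The on-statin curve
`S_S(t) = S_NS(τ*)^{1−θ} S_NS(t)^θ` embodies a proportional hazard reduction
`θ = 0.8` from initiation onward. Net-benefit ties across intervals (they
arise exactly in the degenerate limit θ = 1, u_s = 1, zero costs, and
numerically in near-flat cases) are resolved toward the **largest**
interval within a 1e-9 relative tolerance: at equal benefit, fewer visits
is the patient- and cost-favourable choice. The sensitivity analysis reuses
the per-person EFLY/visit components (they do not depend on λ, u_s, c_s,
c_ν) and re-scores the optimum over one-at-a-time parameter grids; the
hazard ratio is deliberately excluded from those grids because it changes
the components themselves.

## Validation metrics

The supplementary definitions behind the published dynamic metrics are not
available, so the standard forms are implemented and documented as such:
a truncated dynamic C-index (comparable pairs: an observed event within the
window vs. a subject known to survive longer; risk ties count 1/2) and the
Graf-style IPCW Brier score at the window end with a Kaplan–Meier estimate
of the censoring distribution. With no censoring the Brier score equals the
plain mean squared error, and the C-index is invariant to monotone
transformations of the risks — both properties are tested. Evaluation uses
a held-out split by practice (cluster) id.

## Synthetic cohort generator

The generator emulates the *structure* the model assumes, not any specific
population's marginals:

- entry ages uniform on 35–70; administrative censoring at age 80 (deaths
  are folded into administrative censoring, mirroring how the analysis
  treats death); ~20 practice clusters for held-out validation splits;
  Townsend with 5 levels by default (configurable) for desk-scale
  estimability.
- true factor trajectories are linear in age with MVN(0, Σ) person effects
  (Σ handcrafted: negative intercept–slope correlations within factor,
  positive correlations among SBP/TCHOL/BMI intercepts, negative HDL–BMI);
  fixed intercepts are expressed at reference age 60 so defaults read like
  clinical values (SBP 132 mmHg, TCHOL 5.6 mmol/L, BMI 27.2, …).
- measurement times follow a homogeneous Poisson visit process
  (0.4 visits/person-year by default) independent of covariate values —
  non-informative observation, as the mixed model assumes. All five factors
  are recorded at each visit. The sparsity pattern of real primary-care
  data is not publicly documented, so these observation-process defaults
  are invented and labelled as such.
- medication/disease indicators switch on by exponential clocks from entry
  and stay on (monotone); blood-pressure medication shifts measured SBP by
  −9 mmHg, statins shift TCHOL by −1.1 mmol/L.
- CVD events come from a proportional-hazards model with **constant
  baseline rate** (0.0075/year) times `exp` of a linear predictor in the
  person's *noise-free* current factor values (centered at the age-60
  means), current indicator states and Townsend level; event times are
  drawn by inverting the cumulative hazard on a 0.1-year grid. Driving the
  hazard with noise-free values makes Cox-coefficient recovery a clean
  oracle. The baseline rate was chosen so the age-60 landmark cohort shows
  mid-single-digit 10-year incidence.
- smoking is generated as a latent Gaussian and recorded dichotomized at
  0.5 (EHR-like). Recovery checks simulate with the latent value recorded
  instead (`smoke_record="latent"`): a linear fit to 0/1 smoke identifies a
  linear-probability estimand, not the latent-Gaussian coefficients, so
  coefficient recovery is only well-posed on the latent scale.

Consequently, passing tests demonstrate internal statistical correctness
(the pipeline recovers what generated the data, the optimizer maximizes
what it claims to) — they do **not** demonstrate that real EHR data satisfy
linear trajectories, non-informative observation, or a constant baseline
hazard.

## Numerical choices and degenerate inputs

- EM stops when the relative log-likelihood change drops below 1e-8
  (configurable); boundary variance estimates decay slowly under EM, so
  tests of exact degeneracies use balanced designs where GLS = OLS holds
  identically.
- Step-function survival curves are right-continuous; integrals handle
  partial intervals exactly; `S ≡ 1` before the first event.
- Zero events in a Cox window raise an estimation error rather than
  returning a silent null fit; non-finite coefficients (separation) are
  likewise errors carrying the origin, event count and cohort size.
- An empty measurement set for a person yields the population-mean BLUP;
  an empty cohort is an input error.
- Problem sizes in the test-suite: structural checks run on a 300-person
  cohort, the full landmark analysis on 1,500 persons at landmark 60, and
  parameter recovery on 5,000 persons — sizes at which all recovery
  tolerances (3 SE for fixed effects and log-hazard ratios, 25% relative on
  the random-effect variances) hold with margin.

## Limitations

- Single stratum by default; the pipeline accepts a sex column and can be
  run per stratum, but the generator does not emulate sex differences.
- No competing mortality, no informative dropout, no statin non-adherence;
  the hazard ratio θ is constant from initiation.
- Linear age trends only — no splines, no logit sub-model for smoking.
- The net benefit covers the 10-year window without discounting and has no
  recommendation for people already above the threshold at the landmark.
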