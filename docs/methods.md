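# Methods

## The model

Waitlisted transplant candidates die both of "background" causes — the
mortality anyone of their sex, race, age and calendar year faces — and of
causes attributable to end-stage organ failure and waitlisting.  A relative
survival (excess-hazard) model separates the two additively.  On
person-time interval *j* with duration `t_j`, death indicator `d_j` and
expected hazard `λ*_j`, the observed hazard is

```
h_j = λ*_j + μ_j,     μ_j = exp(α_b(j) + x_jᵀ β)
```

and the log likelihood is `Σ_j d_j·log(λ*_j + μ_j) − (λ*_j + μ_j)·t_j`
(piecewise-exponential form).  `α` is a piecewise-constant baseline excess
log-hazard on follow-up bands (default edges 0, 1, 2, 3, 5, 10 years, last
band open); `β` contains log excess-hazard ratios for categorical
covariates.  The female-vs-male contrast exponentiates to a relative excess
risk (RER).  Because current age modifies the sex effect, a sex ×
age-category interaction is in the default design, so the RER is reported
per current-age category (0–12, 13–24, 25–44, 45–59, ≥60 years — ages
chosen to track developmental stages; transitions happen on the birthday).

Key assumptions: the life table correctly describes background mortality
for every stratum (including race "other", which must be supplied as its
own stratum — no averaging is attempted); hazards are constant within the
expanded intervals; censoring at transplant is non-informative; the excess
acts additively on the hazard scale and log-linearly in covariates.

## Person-time expansion

Follow-up runs from waitlist activation to death, transplant or
administrative censoring.  It is split at the union of: listing
anniversaries and configured band edges; every January 1 (life tables are
calendar-year indexed); and every birthday crossing a life-table band edge
or an age-category edge (13, 25, 45, 60).  Intervals are half-open
`[t_start, t_stop)` with the death indicator on the last interval — the
standard Lexis convention.  Splitting finer never changes aggregate
(O, E, PY) per stratum (refinement invariance, tested), so the exact split
granularity is harmless for estimation.

Conventions worth noting:

- time is measured in years of 365.25 days; dates are registry-resolution
  (whole days);
- an outcome on the listing date receives a minimum duration of half a day
  (0.5/365.25 y) — zero-length rows are undefined in the likelihood;
- calendar years outside life-table coverage clamp to the nearest covered
  year with a warning (follow-up routinely outruns published tables);
- era is a property of the listing year (fixed per candidate), partitioned
  by default as 1988–1998 / 1999–2008 / 2009–2019 and configurable (e.g. a
  two-era 1988–2011 / 2012–2019 split);
- waitlist inactive periods are not modelled; follow-up is continuous.

## Estimation and inference

The likelihood is maximised by Newton–Raphson on the analytic score with up
to 50 step-halvings per iteration and a gradient-ascent fallback when the
observed information is not positive definite.  Convergence requires
`|Δloglik| < 1e-8` and `max|score| < 1e-6`.  The covariance is the inverse
observed information; when its condition number exceeds 1e10 a
pseudo-inverse is used with a warning.  Empty design columns (unobserved
levels) are dropped with a warning and contrasts touching them raise a
"not estimable" error rather than returning numbers.  With `λ* ≡ 0` the
model reduces exactly to Poisson regression with a log-exposure offset
(verified against statsmodels in the tests); the general fit is our own
implementation of the full additive-hazard likelihood.

CIs are Wald intervals on the log scale with z = 1.96.  Nested models are
compared by likelihood-ratio chi-square tests (used for the sex × era
interaction).  Era-stratified RERs refit the model per era subset with era
terms removed; eras without deaths are reported as not estimable, never
silently dropped.

Crude descriptive rates per 100 person-years are `O·100/PY` (absolute) and
`(O−E)·100/PY` (excess), with normal-approximation CIs using `Var(O−E) ≈ O`
and E treated as fixed — the usual descriptive choice in relative survival;
the construction is recorded in the output metadata.  Excess rates may be
negative and are reported as-is.  Crude rates ignore time since listing;
the regression model is the adjusted analysis.

## The synthetic cohort generator

Registry data are not redistributable, so the generator emulates the
structure the analysis assumes, with known truth for every test:

- staggered listing uniformly over 1988-01-01 … 2019-12-31, administrative
  censoring 2019-12-31;
- age at listing from a mixture concentrated in middle age (2% at 0–13,
  4% 13–25, 22% 25–45, 42% 45–60, 30% 60–75) — the qualitative shape of an
  adult kidney waitlist with a paediatric tail; birth dates back-computed
  with continuous within-band ages so birthday/calendar splits are
  exercised;
- 39% female; races White/Black/other at 63/29/8%; organ-specific disease
  labels with kidney defaults;
- expected hazard from a Gompertz-like toy life table
  `q(age) = 1 − exp(−b·e^{s·age + g·male})`, defaults `b = 1e-4`,
  `s = 0.075`, `g = 0.45`: roughly realistic adult magnitudes (e.g. male
  hazard ≈ 0.02/y at 65) and the male mortality bias seen in real
  populations; all races identical by construction;
- baseline excess death rates per follow-up band (0.065, 0.055, 0.05,
  0.045, 0.04, 0.035 per person-year) — highest shortly after listing,
  comparable to observed waitlist mortality scales; multiplied for females
  by the configured per-age-category RER and optional per-era multipliers;
- transplant (censoring) times exponential at 0.25 per person-year,
  independent of everything else; an explicitly labelled stress switch can
  make it sex-dependent to demonstrate informative-censoring bias.

Death times are drawn exactly from the piecewise-constant total hazard by
inverting the piecewise-linear cumulative hazard at a single Exp(1) draw
per candidate.  All draws come from one seeded generator in a fixed order,
so a seed reproduces a cohort bit-for-bit.  Outcome dates are rounded to
whole days (registry resolution); exact latent times are kept in the truth
record.

What the generator does **not** emulate: waitlist status changes and
inactive periods, organ allocation dynamics, relistings and multi-organ
listings, covariate-dependent transplant rates (except the stress switch),
secular trends in background mortality, and missing data.  Passing
recovery and calibration tests therefore shows the estimator is correct
*under the model's assumptions*; it cannot show robustness to violations
real registry data may contain.

## Validation design and problem sizes

The test suite validates, beyond unit behaviour:

- closed-form MLE identities (occurrence/exposure; `μ̂ = D/PY − λ*`);
- agreement of the Newton optimum with an exhaustive likelihood lattice
  (step 1e-3) on random 1–2 parameter fixtures, using an independent
  likelihood implementation — fixtures keep expected hazards small relative
  to event rates so the optimum is interior, since a boundary optimum
  (`μ → 0`) would make the lattice comparison ill-posed;
- exact person-time conservation (1e-9 y) and refinement invariance on
  1 000 random candidates;
- end-to-end recovery of a true RER of 1.30 at n = 20 000 (single estimate
  within ±0.10; |bias of log-RER| < 0.02 over 50 replicates);
- 95% Wald CI coverage between 93% and 97% over 200 replicates at
  n = 5 000;
- likelihood-ratio type-I error of the sex × era test within 5% ± 3% over
  200 replicates at n = 3 000 (a 2004–2015 enrollment window spanning two
  eras keeps the per-replicate cost modest while leaving hundreds of deaths
  per era);
- null calibration: O/E within (0.9, 1.1) and crude excess rates centred
  on 0 under zero excess; all age-category RER CIs covering 1 under a unit
  multiplier.

Replicated designs fit the model with the covariates the generator actually
varies (sex, age category, and era where relevant); the generator assigns
race and disease independently of the hazard, so including them only adds
nuisance parameters.

## Known limitations

- The sex × age interaction design means sparse categories (e.g. 0–12 y)
  give wide CIs; contrasts there are honest but weak at desk-scale n.
- Wald CIs and LR chi-squares rely on large-sample theory; with very few
  deaths in a stratum the pseudo-inverse covariance path may produce
  extreme CI bounds (flagged by warnings).
- The baseline excess hazard is piecewise constant; no spline smoothing.
- Complete-case analysis only; no multiple imputation.
- "Other" race must be present in the life table; no mapping rule from
  finer vital-statistics categories is provided.
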