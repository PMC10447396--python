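# Methods

This note documents the statistical procedures implemented in `heatcase`,
the synthetic data-generating process used to exercise them, the numerical
choices behind the fits, and what the test suite does and does not
establish about real data.

## Design and estimand

The analysis is a time-stratified case-crossover study of daily mean summer
temperature and hospital admission. Each admission defines one stratum: the
event day plus every other same-weekday date in the same calendar month and
year (3 referents in a month with four such weekdays, 4 in a month with
five). Strata built this way are disjoint across events, the property that
removes overlap bias; weekday, within-summer seasonality and long-term
trend are controlled by construction, and all time-invariant personal
characteristics cancel.

Exposure is the lag-averaged daily mean temperature at the patient's
(fuzzed) residential grid cell, `Tmean = (Tmin + Tmax)/2`, averaged over
lags 0–3 by default. *Convention:* "lags 0–3" includes the admission day
(lag 0) plus the three preceding days — a four-value average. The window is
configurable (`lag_set`), and the lag sweep runs windows 0, 0–1, …, 0–5.
Exposure at a referent day re-anchors the full window at that day.
Rainfall, relative humidity and wind speed are linked from the coarse grid
at lag 0 only (their lag structure is not part of the design), and national
holidays enter as an indicator. *Coding note:* internally 1 = holiday;
datasets coded the opposite way (0 = holiday) differ only in the sign of
the holiday coefficient, never in the exposure estimate.

The estimand is the % change in hospitalisation risk per 1 °C:
`100·(exp(β) − 1)`, where β is the log relative rate per °C. The transform
is monotone and is applied to posterior draws or quantiles directly, so the
credible interval of the % change is the transformed interval of β.

## Likelihood and priors

The underlying model is a Poisson regression with one intercept per
stratum. Conditioning on each stratum's total count cancels the intercepts
and leaves the multinomial ("conditional logistic") likelihood

    Σ_strata [ x'_case β − log Σ_days exp(x'_day β) ].

We fit this conditional likelihood rather than the unconditional model with
thousands of explicit stratum effects: the two have identical β inference,
and the equivalence is verified in the tests against an independent
conditional-logistic maximum-likelihood implementation (agreement ≤ 1e-4 on
every coefficient across 50 datasets; observed ≈ 1e-7).

Priors are weakly informative and configurable: Normal(0, 10²) on fixed
effects, half-Normal(0, 1) on the patient-effect SD and on the RW2
smoothness SD. At the sample sizes used the prior contribution is
negligible; `prior_sd=None` gives the flat-prior (ML) fit used by the
oracle tests.

**Patient terms.** Recurrent admissions are accommodated by per-patient
terms for patients with ≥ 2 admissions. Because each admission is its own
stratum, these terms are constant within every stratum and the conditional
likelihood is *exactly* invariant to them: their posterior equals their
prior and the exposure coefficient is untouched. `fit_model` detects
stratum-constant columns (zero within-stratum variance) and reports them as
`decoupled` with their prior spread, rather than estimating them
numerically — this is the exact analytic treatment, not an approximation.
The same mechanism demonstrates the design's central claim: any
patient-level confounder of arbitrary strength (e.g. deprivation) cannot
move the exposure estimate.

**Inference backends.** The default is a deterministic Laplace
approximation: Newton ascent with backtracking to the posterior mode
(convergence when the gradient's max-norm falls below 1e-9 relative;
non-convergence raises with the gradient norm), quantiles from the Gaussian
with covariance the inverse negative Hessian. The `mcmc` backend samples
the same posterior with an affine-invariant ensemble sampler (seeded;
burn-in = max(200, draws/2)) and reports split-R̂ and effective sample
size; R̂ > 1.05 is recorded as a warning. Laplace is exact enough here
because the conditional likelihood is smooth and log-concave and the
posteriors are near-Gaussian at a few thousand strata.

## RW2 exposure-response

The linearity sensitivity analysis discretizes exposure into 20 equal-width
bins over the observed range (assignment to the containing bin; the
discretization is a package choice) and replaces the linear term with one
coefficient per bin under a random-walk-of-order-2 prior: precision
τ·D′D with D the second-difference operator. D′D is rank n−2 with null
space spanned by constant and linear vectors, so the prior shrinks toward
linearity without forcing it. The structure matrix is scaled so the
geometric mean of the intrinsic model's marginal variances is one
(generalized-variance scaling), making the half-Normal(0, 1) hyperprior on
σ = τ^(−1/2) scale-free. A sum-to-zero constraint (orthonormal
reparametrization) plus the weak Normal fixed-effect prior make the
posterior proper; the likelihood identifies the linear component. τ is set
by maximizing the Laplace-approximate marginal likelihood over log τ
(bounded scalar optimization), and curve quantiles condition on the
optimized τ — an empirical-Bayes simplification of full hyperparameter
integration that is adequate at these sample sizes.

Two diagnostics summarise the fitted curve over the central 5–95% of
exposure mass: the maximum absolute deviation of the posterior-median curve
from its own least-squares line (relative to the curve's range), and the
posterior probability that the least-squares slope above a given
temperature exceeds the slope below it (computed from Gaussian posterior
draws of the curve).

## Subgroups and the yearly trend

Subgroup analyses (age 5–15/16–64/65+, sex, period, region, and crossed
partitions) re-fit the full model independently per subgroup; since strata
are per-admission, restricting the pooled stratum table to a subgroup's
records is identical to re-running the pipeline on that subgroup. Groups
below a minimum event count are skipped with a logged warning. The identity
partition reproduces the pooled fit exactly (tested).

The post hoc trend procedure fits the fully adjusted model separately per
calendar year, draws 1000 values of the % change per °C from each year's
posterior, fits one unweighted OLS line of effect on year per draw
(a precision-weighted option exists but is off by default), and summarises
the slope draws by median and 95% interval, in percentage points per year.
Years below the minimum event count are omitted from the regression and
logged. The slope statistic is equivariant under a constant shift of all
yearly effects (tested as a property).

## Synthetic data-generating process

The generator emulates the study's restricted inputs with known ground
truth. Defaults (all configurable) describe a deliberately small study —
three summers (2002–2004), 2000 patients, a 33 × 33 grid of 1 km cells
partitioned into nine 11 × 11 regions, coarse covariates at 11 km — so that
the full pipeline runs in seconds and replicated experiments are cheap.
Sample sizes in the validation experiments are set via `expected_events`,
which solves the Poisson intercept exactly for a target cohort size.

* **Temperature.** Tmean = 15.5 °C + a smooth spatial gradient
  (0.06/0.04 °C per km, centred) + a per-year offset (SD 0.6 °C) + a
  sinusoidal within-summer term (amplitude 2.5 °C, peaking mid-summer) + a
  grid-wide AR(1) daily term (lag-1 correlation 0.7, stationary SD 2.2 °C)
  + small cell-day noise (SD 0.3 °C). Tmin/Tmax are Tmean ∓ a half-range
  (|N(4, 1)|). The AR(1) term supplies the within-stratum day-to-day
  variation the design needs; the magnitude of within-summer seasonality is
  a free parameter because it is not identifiable from the design itself.
  Surfaces start 6 days before June 1 so every lag window up to 0–5
  resolves for June 1 events.
* **Covariates.** Coarse-cell humidity, rainfall and wind are affine maps
  of a standard-normal field with configurable correlation to coarse-cell
  temperature (defaults −0.3, −0.2, 0.0), then clipped/truncated to their
  physical ranges. Humidity preserves the configured correlation almost
  exactly; rainfall and wind are attenuated by truncation at zero.
* **Holidays.** The late-August bank holiday each year plus one random
  June/July weekday — a synthetic calendar, no real holiday data.
* **Admissions.** For every patient-day in June–August, a Poisson count
  with log rate = intercept + weekday + month + year effects + β·X_lag +
  γ′(rain, humidity, wind, holiday) + b_patient, with b_patient ~ N(0,
  0.25²) drawn once per patient. Default β = ln(1.02) (+2% per °C);
  subgroup modifiers multiply β per age group/sex/period/region/year; an
  optional piecewise-linear response (threshold + upper slope) generates
  non-linear truths. A log-rate cap guards against runaway configurations.
* **Defect injection.** Configured counts of duplicates (byte-identical,
  same record id), out-of-extent locations, non-summer dates, under-5 ages
  and missing sex/age are appended and tagged, so the exclusion cascade's
  tallies can be asserted exactly.

**What the generator does not emulate:** real postcode geography and
population density, spatially correlated daily weather beyond the shared
AR(1) term, seasonality in admissions beyond the month/weekday effects,
age- or deprivation-dependent exposure behaviour, diagnostic miscoding
other than the injected defects, and any air-pollution or pollen pathway.
Passing tests therefore establish the *statistical machinery* — referent
selection, linkage conventions, likelihood, priors, trend procedure — under
a correctly specified generative model; they cannot certify robustness to
the misspecifications real admission data contain.

## Cleaning and linkage conventions

The exclusion cascade applies, in fixed order: full-field duplicates →
residence outside the grid extent → admission outside June–August → age < 5
→ missing sex or age. Each record is tallied once, under the first rule it
violates; input = retained + removed is asserted. "Duplicate" is full-field
equality — the conservative definition. Residential locations are fuzzed
uniformly on a 100 m disc before cell assignment (privacy emulation);
points pushed outside the extent are clamped back inside, because fuzzing
must never create exclusions. Grid cells are half-open squares (boundary
points belong to the lower/left cell). A lag window that reaches a missing
day raises an error naming the date; partial averaging is never performed.

## Numerical and edge-case choices

* Strata with zero exposure variance contribute a constant to the
  likelihood and are retained, so record counts reconcile.
* Design-matrix column order is fixed: x_lag, rain, humidity, wind,
  holiday (+ any extra columns).
* All randomness descends from a single root seed via `SeedSequence`
  splitting, recorded in the run manifest; the Laplace pipeline is
  byte-identical on re-run.
* Validation problem sizes: oracle agreement at 50 × 200 events; recovery
  bias/coverage at 100 replicates of ~5000 events; type-I calibration at
  200 replicates of ~2000 events; RW2 linearity at ~10 000 events with a
  +5%/°C linear truth (a well-identified curve, so the deviation ratio
  measures curvature rather than posterior noise) and threshold detection
  at ~6000 events with a +10%/°C slope above 20 °C; trend recovery over 12
  years at ~2000 events/year, replicated 8 times because a single
  ~24 000-event study estimates the slope with an SD comparable to the
  recovery tolerance.

## Known limitations

* The Laplace approximation reports Gaussian quantiles; for very small
  subgroups the MCMC backend is the better check.
* Empirical-Bayes τ in the RW2 fit slightly understates curve uncertainty
  relative to full hyperparameter integration.
* Confounders enter at lag 0 only; no distributed-lag non-linear (DLNM)
  cross-basis is provided.
* No meta-analytic pooling or formal heterogeneity test across regions;
  regional comparisons are by interval overlap.
* The generator's calendar is Gregorian-correct but its holiday set is
  synthetic; no real postcode or map geometry is handled anywhere.
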