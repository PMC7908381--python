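# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and what the test suite does and does not
establish.

## 1. Design and likelihood

The analysis is a case-crossover study: each acute cardiovascular
admission (the *case day*) is compared to referent days of the same
subject, so every time-invariant subject characteristic — and any exposure
component that is constant within the matched window — cancels from the
likelihood.  Two referent schemes are implemented:

* **Symmetric bidirectional**: referents at exactly −7 and +7 days.
  Matching on the day of week removes weekly patterns, and the
  bidirectional placement removes slow time trends to first order.  Near
  the study boundary one referent may be lost; a stratum with a single
  surviving referent is *retained* as a 1:1 set (the conditional
  likelihood handles variable set sizes), and a stratum with no referent
  is dropped.
* **Time-stratified**: referents are all days in the same calendar month
  and year sharing the case's weekday (3 or 4 controls).  This is the
  standard sensitivity design; the same-month-same-year reading is used.

Qualifying events are acute (unscheduled) admissions whose primary ICD-9
code lies in 390–459, tested on the integer value of the first three
characters (V/E codes are excluded; unparseable codes are rejected with a
warning).  Multiple admissions by one subject form independent strata;
strata closer than 14 days may share calendar days, which the conditional
independence assumption of the design tolerates.

For stratum *i* with day set *J_i* and case day *c(i)*, the conditional
log-likelihood is

    ℓ = Σ_i [ η_{i,c(i)} − log Σ_{j∈J_i} exp(η_{ij}) ],
    η_{ij} = x_{ij}'β + w_{ij}'γ,

with x the lag-0..6 exposure vector (µg/m³) and w optional calendar
covariates.  Adding a constant to all exposures within a stratum leaves ℓ
unchanged (softmax shift invariance); this is asserted exactly in tests.

## 2. Constrained distributed lags

Daily concentrations are strongly autocorrelated, so the 7 per-lag
coefficients are not separately estimable at a few hundred cases.  The
lag curve is therefore constrained through β = Cθ with

* linear basis: rows (1, l), q = 2;
* log-linear basis: rows (1, ln(l+1)), q = 2 — ln(l+1) keeps lag 0
  defined;
* unconstrained basis: C = I (available for diagnostics and for the
  collapsed-design oracle).

Because η = (Cθ)'x = θ'(C'x), a constrained fit is identical to an
unconstrained fit on the collapsed covariates z = C'x.  This exact
algebraic equivalence is the main oracle for the constraint machinery and
is asserted to 1e-6 in the tests and the acceptance run.

Lag structures are compared by BIC = −2ℓ + k·ln(n) with n the number of
retained strata (= cases) — the standard sample-size choice for a
conditional likelihood, where each stratum contributes one multinomial
observation.  Ties are broken by the declared candidate order (linear
first).  Calendar covariates (three indicators plus linear and quadratic
mean lag 0–1 apparent temperature) can be attached; with irrelevant
covariates the BIC penalty dominates on average, reproducing the
preference for unadjusted models at this sample size.

## 3. Estimation and inference

The likelihood is maximised by Newton–Raphson with analytic gradient and
Hessian (both exact; verified against central finite differences to 1e-6
relative).  Settings: start at θ = 0, tolerance 1e-8 on the gradient
max-norm, at most 50 iterations, step-halving whenever a step would
decrease ℓ.  The likelihood is concave, so any interior optimum is
global; multi-start agreement is tested.  Separation — the likelihood
increasing without bound, e.g. when case days always carry the larger
exposure — is declared when the parameter norm (per µg/m³ scale) exceeds
50, and raises a dedicated error rather than returning a spurious
"converged" answer.  Non-convergence raises an error carrying the last
iterate.  The covariance is the inverse negative Hessian at the optimum.

Coefficients are kept per 1 µg/m³ internally; the reporting scale enters
only at the end: OR_l = exp(10·c_l'θ) with se(log OR) = 10·√(c_l'Vc_l)
and 95% Wald intervals using the normal 0.975 quantile.  The delta-method
standard error is validated against a nonparametric stratum bootstrap
(agreement within 15%).  Under the linear basis, log OR is affine in the
lag, so OR_l = OR_0·(OR_1/OR_0)^l exactly; `extrapolate_lag_or` exposes
this identity, which also serves as an internal-consistency check on
published linear-lag OR tables.

Effect modification by a binary factor m: the full model uses
η = z'θ + m·(z'δ) (z = C'x, linear basis only — the two δ terms shift the
lag function's intercept and slope), the reduced model sets δ = 0, and
the test is 2(ℓ_full − ℓ_reduced) against χ²₂ at the 0.05 level.  The
modifier's main effect is constant within a stratum, hence absorbed by
matching and deliberately not included.  For a binary modifier without
shared covariates the full model is an exact reparameterisation of two
independent per-level fits; the equality of log-likelihoods (and the
recoding map θ↔θ+δ, δ↔−δ) is asserted to 1e-6.  Type-I error of the LRT
is checked empirically at 1000 null replicates.

## 4. The synthetic-data generator

The generator emulates the structure the analysis assumes, with defaults
fixed once to the study conditions the pipeline is meant for:

* **Cohort**: 1585 geocoded subjects, 41% in an urban western strip and
  59% in a suburban remainder of a 6 km × 4 km extent; five binary risk
  factors with plausible prevalences (≥85 years 5%, male 45%, ever-smoker
  50%, occupational exposure 45%, pre-existing cardiovascular/respiratory
  disease 25%).  Area is a deterministic function of the coordinates.
* **Exposure fields**: per pollutant and resolution (1 km-like "coarse",
  200 m-like "fine"), daily cell values are max(0, annual mean + seasonal
  sinusoid + shared regional AR(1) + fixed cell offset + cell noise).
  The regional term is keyed by pollutant only, so the two resolutions of
  one pollutant are realisations of the same atmosphere and strongly
  correlated.  Defaults (e.g. PM₁₀: mean 26, amplitude 7, AR(1) 0.75 with
  innovation sd 3.5) give a pooled IQR of roughly 10–12 µg/m³ for the
  combustion pollutants and ~25–30 µg/m³ for ozone (which peaks in summer
  instead of winter).  Truncation at 0 keeps concentrations physical at
  the cost of a small upward bias in the marginal mean — negligible at
  these means (~3σ above 0).  A warm-up of max-lag days precedes the
  study start so lag vectors are complete from day one.
* **Calendar**: summer-reduction flag 15 July–31 August; holidays from a
  fixed rule (24–26 and 31 December, 1 January, Easter ±1 day by the
  Gregorian computus, 25 April, 1 May, 15 August, 1 November); influenza
  window 1 January–15 February by default; apparent temperature an annual
  sinusoid (mean 15 °C, amplitude 10 °C, peak late July) plus noise.
* **Events**: per subject-day, P(event) = min(1, h₀·exp(Σ_l (a+b·l)·x_{t−l}
  + confounder terms)) with the true lag effect a = ln(1.268)/10,
  b = (ln(1.190) − ln(1.268))/10 per µg/m³ — i.e. a lag-0 OR of 1.268 per
  10 µg/m³ declining below 1 by lag 5–6.  The baseline hazard 1.85e-5 per
  subject-day was calibrated (by measuring the realised hazard multiplier
  over seeds) so the default five-year study yields ≈137 qualifying
  events.  If more than 1% of subject-day probabilities hit the cap the
  generator aborts with a calibration error.  Repeat events per subject
  are allowed by default and configurable off.  A configurable fraction
  of non-qualifying admissions (scheduled, or acute non-cardiovascular)
  is added to exercise the event filters.
* **Direct matched-set sampler** (`simulate_matched_sets`): for
  calibration experiments, day sets are drawn from one seasonal AR(1)
  series and the case index is sampled with probability softmax(β'x) —
  exactly the conditional likelihood — so parameter recovery, CI coverage
  and LRT calibration are measured against a simulator that is correct by
  construction, at a fraction of the cost of the full subject-day hazard
  simulation (which is also exercised end-to-end).

All randomness flows from a single integer seed through named
`numpy.random.SeedSequence` streams; every artefact is byte-reproducible.

What passing tests show — and what they do not: the synthetic fields have
the right marginal scale, seasonality, autocorrelation and cross-
resolution correlation, and events follow the modelled hazard exactly; so
the tests establish correctness of the *machinery* (likelihood,
constraints, inference, bookkeeping) and its calibration *under the
model*.  They cannot establish anything about real exposure-measurement
error, spatial misclassification between true and modelled fields,
unmeasured time-varying confounding, or outcome miscoding in real
discharge records.

## 5. Linkage and assembly conventions

* Cells are half-open, [edge, next_edge), with floor indexing — every
  in-extent point belongs to exactly one cell; the containing cell (not
  the nearest centroid) is assigned.
* Missing exposure days flag the lag vector incomplete; assembly drops
  the affected day (a dropped case day drops the stratum), never imputes.
* Quartiles use linear interpolation between order statistics.
* Paired case/control-day comparisons use the classic paired t-test with
  n−1 df; a zero-variance difference vector yields an explicit
  "undefined" flag rather than p = 0.  Flags mark p < 0.05 (significant)
  and 0.05 ≤ p < 0.1 (borderline) in the report tables.
* Report percentages are rounded to integers in the human-readable
  table; exact fractions are kept alongside in machine-readable columns.

## 6. Problem sizes used in checks

The stochastic checks use 200 replicates of 2000 matched sets for CI
coverage and bias, 1000 replicates of 300 sets for LRT calibration, 500
sets for the collapsed-design oracle, and a handful of full five-year
study simulations for the end-to-end odds-ratio recovery — sizes chosen
to put Monte-Carlo error well inside the asserted bands while keeping a
complete run fast on a single CPU.

## 7. Known limitations

* Only the two lag constraints described above; no polynomial or spline
  lag bases, no penalised distributed-lag models.
* Interaction testing is implemented for the 2-parameter linear basis and
  binary modifiers only.
* The exposure generator stands in for a full atmospheric/machine-learning
  exposure model: it reproduces the statistical structure the analysis
  consumes, not real geography, meteorology or chemistry.
* Wald intervals and the χ² reference for the LRT are asymptotic; at a
  few dozen strata per level, stratified estimates can be unstable and
  are reported as not estimable when fitting fails.
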