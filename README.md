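# lagcrossover

Case-crossover, distributed-lag analysis of short-term air-pollution
effects on acute cardiovascular hospitalizations — with a fully seeded
synthetic study generator, so the entire pipeline runs and is testable
without any restricted health or exposure data.

The package is aimed at environmental epidemiologists and biostatisticians
studying acute outcomes in small cohorts with high-resolution (gridded,
residence-linked) exposure estimates: settings where exposure is assigned
from daily pollutant fields at the home address, cases number in the
hundreds, and between-day exposure collinearity forces a low-dimensional
lag structure.

## The design and the model

Each hospitalization is compared only to the same person on nearby
referent days (case-crossover), so all time-invariant subject
characteristics cancel.  Two referent schemes are implemented:

* **symmetric bidirectional** — control days exactly 7 days before and
  after the admission;
* **time-stratified** — all days sharing the admission's weekday within
  the same calendar month and year (used as a sensitivity analysis).

For each matched set *i* with days *j* (one case among the referents), the
conditional-logistic likelihood is

```
L(θ) = Π_i  exp(η_case,i) / Σ_{j∈i} exp(η_ij),      η_ij = Σ_{l=0}^{6} β_l x_{ij,t−l} + γ'w_ij
```

where `x_{t−l}` is the pollutant concentration (µg/m³) at lag *l* in the
subject's grid cell and `w` are optional calendar covariates (summer
population reduction, holidays, influenza epidemics, linear + quadratic
mean lag 0–1 apparent temperature).  Because ~7 free lag coefficients
cannot be estimated from collinear daily series at this sample size, the
lag curve is constrained to `β_l = θ₁ + θ₂·l` (linear in the lag) or
`β_l = θ₁ + θ₂·ln(l+1)` (linear in the lag logarithm); the structure is
chosen by BIC.  Effects are reported as odds ratios per 10 µg/m³,
`OR_l = exp(10·β_l)`, with delta-method 95% Wald intervals.  Effect
modification by a binary factor *m* is tested by adding interaction shifts
of the lag function's intercept and slope, `η = z'θ + m·(z'δ)` with
`z = C'x`, against the reduced model via a df-2 likelihood-ratio test.

The core estimator, `ConditionalLogisticDLM`, follows scikit-learn
conventions (`fit(X, y, groups)`, `get_params`, fitted attributes with a
trailing underscore) and maximises the exact conditional likelihood by
Newton–Raphson with analytic gradient and Hessian.

## Worked example

```python
from lagcrossover import (SimulationConfig, simulate_study, filter_events,
                          assemble_strata, bic_select)
from lagcrossover.report import pooled_summary, paired_t

cfg = SimulationConfig(seed=42)          # 1585 subjects, 2011–2015
study = simulate_study(cfg, resolutions=("coarse",))
events = filter_events(study["events"])  # acute, ICD-9 390–459 only
grid = study["grids"][("pm10", "coarse")]
strata = assemble_strata(events, study["cohort"], grid, cfg.period,
                         pre_filtered=True)
print(f"{len(events)} qualifying admissions -> {len(strata)} strata")
s = pooled_summary(strata)
print(f"pooled pm10: mean {s.mean:.1f}, sd {s.sd:.1f}, IQR {s.iqr:.1f}")
t = paired_t(strata, -7)
print(f"case vs day-7 control: diff {t.mean_diff:.2f}, "
      f"t = {t.t_statistic:.2f}, p = {t.p_value:.3f}")
best, table = bic_select(strata)
print(best.or_table().round(3))
```

prints

```
146 qualifying admissions -> 146 strata
pooled pm10: mean 27.7, sd 8.0, IQR 10.6
case vs day-7 control: diff 1.27, t = 2.01, p = 0.046
 lag    or  ci_low  ci_high  se_log_or
   0 1.152   0.978    1.357      0.084
   1 1.122   0.995    1.267      0.062
   2 1.093   1.004    1.191      0.044
   3 1.065   0.993    1.143      0.036
   4 1.038   0.951    1.132      0.044
   5 1.011   0.894    1.143      0.063
   6 0.985   0.835    1.163      0.085
```

Read: case days carry on average 1.27 µg/m³ more PM₁₀ than the same
subjects' day −7 controls (paired t, p = 0.046); the BIC-selected linear
lag model estimates a lag-0 odds ratio of 1.152 per 10 µg/m³, declining
geometrically with the lag and dipping below 1 by lag 6 — the
"harvesting" shape in which an exposure peak depletes the susceptible
pool.  (The generator's true lag-0 OR is 1.268; a single ~140-case study
estimates it with the wide confidence interval shown.)

The same pipeline is scriptable from a shell:

```bash
lagcrossover simulate --outdir data --seed 42
lagcrossover assemble --indir data --out strata.csv --design symmetric
lagcrossover fit --strata strata.csv --out fit.json
lagcrossover report --outdir report --seed 42       # full bundle
```

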