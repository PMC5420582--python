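# prandikit

Lifetime feeding ("prandiology") analysis for insect cohorts measured with a
capillary feeder (CAFE) assay, built around the Mediterranean fruit fly
(*Ceratitis capitata*) study design: individually caged flies drink a liquid
sugar or protein diet from a calibrated capillary for 5 h per day, daily egg
production is counted for females, and every individual is followed until
death.

The package covers the full analysis chain:

* **Intake quantification** — the meniscus descent of each fly's capillary is
  corrected by subtracting the descent of a fly-free control capillary kept in
  the same humidity-preservation chamber (HPC); negative differences are
  clipped to zero and flagged.
* **Event-history matrices** — one row per fly, one column per day of life,
  valued by daily intake or egg count, rows ordered longest-lived first.
* **Response surfaces** — cohort daily means (age *x*, mean intake *y*, mean
  eggs *z*) are smoothed non-parametrically with two-predictor tricube LOESS
  (local planes over a fraction *q* of nearest points) and fitted
  parametrically with a five-parameter product-Lorentzian peak

  ```
  f(x, y) = α / { [1 + ((x − x₀)/β)²] · [1 + ((y − y₀)/γ)²] }
  ```

  where (x₀, y₀) is the age/intake location of peak egg production, α the peak
  amplitude (eggs/day), and β, γ the age and intake half-widths.  Inference
  follows the nonlinear-regression ANOVA "corrected for the mean": 4
  regression df, n − 5 residual df, Wald standard errors from
  `ms_res · inv(JᵀJ)` with the analytic Jacobian.
* **Cohort summaries** — cumulative intake over age windows, female/male daily
  intake ratios, Kaplan–Meier survival with restricted-mean and median
  summaries, and the Mantel–Cox log-rank test.
* **A synthetic cohort simulator** — Gompertz lifespans, cohort-specific
  age-patterned intake trajectories, and Poisson/negative-binomial egg counts
  whose conditional mean is the Lorentzian surface, so every stage can be
  tested against known ground truth.

## Worked example

```python
import prandikit as pk

study = pk.simulate_study(pk.SimulationConfig(seed=1))
females = study.cohort(pk.Sex.F, pk.Diet.PROTEIN_LIQUID)
points = pk.aggregate_daily_means(females, max_age=60)
params, inference = pk.fit_lorentzian(points)
print(f"x0 = {params.x0:.2f} d, y0 = {params.y0:.4f}, alpha = {params.alpha:.2f} eggs/d")
print(f"R2 = {inference.r2:.3f}, F = {inference.F:.1f} on ({inference.df_reg}, {inference.df_res}) df")
```

prints

```
x0 = 28.40 d, y0 = 0.1192, alpha = 14.22 eggs/d
R2 = 0.970, F = 447.6 on (4, 55) df
```

i.e. the fitted surface locates peak egg production near age 28 days at a
protein intake of ~0.12 intake units (the simulator's generating values are
x₀ = 28.34, y₀ = 0.1258), explains 97% of the variance in the daily means,
and the ANOVA F is overwhelmingly significant.

The same pipeline is available from the shell:

```sh
prandikit simulate --out-dir data --seed 1
prandikit validate data/F-protein-records.csv data/F-protein-controls.csv
prandikit fit-lorentzian data/F-protein-records.csv data/F-protein-controls.csv --out fit.json
prandikit event-chart data/F-sugar-records.csv data/F-sugar-controls.csv --out matrix.csv
prandikit survival data/F-sugar-records.csv:data/F-sugar-controls.csv \
                   data/M-sugar-records.csv:data/M-sugar-controls.csv --out survival.json
```

## Notes

Intake is kept in a single dimensionless "intake unit" (the unit of the
fitted tables); see `docs/methods.md` for the rationale, the simulator's
assumptions, and known limitations.
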