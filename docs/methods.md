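# Methods

## Study design and data model

The package analyses lifetime feeding experiments in which individually caged
adult flies receive a liquid diet (20% sucrose or 20% protein hydrolysate)
from a calibrated glass capillary for 5 h per day, with the complementary
nutrient available *ad libitum* in solid form.  Five fly cages plus one
fly-free control cage share a humidity-preservation chamber (HPC) that keeps
relative humidity near 80% during exposure to suppress evaporation.  The four
cohorts are female/male × sugar-liquid/protein-liquid, ~30 flies each,
followed until every individual has died; females are also scored for daily
egg production.

A *feeding record* is one fly-day: raw meniscus descent, egg count (females
only), and vital status.  Corrected intake is
`max(raw_descent − control_evaporation, 0)`, matched per (chamber, day); a
negative difference is measurement noise and is clipped to zero with a
warning rather than an error.  A missing day (no row) is distinct from a zero
reading and stays missing through every downstream computation.

### Intake units

Daily intake is kept in a single dimensionless "intake unit" — the unit in
which the fitted surface tables are expressed (peak intakes of roughly
0.1–0.6 per day).  No conversion between capillary volume (μl of solution)
and solute mass (μg) is attempted: the source material is internally
ambiguous about the unit, and fidelity to the fitted coefficient tables takes
priority over a unit guess.

## Lorentzian egg-production surface

Cohort daily means over ages 1–60 give at most 60 observations
(x = age in days, y = mean corrected intake among flies alive that day,
z = mean eggs among those flies).  Aggregating to daily means is an
assumption: only the residual degrees of freedom (n − 5 = 55, total 59) of
the published tables constrain how individual records became fitted points,
and daily means over a 60-day horizon are the natural construction that
yields n = 60.

The parametric model is a product of two Cauchy-shaped factors,

    f(x, y) = α / {[1 + ((x − x0)/β)²][1 + ((y − y0)/γ)²]},

with peak location (x0, y0), amplitude α (eggs/day) and half-widths β (days)
and γ (intake units): f(x0 ± β, y0) = f(x0, y0 ± γ) = α/2.  β is paired with
age and γ with intake, following the formula; the alternative prose pairing
is inconsistent with the coefficient magnitudes (β ≈ 9–13 days versus
γ ≈ 0.07–0.27 intake units).

Fitting minimises the unweighted residual sum of squares by
Levenberg–Marquardt (MINPACK via `scipy.optimize.least_squares`, analytic
Jacobian), with convergence declared at a relative SS change below 1e-10
(`tol`), capped at 500 iterations.  Positivity of α, β, γ is enforced by
optimising their logarithms; the Lorentzian is invariant to the signs of β
and γ, so this removes a sign ambiguity without constraining the fit.
Default start values: (x0, y0) at the arg-max observation, α at max z, β and
γ at half the predictor ranges.  Degenerate inputs — fewer than 6 points or a
constant response — are rejected before fitting.

### Inference

The ANOVA is "corrected for the mean": ss_total = Σ(z − z̄)², ss_res = Σ
residuals², and ss_reg := ss_total − ss_res *by definition* (the additive
decomposition is not automatic in nonlinear regression).  Degrees of freedom
are 4 (5 parameters − 1 for the mean correction), n − 5 and n − 1;
F = ms_reg/ms_res with an upper-tail p on (4, n − 5); R² = ss_reg/ss_total,
adjusted R² = 1 − ms_res/(ss_total/df_total), SE of estimate = √ms_res.
Parameter covariance is ms_res·inv(JᵀJ) at the estimates with the analytic
Jacobian; t = estimate/SE with two-sided p on n − 5 df.  These identities are
checked to machine precision in the test suite, and pushing the published
sums of squares through the same formulas reproduces the published F, R²,
adjusted R², SE-of-estimate and t values to print precision.

A caveat demonstrated by simulation: daily-mean egg counts are
heteroscedastic (Poisson-mean variance divided by the number of flies alive,
largest near the production peak), while the classical covariance assumes
homoscedastic errors.  Wald 95% intervals therefore cover the generating
(x0, y0) slightly below nominal in replicate simulated cohorts (~90–93%
observed); under homoscedastic Gaussian noise on the same designs coverage is
exactly nominal.  This is a property of the classical method on such data,
inherited faithfully, not corrected away.

## LOESS surface

Two-predictor locally weighted regression of degree 1: for each query point,
the ⌈q·n⌉ nearest observations in standardised predictor space (each
predictor scaled by its sample SD before Euclidean distance) are selected,
weighted by the tricube kernel w(u) = (1 − |u|³)³ of distance scaled to the
neighbourhood's maximum distance, and a weighted least-squares plane is
evaluated at the query.  Admissible smoothing fractions satisfy
(λ + 1)/n < q < 1 with λ = 1.  Degree-1 locality makes the smoother exact on
plane-generated data for any admissible q, which the tests exploit as an
oracle; a `weights="uniform"` option reduces the fit at q → 1 to the global
OLS plane for cross-checking.  Collinear neighbourhoods raise an error naming
the query.  The smoother is written here because no installed package offers
two-predictor tricube LOESS with this neighbourhood rule.

## Survival summaries

Kaplan–Meier curves, the median and its log-log confidence interval, and the
log-rank test come from lifelines.  Mean survival is the restricted mean to
the largest observed time, computed exactly as the area under the KM step
function with the Klein–Moeschberger/Greenwood variance
Σ A_i² d_i/(n_i(n_i − d_i)); with complete follow-up (the study design — no
censoring) this equals the arithmetic mean of the death days with SE equal to
the population SD over √n, which the tests verify.  The median's SE is
reported as CI width / (2·1.96), an approximation chosen because the log-log
CI is the primitive lifelines exposes.  Censoring support exists for
generality but defaults off.

## Synthetic cohorts

The simulator reproduces the study's statistical structure with known ground
truth; one integer seed fixes the output bit-for-bit.

* **Lifespans** are Gompertz — right-skewed and actuarially standard for
  medflies — parameterised by the cohort mean (defaults 38.935, 50.833,
  40.057, 75.037 days for F/sugar, M/sugar, F/protein, M/protein) and a
  common shape b = 0.1/day (hazard a·e^{bt}; the baseline a is solved from
  the closed form E[T] = e^{a/b}E₁(a/b)/b).  Draws are truncated at one day
  and rounded up.  b = ∞ is the degenerate zero-variance limit used in tests.
* **Intake trajectories** are smooth parametric age profiles per cohort —
  sugar-fed females: high intake over the first ~10 days declining to a low
  plateau; sugar-fed males: early intake, mid-life dip, broad late
  resurgence with a weekly oscillation; protein-fed females: unimodal
  mid-life peak centred at age 30 (intake range ~0.06–0.16, straddling the
  surface's y0 = 0.1258); protein-fed males: constant moderate level —
  multiplied by lognormal day-to-day noise with CV 0.25.  The profile shapes
  are constrained only qualitatively by the source charts; their levels and
  the noise scale are the package's own choices of realistic values, not
  estimates.
* **Egg counts** are Poisson by default (negative binomial with size
  `egg_dispersion` when finite) with conditional mean equal to the diet's
  Lorentzian surface at (age, that fly's true intake that day).  A
  `deterministic_eggs` switch records the surface mean itself, giving
  noise-free cohorts on which the fit recovers the generating parameters to
  machine precision (a pipeline identity test).
* **Raw readings** are true intake + the chamber's evaporation draw
  (N(0.05, 0.01²) clipped at 0, shared by the five flies of an HPC and its
  control) + N(0, 0.005²) reading noise, so evaporation correction recovers
  true intake in expectation.

What the simulator does *not* emulate: mating-window gating of oviposition
(eggs depend on age and intake only, because that is the fitted model),
between-fly frailty in fecundity, senescent decline in capillary access, and
any humidity or temperature effect.  Passing tests therefore validate the
pipeline's arithmetic and statistical behaviour under the assumed generative
model, not the biological completeness of that model.

## Problem sizes and numerical choices

Tests and the acceptance script use 30-fly cohorts (the study's size), 60
aggregated surface points, 200 replicate cohorts for coverage, 10⁴ label
permutations for the log-rank oracle, and ~10⁵ draws for distributional
checks — sizes at which Monte-Carlo error is far below the assertion
tolerances while the whole suite runs in seconds.  Ties in the event-matrix
row ordering break lexicographically by fly id; LOESS requires at least three
positively weighted, non-collinear neighbours; the Lorentzian fit reports a
convergence error carrying the last iterate rather than silently returning.
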