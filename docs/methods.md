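# Methods

This note documents the models implemented in `childmort`, the choices made
where the design was genuinely open, and what the synthetic-data experiments
do and do not demonstrate.

## Under-5 mortality model

### Data model

Observed rates are treated as the true rate times a multiplicative error.
On the log scale, for observation *i* in country *c*:

```
log y_i = f_c(t_i) + b_{s(i)} + u_{j(i)} + eps_i
Var(eps_i) = se_i^2 + sigma^2_{s(i)}
```

- `se_i` — the reported sampling SD of the log observation (from the data
  file; treated as known).
- `b_s` — mean log error-multiplier of source type `s` in
  {VR, SRS, survey_FBH, census_SBH}. Vital registration is the zero-bias
  anchor: `b_VR = 0` fixes the identifiable level of the system. Other
  types get `b_s ~ N(0, 0.3^2)`, pooled across all countries in a fit batch,
  so countries without VR borrow the bias information learned where VR and
  surveys overlap.
- `u_j` — a persistent effect for each individual non-anchor series,
  `u_j ~ N(0, omega^2_s)` with a per-source-type variance under an
  InvGamma(1.5, 0.003) prior. This term matters: a survey programme that
  sits systematically high or low produces *correlated* errors across its
  ~12 retrospective points. Modelling it as iid extra noise lets the level
  estimate average it away and understates uncertainty precisely in the
  countries that rely on one or two survey series; with the series effect the
  90% intervals are calibrated (see Validation).
- `sigma_s` — extra non-sampling SD per source type, half-normal(0.1) prior,
  shared across countries.

### Trend model

`f_c` is a cubic B-spline on a clamped knot grid with 2.5-year spacing,
with a first-order random-walk prior on the coefficients,
`diff(beta_c) ~ N(0, tau^2)`, and a weak level prior
`beta_{c,0} ~ N(ybar_c, 2^2)` centred at the country's precision-weighted
mean log observation. The smoothing variance `tau^2` is shared across the
batch with an InvGamma(1, 0.005) prior; it doubles as the per-year innovation
scale used when extrapolating (per-year SD `tau/sqrt(knot spacing)`).

### Sampler

Conditional on `(tau^2, sigma, omega^2)` the model is jointly Gaussian in
all spline coefficients, source biases and series effects, with an arrowhead
precision structure: country blocks are independent given the shared biases.
One sweep therefore draws the biases exactly from their marginal (Schur
complement over country blocks), then each country's local block exactly,
then `tau^2` and the `omega^2_s` conjugately, and each `sigma_s` by a
Metropolis step on its log. Four chains (default 400 warmup + 500 kept
draws each) are run from dispersed variance initialisations;
`fit_b3` *raises* if split-R-hat on monitored trajectories or biases exceeds
1.05 rather than returning a silently unconverged posterior. Because the
Gaussian block is drawn exactly, mixing is near-iid and R-hat is typically
below 1.01.

### Extrapolation

Countries whose series end before the common endpoint are truncated at their
last observation year and extended draw-by-draw. In extrapolated year `k`
the per-year log decrement is `rho^k * a_d + (1 - rho^k) * a_global` with
`rho = 0.9`: a draw's own recent trend `a_d` (ARR over its last 10 fitted
years) dominates at first and the global trend (cross-country median ARR)
takes over with horizon. Gaussian innovations at the posterior smoothing
scale make intervals widen with extrapolation length. The blend weight and
window are configurable; the defaults encode "a combination of the country
and global trend" with a one-decade memory.

### Reporting

Estimates are posterior medians with 90% equal-tailed intervals (5th/95th
percentiles) on the rate scale. Rates are stored unrounded; display rounding
to one decimal happens only at the reporting layer.

## Neonatal mortality

NMR is estimated through the ratio `R(c,t) = NMR/(U5MR - NMR)`:

- `W(u5mr)` — global expected ratio, `log W = b0 + b1 log u5mr + b2 (log
  u5mr)^2`, fitted by least squares to pooled country-year pairs of observed
  ratio and estimated U5MR. The quadratic term is kept because the data
  decide whether the log-log relation is exactly linear; on noise-free linear
  input the fit recovers `b2 = 0` exactly.
- `P(c,t)` — country multiplier, `log P` a B-spline with the same
  random-walk smoothing machinery, level prior `N(0, 0.3^2)` centred at
  `P = 1`. Countries with no usable NMR observations therefore revert to the
  global relation. Ratio observations inherit the log-scale sampling error of
  the NMR observation scaled by the delta-method factor `(u/(u - n))^2`;
  summary-birth-history series are excluded from the NMR data (they cannot
  support direct neonatal estimation).
- NMR draws are `U5MR_draw * R_draw/(1 + R_draw)` with U5MR posterior draws
  paired one-to-one with ratio draws — a hard guarantee of NMR < U5MR per
  draw, and joint uncertainty propagates without modelling a cross-correlation
  the data cannot identify.

## Birth-week cohort death counts

Rates are converted to hazards by exact inversion of the two cohort
probabilities: `h_neo = -ln(1 - nmr/1000)/(28/365.25)` over ages
[0, 28/365.25) years and `h_post = -ln((1 - u5mr/1000)/(1 -
nmr/1000))/(5 - 28/365.25)` over the rest of the first five years,
piecewise-constant within calendar years. Each annual birth cohort is split
into 52 weekly cohorts seeded at week midpoints (week = 1/52 year exactly);
every 1/52-year age step is split exactly at calendar-year boundaries and at
the neonatal age boundary, so survival decrements integrate the hazard
exactly and each death lands in the correct year and age group. Consequences
verified by tests: cohort conservation holds to ~1e-16 relative, steady-state
annual deaths equal `births x rate/1000` to machine precision, and a
1/365-step brute-force microsimulation agrees within 0.07% on a toy world
with strongly time-varying hazards (the residual is the oracle's own
within-day discretisation).

Cohorts born within five years of the reporting end are exposed using the
last available year's schedule for later years (truncation rule); death
intervals are computed by running the cohort engine per posterior draw with
livebirths held fixed, so they reflect rate uncertainty only. The engine is
vectorised over draws and thins to 200 draws by default to bound runtime.

The production systems this emulates use finer age splits (via infant
mortality, which is out of scope here); the two-segment schedule is the
declared approximation and the microsimulation bounds its numerical error,
not that structural choice.

## Scenarios (2020–2030)

- ARR convention: `ARR = ln(r_1/r_2)/(t_2 - t_1)` — positive for decline.
  The 2010–19 ARR is computed from posterior-median rates; an optional
  per-country-year rate-adjustment input removes crisis mortality from the
  trend (the adjustments themselves are an external input).
- `constant_2019`: flat at the 2019 level.
- `current_trends`: exponential decline at `max(ARR, 0)` (mortality increases
  are not projected forward), clamped at the lowest observed rates — U5MR
  1.7, NMR 0.85 per 1000 — once reached.
- `achieve_sdg` / `achieve_hic`: countries already at or on track for the
  target (current-trends 2030 value at or below it) keep their current-trends
  path; all others follow the constant required ARR `ln(r_2019/target)/11`,
  landing exactly on the target (25/12 for SDG, 5.0/2.9 for the HIC average)
  in 2030.
- Projected NMR is capped at 0.79 × projected U5MR each year, the highest
  ratio observed in a country with reliable vital registration. U5MR and NMR
  are projected independently and the cap applied afterwards — the literal
  reading of the scenario rules; a joint projection would need a model of the
  ratio's trajectory that the rules do not specify.
- Deaths use the same cohort engine with one shared livebirths projection
  across scenarios, so averted-death differences isolate mortality. Floors
  can never bind on SDG paths (floor < target by construction).

## Progress classification and aggregation

A country has *achieved* a target iff its 2019 estimate is at or below it;
*on track* iff the current-trends 2030 value reaches it; otherwise
*acceleration needed* with factor `required ARR / max(current ARR, 1e-6)` —
the floor gives stagnating countries a finite factor and places them in the
highest band (≥3, "must at least triple the pace"). The projected
achievement year is `2019 + ceil(ln(est/target)/ARR)`, reported as ">2099"
for stagnation or beyond-century dates.

Death aggregates sum posterior draws across group members cell-wise and take
quantiles of the sums (never sums of quantiles; the draw-level sums are exact
while quantiles are subadditive). Group rates are births-weighted means of
member rates — a convex combination bounded by the member range, exact when
members coincide and within the cohort model's nonlinearity (relative error
below ~rate/1000) otherwise, since deaths are nearly linear in the rate at
these magnitudes.

## Synthetic worlds

The generator produces the structure the estimator assumes, deliberately:
true log-U5MR trajectories are exponential-decline mean paths (levels ~10–220
per 1000 in 1985, ARRs 0.5–5%/yr) with random-walk coefficient noise on the
same 2.5-year knot grid; true NMR comes from the global ratio relation (its
default coefficients are calibrated to the published 1990/2019 global rate
pairs) times a smooth country multiplier; livebirths follow compound growth.
Observation series emulate the four source types with signatures
(mean bias multiplier, per-series jitter SD, sampling SD, extra SD):
VR (1.0, 0, 0.025, 0.01), SRS (1.0, 0.02, 0.04, 0.02), survey_FBH
(0.97, 0.04, 0.07, 0.03), census_SBH (0.90, 0.06, 0.10, 0.05). Bias
magnitudes for non-VR sources are not published quantities; these are the
package's fixed test conditions. Low-mortality countries are VR-only;
others mix SRS/survey/census series, some ending 2–8 years before the
endpoint so extrapolation is exercised. The default world is 25 countries
over 1985.5–2019.5; recovery and coverage experiments use 50 countries, a
size chosen for minutes-scale runtimes on one CPU.

Because truth and model share a family, passing recovery and coverage tests
demonstrates internal correctness (the sampler targets the right posterior,
the intervals mean what they claim under the assumed error structure) — not
that real observation errors follow these distributions, that real biases
are constant within a series, or that real trends are splines. The
generator also omits mortality crises, HIV-type epidemics and any feedback
of mortality on fertility.

## Validation summary

What the test suite and acceptance script compute (not asserted from
memory): on 50-country worlds the posterior median log-U5MR RMSE is ~0.03
and empirical 90%-interval coverage 0.89–0.94 across seeds with max split-
R-hat < 1.01; a source simulated at 0.8× truth receives a negative posterior
mean bias in 20/20 replicates; the cohort engine matches the daily
microsimulation within 0.07% and conserves cohorts to ~1e-16; scenario paths
hit 25.0/12.0/5.0 exactly at 2030, activate the 1.7/0.85 floors and the 0.79
cap, respect the scenario ordering, and round-trip the ARR to machine
precision; no NMR draw reaches its U5MR draw in 3.5 million checks.

## Known limitations

- Crisis and epidemic mortality adjustments are represented only as an
  optional rate-adjustment input to the ARR computation.
- The extra-variance term stands in for a full series-divergence covariate;
  series effects capture persistent level offsets but not time-varying
  divergence.
- Group rate aggregation is a births-weighted approximation, documented
  above, rather than an exact inversion of the cohort model.
- The 1–59-month hazard is constant within each calendar year; no within-
  range age curve is modelled.
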