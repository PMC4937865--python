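# Methods

## Study design and estimand

The package addresses a within-city question: do neighborhoods that run
hotter than the city average (positive UHI anomaly) suffer more on hot
days — and less on cold days — than their extra degrees would predict?
"Acclimatization" here is a difference in susceptibility *across areas*,
whatever its mechanism (building stock, behavior, physiology), not a
change over time.

All inference is built on a time-stratified case–crossover analysis of
daily death counts per UHI-anomaly decile group, with strata defined by
(calendar year, calendar month, group): each day is compared only with
the 27–30 other days of the same month, year and group, which removes
seasonal, long-term-trend and between-area confounding by design.

## UHI anomaly

`uhia_g = (1/n_g) Σ_j (T_gj − T_j)` with `T_j` the unweighted mean over
grids reporting on day j. One temperature statistic (daily mean by
default, configurable) is used for both terms; an excess of a grid's
daily maximum over a city daily mean would conflate the anomaly with
the diurnal range, so mixing statistics is deliberately not supported.
Decile groups are formed by rank: grids sorted by (anomaly, grid id),
split into ten equal blocks, remainders to the lower groups. The tie
break by grid id makes the assignment deterministic and independent of
input record order.

## Conditional Poisson engine

With stratum totals conditioned out, each stratum's likelihood is
multinomial over its days:

    l(β) = Σ_s [ Σ_i y_i x_i'β − Y_s log Σ_i exp(x_i'β) ].

This objective is exactly the stratum-fixed-effects Poisson
log-likelihood with the intercepts profiled out in closed form, so
point estimates coincide with the explicit fixed-effects fit (tested
against an independent GLM implementation to 1e-6). Newton–Raphson
with step halving; convergence when the relative log-likelihood change
is below 1e-10 (cap 100 iterations). Strata with zero deaths are
dropped (they contribute no information); columns constant within every
stratum, or collinear after within-stratum centering, are rejected by
name. The deviance is reported on the conditional scale against the
saturated multinomial fit; a Pearson dispersion factor is computed and
reported, but confidence intervals default to the Poisson scale (a
`quasi` flag rescales). Counts may be non-integer: expected counts
define a valid quasi-likelihood, which the exact-recovery tests use.

## Temperature bases

* Summer lag structure: unconstrained lags 0–1. Winter: natural cubic
  spline over lags 0–13 with two interior knots equally spaced on the
  log(lag+1) scale — the convention of the standard distributed-lag
  software; this placement is a documented assumption and is
  configurable.
* Rows whose lag window reaches before the start of the series are
  dropped from the likelihood rather than zero-padded. Lags are
  computed on the full calendar before any seasonal restriction, so
  September case days in the winter window draw on August temperatures.
* The natural cubic spline uses the compact truncated-power form with
  linear tails; a df-column basis places boundary knots at the data
  min/max and interior knots at equally spaced quantiles. It is
  oracle-tested against an independent truncated-power-plus-constraints
  construction.
* Hot/cold cut-point selection scans a candidate grid (defaults: 0.1 °C
  steps across the 90th–99th percentile for heat, 1st–25th for cold)
  and picks the candidate maximizing the Wald z of the cumulative
  dichotomy effect. The minimum-mortality temperature is the argmin of
  the cumulative all-year spline curve on a 0.1 °C grid; the all-year
  model uses the 0–13 spline lag structure (the natural choice for a
  curve dominated by cold effects; the summer window is unaffected).

## Method 1: observed vs expected IRR

The interaction model adds one column per cross-basis sub-term times
the continuous group anomaly. The cumulative log-IRR is the
lag-weighted sum of the interaction coefficients; RRs are reported at
anomalies ±0.5 °C and the IRR as their ratio per 1 °C, with the cold
contrast reported cooler-over-warmer. CIs are delta-method from the
joint covariance.

The expected IRR refits the model without interactions, replacing the
dichotomy with a segmented-linear temperature term. For heat the
expected IRR is the exponent of the cumulative slope above the top knot
(all segment coefficients active); for cold, per −1 °C below the bottom
knot (linear term only). Knots whose kink is not straddled by the
temperatures actually entering the seasonal design are dropped with a
warning — e.g. a 6.4 °C knot contributes nothing in a June–August
window and would otherwise make the design singular. The expected-IRR
CI does not account for cut-point selection uncertainty.

## Method 2: shifted spline

For each γ on the grid (default −0.5 … 1.5, step 0.1) the 4-df spline
cross-basis is evaluated at `t + γ·u_g` per group and the model refit
(warm-started from the previous grid point). Knots are frozen once from
the unshifted seasonal temperatures, so shape is fixed and only
location responds to γ. The MLE is the grid argmin refined by a
quadratic through the bracketing triple (both values are reported); the
95% profile CI is the deviance-within-3.841 region with
linearly-interpolated crossings, clipped and flagged at grid edges; the
LRTs at γ = 0 and γ = 1 use the chi-square(1) tail of the deviance gap
to the minimum. A flat profile (all anomalies equal) raises an
"unidentifiable" error; isolated fit failures are dropped with a
warning provided at least 80% of the grid succeeds.

## Synthetic data

The generator emulates the data structure the estimators need, at the
scale of a large-city mortality register: 14 years, 10 groups at the
published London decile-mean anomalies (−0.93 … 0.63 °C), baseline
16.5 deaths/group/day (~165/day citywide). Temperature is a seasonal
cosine (mean 11.5 °C, amplitude 7.5 °C, mid-July peak) plus AR(1) noise
(ρ = 0.75, innovation sd 2.5 °C), giving London-like summers in which
roughly a sixth of July days exceed the 22.3 °C heat cut-point.
Influenza is a winter-peaking seasonal Poisson series. The log death
rate adds day-of-week offsets, a linear influenza term, and
piecewise-linear heat (log 1.07 per °C above 22.3 °C) and cold
(log 1.03 per °C below 6.4 °C) effects of the *effective* temperature
`t + γ_true·u_g`, each averaged over its lag window (0–1 heat, 0–13
cold) so the cumulative log-RR per °C equals the configured slope —
the same cumulative convention the estimators report. A 3-year,
5-group "small" profile keeps unit tests fast.

What the generator does not emulate: overdispersion beyond Poisson,
harvesting/mortality displacement, spatial correlation between groups,
demographic structure, lag-shape mismatch between generation and
fitting, and measurement error in the anomaly map. Passing recovery
tests therefore demonstrate internal consistency of the estimators
under clean conditions, not robustness to those real-data features;
the deliberately matched lag windows keep γ-recovery well-posed.

## Numerical and design choices

* Deviance-grid γ estimation (not gradient-based): the profile is cheap
  (a few hundred Newton steps in total with warm starts) and the grid
  is what makes edge behavior and multimodality visible.
* Profile CI cutoff 3.841 (χ²₁ at 0.95) is an added convention; the
  underlying analysis plan reports only the endpoint LRTs.
* Quadratic MLE refinement can land between grid points; both the grid
  argmin and the refined value are exposed.
* Influenza enters linearly (the covariate list treats it as a linear
  term); the transform is configurable.
* The estimators are scikit-learn-style classes (`fit`, `get_params`,
  trailing-underscore fitted attributes) so they compose with generic
  tooling; module-level functions wrap them for one-call use.
* Replicate seeds in tests and the acceptance script derive from one
  master seed through a SeedSequence stream, folded below 2^31.

## Known limitations

* γ is weakly identified when anomalies are small relative to
  temperature noise — profiles can be nearly flat (the cold season is
  notorious for this: the cold slope is about a third of the heat
  slope on the log scale, so discrimination between γ = 0 and γ = 1
  needs far more data).
* The profile CI is asymptotic; at moderate sample sizes its coverage
  runs a shade below nominal (about 92–95% in the recovery
  simulations), consistent with the mild non-quadraticity of the
  profile near grid edges.
* The dichotomy cut-point and the MMT are treated as fixed when the
  IRR models are fit; selection uncertainty is not propagated.
* Age-stratified runs refit per band; no pooled heterogeneity statistic
  is computed.
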