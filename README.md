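# uhiacclim

Tools for estimating the degree of **acclimatization to the urban heat
island (UHI)** in heat- and cold-related mortality.

Built-up neighborhoods run warmer than their city's average (the UHI
effect). If their residents are *not* acclimatized, hot days should be
deadlier there in proportion to the extra degrees; if they are *fully*
acclimatized, mortality risk should track the shared city-wide
temperature series identically everywhere. `uhiacclim` quantifies where
a city sits on that continuum from small-area daily death counts, a
single city temperature series, and a map of local temperature
anomalies. It is aimed at environmental epidemiologists working with
time-stratified case–crossover designs.

## The model

Grids are scored by their **UHI anomaly**, the long-run mean daily
excess over the same-day city mean,
`UHIa_g = (1/n) Σ_j (T_gj − T_j)`, and classified into decile groups
(group 1 coolest … 10 hottest). Daily death counts `Y_ij` per group are
analysed as a case–crossover stratified by (year, month, group) via a
**conditional Poisson** model — the likelihood is conditioned on
stratum totals, eliminating all baseline rates — with day-of-week and
influenza covariates, and temperature entering through distributed-lag
bases (unconstrained lags 0–1 in summer; a natural-cubic-spline lag
curve over lags 0–13 in winter).

Two acclimatization estimators sit on top of this engine:

1. **Interaction rate ratio (IRR).** Hot (cold) days are defined by a
   cut-point chosen to maximize the Wald z of the excess risk
   (defaults 22.3 °C / 6.4 °C). The hot-day effect is interacted with
   the group anomaly; the IRR is the ratio of the cumulative relative
   risk at UHIa +0.5 °C to that at −0.5 °C (reversed for cold). It is
   compared with the **expected IRR under no acclimatization** — the
   city-wide per-°C slope of log risk beyond the cut-point from a
   segmented-linear model with knots at the minimum-mortality
   temperature (18.6 °C) and the cut-point.

2. **Shifted spline.** A fixed-shape 4-df natural cubic spline
   temperature–mortality function is evaluated at `t_j + γ·UHIa_i`
   and the displacement γ profiled over a deviance grid on
   [−0.5, 1.5]. γ = 1 means the group curves are separated by their
   true temperature differences (no acclimatization); γ = 0 means they
   coincide on the shared series (full acclimatization). The profile
   yields the MLE, a 95% profile CI (deviance within 3.84 of the
   minimum) and likelihood-ratio tests against γ = 0 and γ = 1.

Because no small-area mortality data can ship with the package, a
synthetic-data module generates the whole study design — seasonal AR(1)
temperature, winter-peaking influenza, and Poisson deaths for groups at
the published London decile anomalies — with a *known* γ, so every
estimator is testable by parameter recovery.

## Worked example

```python
import uhiacclim as ua

ds = ua.simulate(ua.SimulationConfig.london(gamma_true=1.0, seed=42))

m = ua.IRRModel(side="heat").fit(ds.city, ds.deaths, ds.uhia_by_group)
print(m.result_.as_frame())

s = ua.ShiftedSplineModel(side="heat").fit(ds.city, ds.deaths, ds.uhia_by_group)
p = s.profile_
print(p.gamma_mle, p.ci, p.p_gamma0, p.p_gamma1)
```

Output (14 simulated years, 10 groups, no acclimatization):

```
exposure uhia       rr    rr_lo    rr_hi      irr   irr_lo   irr_hi  expected_irr ...
    heat -0.5 1.144948 1.120356 1.170080 1.000000      NaN      NaN      1.000000
    heat +0.5 1.215583 1.189987 1.241729 1.061692 1.028163 1.096315      1.068104

gamma grid argmin 1.1, refined MLE 1.064
95% profile CI (0.52, 1.50)
LRT p at gamma=0: 0.0001, at gamma=1: 0.8207
```

Read: hot days carry ~21% excess mortality in the warmer areas versus
~14% in the cooler ones; the observed IRR (1.062 per °C of anomaly)
matches the expected IRR under no acclimatization (1.068), and the
shifted-spline profile puts γ̂ ≈ 1.06 with γ = 0 firmly rejected
(p = 0.0001) and γ = 1 not (p = 0.82) — the estimators correctly
recover the generative regime of no acclimatization.

The same analyses run from the shell on delimited-text inputs:

```sh
uhiacclim simulate --profile london --gamma 1.0 --seed 42 --out run/
uhiacclim fit-irr   --city-series run/city_series.csv --deaths run/deaths.csv \
                    --groups run/groups.csv --side heat --out run/irr.csv
uhiacclim fit-shift --city-series run/city_series.csv --deaths run/deaths.csv \
                    --groups run/groups.csv --side heat --out run/profile.csv
```

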