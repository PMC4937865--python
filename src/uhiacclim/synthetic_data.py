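"""Synthetic city-scale mortality and temperature series with a known
acclimatization parameter.

The generator emulates the structure the estimators are built for: one
city temperature series, daily influenza counts, and Poisson death
counts in a set of small-area groups whose local climate differs from
the city series by a fixed anomaly.  The displacement parameter
``gamma_true`` controls how much of each group's anomaly is *felt*:
group g experiences effective temperature t + gamma_true * UHIa_g, so
gamma_true = 1 means no acclimatization (risk follows local
temperature) and gamma_true = 0 full acclimatization (every group
shares the city-wide risk function).

The log death rate is

    log mu_gj = log(baseline_g) + dow(j) + flu_coef * flu_j
              + heat_slope * mean_{k in heat window} (t*_{g,j-k} - heat_knot)+
              + cold_slope * mean_{k in cold window} (cold_knot - t*_{g,j-k})+

so the *cumulative* (summed over lags) log rate ratio per degC beyond a
knot equals the configured slope — the same cumulative-effect
convention the estimators report.  Lag windows match the estimation
defaults (0-1 heat, 0-13 cold, uniform weights).

The default ("London-scale") scenario: 14 years, 10 groups with
anomalies set to the observed London decile means, ~165 deaths/day in
total, heat slope log(1.07) above 22.3 degC and cold slope log(1.03)
below 6.4 degC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate",
           "simulate_temperature", "simulate_flu", "simulate_deaths",
           "replicate_seeds", "LONDON_DECILE_UHIA"]


def replicate_seeds(master_seed, n):
    """Independent per-replicate seeds derived from one master seed
    (SeedSequence stream, folded below 2**31)."""
    return [int(s) % 2**31 for s in
            np.random.SeedSequence(master_seed).generate_state(n, np.uint64)]

# observed per-decile mean anomalies for London (degC), coolest to hottest
LONDON_DECILE_UHIA = (-0.93, -0.51, -0.26, -0.11, 0.01, 0.12, 0.23, 0.34, 0.47, 0.63)


@dataclass(frozen=True)
class SimulationConfig:
    n_years: int = 14
    start_year: int = 1993
    # (group id, anomaly degC, baseline deaths/day)
    groups: tuple = tuple((i + 1, u, 16.5) for i, u in enumerate(LONDON_DECILE_UHIA))
    gamma_true: float = 1.0
    temp_mean: float = 11.5
    temp_amplitude: float = 7.5
    temp_peak_doy: int = 197  # mid-July
    temp_ar_rho: float = 0.75
    temp_sd: float = 2.5  # AR(1) innovation sd, degC
    heat_slope: float = math.log(1.07)  # log-RR per degC above heat_knot
    cold_slope: float = math.log(1.03)  # log-RR per degC below cold_knot
    heat_knot: float = 22.3
    cold_knot: float = 6.4
    mmt: float = 18.6
    heat_lag: tuple = (0, 1)
    cold_lag: tuple = (0, 13)
    # Monday..Sunday log-rate offsets
    dow_effects: tuple = (0.0, -0.005, -0.01, -0.005, 0.0, 0.015, 0.02)
    flu_base: float = 5.0
    flu_amplitude: float = 2.0  # log scale; winter peak
    flu_peak_doy: int = 20
    flu_coef: float = 0.002  # log-RR per influenza count
    seed: int = 0

    def __post_init__(self):
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if any(b <= 0 for _, _, b in self.groups):
            raise ValueError("baseline death rates must be positive")
        if not (self.heat_knot > self.mmt > self.cold_knot):
            raise ValueError("need heat_knot > mmt > cold_knot")
        if not (0 <= self.temp_ar_rho < 1):
            raise ValueError("temp_ar_rho must be in [0, 1)")
        if not (-0.5 <= self.gamma_true <= 1.5):
            raise ValueError("gamma_true outside the supported range [-0.5, 1.5]")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must give 7 log-rates")

    @classmethod
    def london(cls, **overrides):
        """Full-scale default scenario."""
        return cls(**overrides)

    @classmethod
    def small(cls, **overrides):
        """Fast 3-year, 5-group profile for tests."""
        groups = tuple((i + 1, u, 30.0) for i, u in
                       enumerate((-0.9, -0.4, 0.0, 0.3, 0.6)))
        kw = dict(n_years=3, groups=groups)
        kw.update(overrides)
        return cls(**kw)

    @property
    def uhia_by_group(self):
        return {g: u for g, u, _ in self.groups}

    def dates(self):
        start = pd.Timestamp(year=self.start_year, month=1, day=1)
        end = pd.Timestamp(year=self.start_year + self.n_years - 1, month=12, day=31)
        return pd.date_range(start, end, freq="D")


@dataclass
class SimulatedDataset:
    """City series, per-group daily deaths, and the generating truth."""

    city: pd.DataFrame  # indexed by date: temp, flu
    deaths: pd.DataFrame  # date, group, deaths
    groups: pd.DataFrame  # group, uhia, baseline
    config: SimulationConfig

    @property
    def uhia_by_group(self):
        return dict(zip(self.groups["group"], self.groups["uhia"]))

    @property
    def truth(self):
        c = self.config
        return {"gamma": c.gamma_true, "heat_slope": c.heat_slope,
                "cold_slope": c.cold_slope, "heat_knot": c.heat_knot,
                "cold_knot": c.cold_knot, "mmt": c.mmt}


def simulate_temperature(config: SimulationConfig, rng=None) -> pd.Series:
    """Seasonal cosine plus AR(1) noise, seeded and reproducible."""
    rng = np.random.default_rng(config.seed if rng is None else rng)
    dates = config.dates()
    doy = dates.dayofyear.to_numpy()
    seasonal = config.temp_mean + config.temp_amplitude * np.cos(
        2 * np.pi * (doy - config.temp_peak_doy) / 365.25
    )
    n = len(dates)
    rho, sd = config.temp_ar_rho, config.temp_sd
    eps = rng.normal(0.0, sd, n)
    noise = np.empty(n)
    # stationary start
    noise[0] = eps[0] / np.sqrt(1 - rho**2) if sd > 0 else 0.0
    for j in range(1, n):
        noise[j] = rho * noise[j - 1] + eps[j]
    return pd.Series(seasonal + noise, index=dates, name="temp")


def simulate_flu(config: SimulationConfig, rng=None) -> pd.Series:
    """Winter-peaking seasonal Poisson influenza counts."""
    rng = np.random.default_rng(config.seed + 1 if rng is None else rng)
    dates = config.dates()
    doy = dates.dayofyear.to_numpy()
    lam = config.flu_base * np.exp(
        config.flu_amplitude * np.cos(2 * np.pi * (doy - config.flu_peak_doy) / 365.25)
    )
    return pd.Series(rng.poisson(lam).astype(float), index=dates, name="flu")


def _lag_window_mean(x, window):
    """Mean of x over lags L0..L1, truncating the window at the series
    start (those early days are dropped from any likelihood anyway)."""
    L0, L1 = window
    n = x.size
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for k in range(L0, L1 + 1):
        if k == 0:
            acc += x
            cnt += 1
        elif k < n:
            acc[k:] += x[:-k]
            cnt[k:] += 1
    return acc / np.maximum(cnt, 1)


def simulate_deaths(config: SimulationConfig, temps=None, flu=None,
                    noiseless=False) -> SimulatedDataset:
    """Draw per-group daily death counts under the configured truth.

    ``noiseless=True`` returns the exact expected counts (floats) in
    place of Poisson draws — useful for exact-recovery checks.
    """
    rng = np.random.default_rng(config.seed)
    if temps is None:
        temps = simulate_temperature(config, rng.integers(2**31))
    if flu is None:
        flu = simulate_flu(config, rng.integers(2**31))
    dates = config.dates()
    if not temps.index.equals(dates):
        raise ValueError("temperature series does not cover the configured calendar")
    t = temps.to_numpy(dtype=float)
    f = flu.to_numpy(dtype=float)
    dow = dates.dayofweek.to_numpy()
    dow_eff = np.asarray(config.dow_effects)[dow]

    frames = []
    for g, u, base in config.groups:
        tstar = t + config.gamma_true * u
        heat = config.heat_slope * _lag_window_mean(
            np.maximum(tstar - config.heat_knot, 0.0), config.heat_lag
        )
        cold = config.cold_slope * _lag_window_mean(
            np.maximum(config.cold_knot - tstar, 0.0), config.cold_lag
        )
        mu = base * np.exp(dow_eff + config.flu_coef * f + heat + cold)
        if mu.max() > 1e6:
            raise ValueError(
                f"death rate overflow (max mu = {mu.max():.3g}); check config scaling"
            )
        y = mu if noiseless else rng.poisson(mu).astype(float)
        frames.append(pd.DataFrame({"date": dates, "group": g, "deaths": y}))

    deaths = pd.concat(frames, ignore_index=True)
    city = pd.DataFrame({"temp": t, "flu": f},
                        index=pd.DatetimeIndex(dates, name="date"))
    groups = pd.DataFrame(
        {"group": [g for g, _, _ in config.groups],
         "uhia": [u for _, u, _ in config.groups],
         "baseline": [b for _, _, b in config.groups]}
    )
    return SimulatedDataset(city, deaths, groups, config)


def simulate(config: SimulationConfig, noiseless=False) -> SimulatedDataset:
    """Convenience wrapper: temperature + influenza + deaths."""
    return simulate_deaths(config, noiseless=noiseless)
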