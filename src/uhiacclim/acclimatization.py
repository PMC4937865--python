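"""Two estimators of acclimatization to the urban heat island.

Method 1 (interaction rate ratio).  The hot-day (cold-day) excess risk
is allowed to vary linearly with the group anomaly by adding one
interaction column per cross-basis sub-term (sub-term x UHIa).  The
IRR is the ratio of the cumulative relative risk at UHIa +0.5 degC to
that at -0.5 degC (reversed for cold, so the cooler area is the
numerator), i.e. the multiplicative change in excess risk per degC of
anomaly.  It is compared with the *expected* IRR under no
acclimatization: the city-wide per-degC slope of risk beyond the
cut-point, from a segmented-linear temperature model.

Method 2 (shifted spline).  A fixed-shape 4-df natural cubic spline
temperature-mortality function is evaluated at t + gamma * UHIa_g and
the displacement gamma profiled over a deviance grid.  gamma = 1 means
the group curves are separated by their actual temperature differences
(no acclimatization); gamma = 0 means they coincide on the shared city
series (full acclimatization).  The profile gives the MLE, a 95%
profile confidence interval (deviance within 3.841 of the minimum),
and likelihood-ratio tests against gamma = 0 and gamma = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .basis import (
    SUMMER_LAG,
    WINTER_LAG,
    DichotomyVarSpec,
    LinearSplineVarSpec,
    NSVarSpec,
    crossbasis,
    ncs_knots,
    shifted_crossbasis,
)
from .casecrossover import (
    ConditionalPoissonRegression,
    build_strata,
    covariate_matrix,
    design_rows,
)

__all__ = [
    "IRRResult",
    "GammaProfile",
    "IRRModel",
    "ShiftedSplineModel",
    "estimate_irr",
    "expected_irr",
    "profile_gamma",
    "adjust_variants",
    "DEFAULT_CUTPOINTS",
    "DEFAULT_MMT",
    "CHI2_95",
]

DEFAULT_CUTPOINTS = {"heat": 22.3, "cold": 6.4}
DEFAULT_MMT = 18.6
DEFAULT_SEASON = {"heat": "summer", "cold": "winter"}
DEFAULT_LAG = {"heat": SUMMER_LAG, "cold": WINTER_LAG}
CHI2_95 = float(stats.chi2.ppf(0.95, 1))  # 3.841...


def _ci(log_point, se):
    z = stats.norm.ppf(0.975)
    return (np.exp(log_point - z * se), np.exp(log_point + z * se))


@dataclass
class IRRResult:
    """Observed (and optionally expected) interaction rate ratio."""

    side: str
    rr_minus: float
    rr_minus_ci: tuple
    rr_plus: float
    rr_plus_ci: tuple
    irr: float
    irr_ci: tuple
    expected_irr: float = None
    expected_irr_ci: tuple = None

    def as_frame(self):
        """Summary table: RR rows at UHIa -/+0.5 plus the IRR row,
        ordered with the reference anomaly first (as is conventional
        for the cold contrast, the cooler area is the comparison)."""
        first, second = ("-0.5", "+0.5") if self.side == "heat" else ("+0.5", "-0.5")
        rr1, ci1 = ((self.rr_minus, self.rr_minus_ci) if self.side == "heat"
                    else (self.rr_plus, self.rr_plus_ci))
        rr2, ci2 = ((self.rr_plus, self.rr_plus_ci) if self.side == "heat"
                    else (self.rr_minus, self.rr_minus_ci))
        rows = [
            {"exposure": self.side, "uhia": first, "rr": rr1,
             "rr_lo": ci1[0], "rr_hi": ci1[1], "irr": 1.0,
             "irr_lo": np.nan, "irr_hi": np.nan,
             "expected_irr": 1.0, "expected_lo": np.nan, "expected_hi": np.nan},
            {"exposure": self.side, "uhia": second, "rr": rr2,
             "rr_lo": ci2[0], "rr_hi": ci2[1], "irr": self.irr,
             "irr_lo": self.irr_ci[0], "irr_hi": self.irr_ci[1],
             "expected_irr": self.expected_irr,
             "expected_lo": (self.expected_irr_ci or (np.nan, np.nan))[0],
             "expected_hi": (self.expected_irr_ci or (np.nan, np.nan))[1]},
        ]
        return pd.DataFrame(rows)


@dataclass
class GammaProfile:
    """Deviance profile of the displacement parameter."""

    gammas: np.ndarray
    deviances: np.ndarray
    gamma_grid_argmin: float
    gamma_mle: float  # quadratic-interpolation refinement
    deviance_min: float
    ci: tuple  # 95% profile interval (clipped to the grid)
    ci_open: tuple  # flags: bound sits on the grid edge
    p_gamma0: float
    p_gamma1: float
    n_failed: int = 0

    def as_frame(self):
        rel = self.deviances - self.deviance_min
        return pd.DataFrame({"gamma": self.gammas, "deviance": self.deviances,
                             "delta_deviance": rel})

    def contains(self, value):
        lo, hi = self.ci
        return lo <= value <= hi


# ---------------------------------------------------------------------------
# Method 1


class IRRModel:
    """Observed-vs-expected interaction rate ratio estimator.

    Parameters
    ----------
    side : "heat" or "cold".
    cutpoint : hot/cold day threshold (degC); defaults to the London
        values 22.3 / 6.4.
    season : stratification window; defaults to summer for heat,
        winter (Sep-May) for cold.
    lagspec : distributed-lag structure; defaults to unconstrained 0-1
        (heat) or spline 0-13 (cold).
    knots : linear-spline knots for the expected IRR; defaults to
        (MMT, cutpoint) for heat and (cutpoint, MMT) for cold.  Knots
        with no kink inside the season's observed temperatures are
        dropped automatically.
    pollution : add linear O3 and PM10 terms.
    deprivation : optional {group: score}; adds a second interaction
        block (sub-term x deprivation score).
    with_expected : also fit the no-interaction segmented model.

    After ``fit(city, deaths, uhia_by_group)``: ``result_`` is an
    :class:`IRRResult`; ``fit_`` and ``expected_fit_`` hold the
    underlying conditional-Poisson fits.
    """

    def __init__(self, side="heat", cutpoint=None, season=None, lagspec=None,
                 knots=None, mmt=DEFAULT_MMT, pollution=False, deprivation=None,
                 with_expected=True):
        self.side = side
        self.cutpoint = cutpoint
        self.season = season
        self.lagspec = lagspec
        self.knots = knots
        self.mmt = mmt
        self.pollution = pollution
        self.deprivation = deprivation
        self.with_expected = with_expected

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("side", "cutpoint", "season", "lagspec", "knots", "mmt",
                 "pollution", "deprivation", "with_expected")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _resolved(self):
        side = self.side
        if side not in ("heat", "cold"):
            raise ValueError("side must be 'heat' or 'cold'")
        cut = DEFAULT_CUTPOINTS[side] if self.cutpoint is None else self.cutpoint
        season = DEFAULT_SEASON[side] if self.season is None else self.season
        lag = DEFAULT_LAG[side] if self.lagspec is None else self.lagspec
        if self.knots is None:
            knots = (self.mmt, cut) if side == "heat" else (cut, self.mmt)
        else:
            knots = tuple(sorted(self.knots))
        return side, cut, season, lag, knots

    def fit(self, city, deaths, uhia_by_group, age_band=None):
        side, cut, season, lag, knots = self._resolved()
        table = build_strata(deaths, city, season, age_band=age_band)
        temps = city["temp"].to_numpy()

        cb = crossbasis(temps, DichotomyVarSpec(cut, "hot" if side == "heat" else "cold"), lag)
        complete, block = design_rows(table, cb=cb)
        sub = table[complete]
        main = block[complete]
        if not np.any(main[:, 0] != 0):
            raise ValueError(f"no {side} exceedance days beyond cut-point {cut}")
        u = sub["group"].map(uhia_by_group).to_numpy(dtype=float)
        inter = main * u[:, None]
        blocks = [main, inter]
        names = list(cb.colnames) + [f"{c}:uhia" for c in cb.colnames]
        if self.deprivation is not None:
            d = sub["group"].map(self.deprivation).to_numpy(dtype=float)
            if np.ptp(d) == 0:
                raise ValueError(
                    "deprivation score is constant across groups; the "
                    "deprivation interaction columns are inestimable"
                )
            blocks.append(main * d[:, None])
            names += [f"{c}:depriv" for c in cb.colnames]
        cov, covnames = covariate_matrix(sub, pollution=self.pollution)
        blocks.append(cov)
        names += covnames

        est = ConditionalPoissonRegression()
        est.fit(pd.DataFrame(np.column_stack(blocks), columns=names),
                sub["deaths"].to_numpy(), sub["stratum"].to_numpy())
        self.fit_ = est.result_

        k = cb.ncol
        w = cb.cumulative_weights()
        beta, theta = est.coef_[:k], est.coef_[k:2 * k]
        cov_bt = est.cov_[: 2 * k, : 2 * k]

        def rr_at(uval):
            wv = np.concatenate([w, uval * w])
            lp = float(wv @ np.concatenate([beta, theta]))
            se = float(np.sqrt(wv @ cov_bt @ wv))
            return np.exp(lp), _ci(lp, se)

        rr_m, ci_m = rr_at(-0.5)
        rr_p, ci_p = rr_at(+0.5)
        sign = 1.0 if side == "heat" else -1.0
        log_irr = sign * float(w @ theta)
        se_irr = float(np.sqrt(w @ est.cov_[k:2 * k, k:2 * k] @ w))
        self.result_ = IRRResult(side, rr_m, ci_m, rr_p, ci_p,
                                 float(np.exp(log_irr)), _ci(log_irr, se_irr))

        if self.with_expected:
            exp_irr, exp_ci, exp_fit = _expected_irr_fit(
                table, city, side, knots, lag, pollution=self.pollution
            )
            self.expected_fit_ = exp_fit
            self.result_.expected_irr = exp_irr
            self.result_.expected_irr_ci = exp_ci
        return self


def _expected_irr_fit(table, city, side, knots, lag, pollution=False):
    """No-interaction segmented-linear temperature model; the expected
    IRR is the cumulative slope beyond the outermost knot (per +1 degC
    above the top knot for heat, per -1 degC below the bottom knot for
    cold)."""
    temps = city["temp"].to_numpy()
    # a knot only contributes a kink if the temperatures actually entering
    # the seasonal design (case days and their lags) straddle it
    days = np.unique(table["day_index"].to_numpy())
    lagged = np.unique(np.concatenate(
        [np.clip(days - k, 0, None) for k in range(lag.lag[0], lag.lag[1] + 1)]
    ))
    used = temps[lagged]
    keep = [k for k in knots if used.min() < k < used.max()]
    dropped = [k for k in knots if k not in keep]
    if dropped:
        warnings.warn(
            f"linear-spline knot(s) {dropped} have no kink in the observed "
            "temperatures and were dropped", stacklevel=2
        )
    vs = LinearSplineVarSpec(tuple(keep))
    cb = crossbasis(temps, vs, lag)
    complete, block = design_rows(table, cb=cb)
    sub = table[complete]
    if side == "heat":
        top = max(keep) if keep else -np.inf
        if not np.any(temps > top):
            raise ValueError(f"no days above the top knot {top}")
    else:
        bot = min(keep) if keep else np.inf
        if not np.any(temps < bot):
            raise ValueError(f"no days below the bottom knot {bot}")
    cov, covnames = covariate_matrix(sub, pollution=pollution)
    est = ConditionalPoissonRegression()
    est.fit(pd.DataFrame(np.column_stack([block[complete], cov]),
                         columns=list(cb.colnames) + covnames),
            sub["deaths"].to_numpy(), sub["stratum"].to_numpy())
    # derivative of the segmented curve beyond the outer knot:
    # above the top knot every segment slope is active; below the
    # bottom knot only the plain linear term is.
    pv, pl = vs.ncol, cb.ncol // vs.ncol
    deriv = np.ones(pv) if side == "heat" else np.r_[1.0, np.zeros(pv - 1)]
    w = np.outer(deriv, cb.lag_weights).ravel()
    sign = 1.0 if side == "heat" else -1.0
    slope = sign * float(w @ est.coef_[: cb.ncol])
    se = float(np.sqrt(w @ est.cov_[: cb.ncol, : cb.ncol] @ w))
    return float(np.exp(slope)), _ci(slope, se), est.result_


# ---------------------------------------------------------------------------
# Method 2


class ShiftedSplineModel:
    """Profile-likelihood estimator of the displacement parameter gamma.

    For each gamma on the grid, a fixed-knot 4-df natural cubic spline
    cross-basis is evaluated at t + gamma * UHIa_g per group and the
    case-crossover model refitted; the deviance curve over gamma yields
    the MLE (grid argmin refined by quadratic interpolation of the
    bracketing points), the 95% profile CI, and LRTs at gamma = 0 and 1.

    Knots are placed once on the unshifted seasonal temperatures
    (boundary at min/max, interior at equally spaced quantiles), so the
    spline's shape is identical for every group and every gamma.
    """

    def __init__(self, side="heat", season=None, lagspec=None, df=4,
                 gamma_grid=None, pollution=False):
        self.side = side
        self.season = season
        self.lagspec = lagspec
        self.df = df
        self.gamma_grid = gamma_grid
        self.pollution = pollution

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("side", "season", "lagspec", "df", "gamma_grid", "pollution")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, city, deaths, uhia_by_group, age_band=None):
        side = self.side
        season = DEFAULT_SEASON[side] if self.season is None else self.season
        lag = DEFAULT_LAG[side] if self.lagspec is None else self.lagspec
        grid = (np.round(np.arange(-0.5, 1.5 + 1e-9, 0.1), 10)
                if self.gamma_grid is None else np.asarray(self.gamma_grid, float))
        if grid.size < 2:
            raise ValueError("gamma grid needs at least 2 points")

        anomalies = np.asarray(list(uhia_by_group.values()), float)
        if np.allclose(anomalies, anomalies[0], atol=1e-12):
            raise ValueError(
                "gamma unidentifiable: all group anomalies are equal, so the "
                "shift has no between-group contrast"
            )

        table = build_strata(deaths, city, season, age_band=age_band)
        temps = city["temp"].to_numpy()
        # knots frozen from the unshifted values that enter the seasonal fit
        season_vals = temps[np.unique(table["day_index"].to_numpy())]
        knots = ncs_knots(season_vals, self.df)
        varspec = NSVarSpec(tuple(knots))
        self.knots_ = knots

        cov, covnames = None, None
        devs = np.full(grid.size, np.nan)
        start = None
        idx = table["day_index"].to_numpy()
        grp = table["group"].to_numpy()
        failures = 0
        for i, g in enumerate(grid):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cbs = shifted_crossbasis(temps, g, uhia_by_group, varspec, lag)
            complete, block = design_rows(table, cb_by_group=cbs)
            sub = table[complete]
            if cov is None:
                cov, covnames = covariate_matrix(sub, pollution=self.pollution)
                y = sub["deaths"].to_numpy()
                strat = sub["stratum"].to_numpy()
                any_cb = next(iter(cbs.values()))
                names = list(any_cb.colnames) + covnames
            X = np.column_stack([block[complete], cov])
            est = ConditionalPoissonRegression()
            try:
                est.fit(pd.DataFrame(X, columns=names), y, strat, start=start)
            except (RuntimeError, ValueError) as err:
                failures += 1
                warnings.warn(f"fit failed at gamma={g:g}: {err}", stacklevel=2)
                continue
            devs[i] = est.deviance_
            start = est.coef_
        if failures > 0.2 * grid.size:
            raise RuntimeError(
                f"profile failed at {failures}/{grid.size} grid points"
            )

        ok = np.isfinite(devs)
        self.profile_ = _summarize_profile(grid[ok], devs[ok], failures)
        return self


def _summarize_profile(gammas, devs, n_failed=0):
    if np.ptp(devs) < 1e-9:
        raise ValueError("gamma unidentifiable: deviance profile is flat")
    i = int(np.argmin(devs))
    g_grid = float(gammas[i])
    if 0 < i < gammas.size - 1:
        # quadratic through the bracketing triple
        x0, x1, x2 = gammas[i - 1: i + 2]
        y0, y1, y2 = devs[i - 1: i + 2]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
        if a > 0:
            g_mle = float(-b / (2 * a))
            c = y1 - a * x1**2 - b * x1
            d_min = float(a * g_mle**2 + b * g_mle + c)
        else:
            g_mle, d_min = g_grid, float(devs[i])
    else:
        g_mle, d_min = g_grid, float(devs[i])

    rel = devs - d_min
    inside = rel <= CHI2_95
    lo, hi = gammas[0], gammas[-1]
    lo_open = hi_open = True
    idx_in = np.flatnonzero(inside)
    if idx_in.size:
        j0, j1 = idx_in[0], idx_in[-1]
        if j0 > 0:
            # linear interpolation of the crossing
            x0, x1 = gammas[j0 - 1], gammas[j0]
            r0, r1 = rel[j0 - 1], rel[j0]
            lo = float(x0 + (CHI2_95 - r0) * (x1 - x0) / (r1 - r0))
            lo_open = False
        if j1 < gammas.size - 1:
            x0, x1 = gammas[j1], gammas[j1 + 1]
            r0, r1 = rel[j1], rel[j1 + 1]
            hi = float(x0 + (CHI2_95 - r0) * (x1 - x0) / (r1 - r0))
            hi_open = False

    def p_at(value):
        k = np.argmin(np.abs(gammas - value))
        if abs(gammas[k] - value) > 1e-6:
            return np.nan
        return float(stats.chi2.sf(max(devs[k] - d_min, 0.0), 1))

    return GammaProfile(gammas, devs, g_grid, g_mle, d_min, (float(lo), float(hi)),
                        (lo_open, hi_open), p_at(0.0), p_at(1.0), n_failed)


# ---------------------------------------------------------------------------
# functional wrappers (the module-level interface)


def estimate_irr(city, deaths, uhia_by_group, side="heat", cutpoint=None,
                 season=None, lagspec=None, **kw):
    """Observed IRR (Method 1); see :class:`IRRModel`."""
    m = IRRModel(side=side, cutpoint=cutpoint, season=season, lagspec=lagspec,
                 with_expected=False, **kw)
    return m.fit(city, deaths, uhia_by_group).result_


def expected_irr(city, deaths, side="heat", knots=None, season=None,
                 lagspec=None, pollution=False):
    """Expected IRR under no acclimatization: cumulative slope of a
    segmented-linear temperature model beyond the outer knot."""
    side_, cut = side, DEFAULT_CUTPOINTS[side]
    if knots is None:
        knots = (DEFAULT_MMT, cut) if side == "heat" else (cut, DEFAULT_MMT)
    season = DEFAULT_SEASON[side] if season is None else season
    lag = DEFAULT_LAG[side] if lagspec is None else lagspec
    table = build_strata(deaths, city, season)
    value, ci, fit = _expected_irr_fit(table, city, side, tuple(knots), lag,
                                       pollution=pollution)
    return value, ci, fit


def profile_gamma(city, deaths, uhia_by_group, side="heat", gamma_grid=None,
                  **kw):
    """Shifted-spline profile of gamma (Method 2); see
    :class:`ShiftedSplineModel`."""
    m = ShiftedSplineModel(side=side, gamma_grid=gamma_grid, **kw)
    return m.fit(city, deaths, uhia_by_group).profile_


def adjust_variants(city, deaths, uhia_by_group, variant, side="heat",
                    deprivation=None, age_bands=None, method="irr"):
    """Bias-control variants of the main analyses.

    variant: "deprivation-interaction" (second modifier block),
    "pollution-linear" (O3 + PM10 linear terms),
    "age-stratified" (refit per age band),
    "season-sensitivity" (Oct-Apr winter window).
    """
    if variant == "deprivation-interaction":
        if deprivation is None:
            raise ValueError("deprivation scores required")
        return IRRModel(side=side, deprivation=deprivation).fit(
            city, deaths, uhia_by_group).result_
    if variant == "pollution-linear":
        if method == "irr":
            return IRRModel(side=side, pollution=True).fit(
                city, deaths, uhia_by_group).result_
        return ShiftedSplineModel(side=side, pollution=True).fit(
            city, deaths, uhia_by_group).profile_
    if variant == "age-stratified":
        bands = age_bands or sorted(deaths["age_band"].unique())
        out = {}
        for b in bands:
            if method == "irr":
                out[b] = IRRModel(side=side).fit(
                    city, deaths, uhia_by_group, age_band=b).result_
            else:
                out[b] = ShiftedSplineModel(side=side).fit(
                    city, deaths, uhia_by_group, age_band=b).profile_
        return out
    if variant == "season-sensitivity":
        if method == "irr":
            return IRRModel(side="cold", season="oct-apr").fit(
                city, deaths, uhia_by_group).result_
        return ShiftedSplineModel(side="cold", season="oct-apr").fit(
            city, deaths, uhia_by_group).profile_
    raise ValueError(f"unknown variant {variant!r}")
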