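"""Temperature and lag design-matrix construction.

Everything the mortality models need on the design side lives here:
indicator ("hot day" / "cold day") transforms, natural cubic splines,
segmented linear splines, and the distributed-lag cross-basis that
spreads any of these transforms over a window of lags.  The cross-basis
follows the usual DLNM construction: the design block is the tensor
product of a basis in the exposure dimension and a basis in the lag
dimension, and the cumulative log-rate-ratio of a sustained exposure is
the coefficient vector dotted with (exposure basis) x (lag-basis column
sums).

The natural cubic spline uses the compact truncated-power
representation (linear tails beyond the boundary knots).  It is built
here rather than taken from a formula interface because the shifted
spline estimator must evaluate one *fixed-knot* basis at displaced
temperatures t + gamma * UHIa for every candidate gamma; the knots are
frozen from the unshifted series so only the location of the curve, not
its shape, responds to gamma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LagSpec",
    "CrossBasis",
    "CutpointResult",
    "NSVarSpec",
    "LinearSplineVarSpec",
    "DichotomyVarSpec",
    "natural_spline",
    "ncs_knots",
    "crossbasis",
    "dichotomy_basis",
    "ncs_basis",
    "linear_spline_basis",
    "shifted_crossbasis",
    "select_cutpoint",
    "find_mmt",
]


# ---------------------------------------------------------------------------
# scalar-variable bases


def natural_spline(x, knots, intercept=False):
    """Natural cubic spline basis at ``x`` for the given knot vector.

    ``knots`` must be sorted and include the boundary knots as first and
    last elements.  With K knots the basis spans K functions including
    the constant; ``intercept=False`` drops the constant, giving K - 1
    columns.  The function is linear beyond the boundary knots (second
    and third derivatives vanish there), the defining property of a
    natural spline.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or knots.size < 3:
        raise ValueError("need at least 3 knots (2 boundary + 1 interior)")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    K = knots.size
    xmax = knots[-1]

    def d(k):
        # truncated-cubic difference ratio; linear-tail constraint built in
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - xmax, 0.0) ** 3
        return num / (xmax - knots[k])

    dlast = d(K - 2)
    cols = [np.ones_like(x), x] + [d(k) - dlast for k in range(K - 2)]
    B = np.column_stack(cols)
    return B if intercept else B[:, 1:]


def ncs_knots(values, df=4):
    """Knot vector for a ``df``-column natural spline: boundary knots at
    the min/max of ``values``, interior knots at equally spaced
    quantiles."""
    values = np.asarray(values, dtype=float)
    if df < 2:
        raise ValueError("df must be >= 2")
    n_interior = df - 1
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(values, qs)
    knots = np.concatenate([[values.min()], interior, [values.max()]])
    if np.unique(knots).size != knots.size:
        raise ValueError(
            f"df={df} exceeds the resolution of the data: duplicate knots {knots}"
        )
    return knots


def hinge(x, k):
    return np.maximum(np.asarray(x, dtype=float) - k, 0.0)


# variable-transform specs: each knows how to evaluate its design at
# arbitrary temperatures, so a cross-basis can be re-evaluated at
# shifted or counterfactual values.


@dataclass(frozen=True)
class NSVarSpec:
    """Natural cubic spline in temperature with frozen knots."""

    knots: tuple

    def design(self, x):
        return natural_spline(x, np.asarray(self.knots))

    @property
    def ncol(self):
        return len(self.knots) - 1

    def labels(self):
        return [f"ns{v}" for v in range(self.ncol)]


@dataclass(frozen=True)
class LinearSplineVarSpec:
    """Linear term plus one hinge (x - k)+ per knot."""

    knots: tuple

    def design(self, x):
        x = np.asarray(x, dtype=float)
        return np.column_stack([x] + [hinge(x, k) for k in self.knots])

    @property
    def ncol(self):
        return 1 + len(self.knots)

    def labels(self):
        return ["lin"] + [f"hinge{k:g}" for k in self.knots]


@dataclass(frozen=True)
class DichotomyVarSpec:
    """Hot-day or cold-day indicator."""

    cutpoint: float
    side: str  # "hot" | "cold"

    def __post_init__(self):
        if self.side not in ("hot", "cold"):
            raise ValueError(f"dichotomy side must be 'hot' or 'cold', got {self.side!r}")

    def design(self, x):
        x = np.asarray(x, dtype=float)
        ind = (x > self.cutpoint) if self.side == "hot" else (x < self.cutpoint)
        return ind.astype(float)[:, None]

    @property
    def ncol(self):
        return 1

    def labels(self):
        return [self.side]


# ---------------------------------------------------------------------------
# lag structures


@dataclass(frozen=True)
class LagSpec:
    """Lag window and the basis spread across it.

    ``kind="unconstrained"`` gives one free coefficient per lag (the
    summer default over lags 0-1); ``kind="ns"`` constrains the lag
    curve to a natural cubic spline with ``n_knots`` interior knots
    placed equally spaced on the log(lag + 1) scale (the winter default
    over lags 0-13 with 2 knots).  The spline lag basis includes the
    constant column, matching the usual distributed-lag convention.
    """

    kind: str = "unconstrained"
    lag: tuple = (0, 1)
    n_knots: int = 2

    def __post_init__(self):
        if self.kind not in ("unconstrained", "ns"):
            raise ValueError(f"unknown lag basis kind {self.kind!r}")
        if self.lag[0] > self.lag[1]:
            raise ValueError("lag window must have L0 <= L1")

    @property
    def lags(self):
        return np.arange(self.lag[0], self.lag[1] + 1)

    def basis(self):
        """Lag-basis matrix, one row per lag in the window."""
        lags = self.lags.astype(float)
        if self.kind == "unconstrained":
            return np.eye(lags.size)
        if lags.size < self.n_knots + 2:
            raise ValueError("lag window too short for the requested spline")
        logk = np.linspace(
            np.log(lags[0] + 1.0), np.log(lags[-1] + 1.0), self.n_knots + 2
        )
        knots = np.exp(logk) - 1.0
        return natural_spline(lags, knots, intercept=True)

    def labels(self):
        if self.kind == "unconstrained":
            return [f"lag{k}" for k in self.lags]
        return [f"lagns{j}" for j in range(self.basis().shape[1])]


SUMMER_LAG = LagSpec("unconstrained", (0, 1))
WINTER_LAG = LagSpec("ns", (0, 13), 2)


# ---------------------------------------------------------------------------
# cross-basis


@dataclass
class CrossBasis:
    """Exposure transform distributed over lags, as a design block.

    ``values[t, (v, l)] = sum_k V[t - k, v] * C[k - L0, l]`` where V is
    the variable basis evaluated on the daily series and C the lag
    basis.  Rows whose lag window reaches before the start of the
    series are marked incomplete and must not enter a likelihood.
    """

    values: np.ndarray
    colnames: list
    varspec: object
    lagspec: LagSpec
    complete: np.ndarray = field(repr=False)
    lag_weights: np.ndarray = field(repr=False)  # column sums of the lag basis

    @property
    def ncol(self):
        return self.values.shape[1]

    def cumulative_weights(self, at=None):
        """Weight vector w such that w . beta is the cumulative
        (summed over lags) log rate ratio.

        ``at`` evaluates the variable basis at a specific exposure
        value; ``at=None`` uses a unit variable basis in every column,
        which is the correct contrast for a dichotomy (indicator = 1)
        and the per-column cumulative sums otherwise.
        """
        pv = self.varspec.ncol
        if at is None:
            vrow = np.ones(pv)
        else:
            vrow = np.asarray(self.varspec.design([at]))[0]
        return np.outer(vrow, self.lag_weights).ravel()

    def cumulative_curve(self, xs):
        """Matrix mapping coefficients to the cumulative curve at ``xs``."""
        V = self.varspec.design(xs)
        return np.einsum("iv,l->ivl", V, self.lag_weights).reshape(len(V), -1)


def crossbasis(series, varspec, lagspec):
    """Build the cross-basis of ``varspec`` over ``lagspec`` on a daily
    series (ordered, consecutive days)."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("series must be a non-empty 1-d array")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite temperatures")
    V = varspec.design(x)
    C = lagspec.basis()
    L0, L1 = lagspec.lag
    n, pv = V.shape
    pl = C.shape[1]
    Z = np.zeros((n, pv * pl))
    for j, k in enumerate(lagspec.lags):
        shifted = np.zeros_like(V)
        if k == 0:
            shifted = V
        elif k < n:
            shifted[k:] = V[:-k]
        Z += np.einsum("iv,l->ivl", shifted, C[j]).reshape(n, pv * pl)
    complete = np.arange(n) >= L1
    names = [f"{v}:{l}" for v in varspec.labels() for l in lagspec.labels()]
    return CrossBasis(Z, names, varspec, lagspec, complete, C.sum(axis=0))


def dichotomy_basis(series, cutpoint, side, lagspec):
    """Hot/cold indicator distributed over lags.

    A cut-point beyond the observed range on the far side (every day
    would be flagged) is an error; a cut-point that no day exceeds
    yields an all-zero basis with a warning (harmless in itself, though
    such a term is inestimable in any model).
    """
    x = np.asarray(series, dtype=float)
    if side not in ("hot", "cold"):
        raise ValueError("side must be 'hot' or 'cold'")
    if (side == "hot" and cutpoint < x.min()) or (side == "cold" and cutpoint > x.max()):
        raise ValueError(
            f"cutpoint {cutpoint} outside observed range "
            f"[{x.min():.2f}, {x.max():.2f}]: every day would be a {side} day"
        )
    cb = crossbasis(x, DichotomyVarSpec(cutpoint, side), lagspec)
    if not cb.values.any():
        warnings.warn(f"no {side}-day exceedances at cut-point {cutpoint}", stacklevel=2)
    return cb


def ncs_basis(values, df=4, knots=None):
    """Natural-cubic-spline transform (no lag structure: lag window
    [0, 0]); ``df`` columns with knots at equally spaced quantiles when
    not supplied."""
    values = np.asarray(values, dtype=float)
    if knots is None:
        knots = ncs_knots(values, df)
    return crossbasis(values, NSVarSpec(tuple(knots)), LagSpec("unconstrained", (0, 0)))


def linear_spline_basis(values, knots):
    """Segmented-linear transform: linear term plus (x - k)+ hinges."""
    knots = list(knots)
    if any(b <= a for a, b in zip(knots, knots[1:])):
        raise ValueError("knots must be strictly increasing")
    return crossbasis(values, LinearSplineVarSpec(tuple(knots)), LagSpec("unconstrained", (0, 0)))


def shifted_crossbasis(series, gamma, group_anomalies, varspec, lagspec):
    """Per-group cross-bases evaluated at t + gamma * UHIa_g.

    The variable spec carries knots frozen from the unshifted series,
    so every group and every gamma sees the same spline shape, only
    displaced along the temperature axis.  Returns ``{group: CrossBasis}``.
    """
    x = np.asarray(series, dtype=float)
    if not isinstance(varspec, NSVarSpec):
        raise TypeError("shifted cross-basis requires a fixed-knot spline varspec")
    bmin, bmax = varspec.knots[0], varspec.knots[-1]
    out = {}
    for g, u in group_anomalies.items():
        shifted = x + gamma * u
        if shifted.max() > bmax + 5.0 or shifted.min() < bmin - 5.0:
            warnings.warn(
                f"group {g}: shifted temperatures extend > 5 degC beyond the knot range",
                stacklevel=2,
            )
        out[g] = crossbasis(shifted, varspec, lagspec)
    return out


# ---------------------------------------------------------------------------
# data-driven choices: cut-point and minimum-mortality temperature
#
# Both require fitting the case-crossover model repeatedly, so they sit
# on top of the conditional-Poisson engine.


@dataclass
class CutpointResult:
    cutpoint: float
    wald_z: float
    grid: list  # (candidate, z) pairs


def default_candidates(series, side, step=0.1):
    """Candidate cut-point grid: 90th-99th percentile (hot) or
    1st-25th percentile (cold) of the series, in ``step`` degC steps."""
    x = np.asarray(series, dtype=float)
    lo, hi = (np.percentile(x, [90, 99]) if side == "hot" else np.percentile(x, [1, 25]))
    return np.round(np.arange(lo, hi + step / 2, step), 6)


def select_cutpoint(city, deaths, season, side, candidates, lagspec=None,
                    uhia_by_group=None):
    """Choose the hot (cold) day cut-point maximizing the Wald z of the
    cumulative excess risk, z = log(RR) / SE(log RR), over a candidate
    grid.  Fits the dichotomy model once per candidate."""
    from .casecrossover import build_strata, fit_dichotomy_model

    candidates = np.asarray(candidates, dtype=float)
    if candidates.size < 1:
        raise ValueError("need at least one candidate cut-point")
    if lagspec is None:
        lagspec = SUMMER_LAG if side == "hot" else WINTER_LAG
    table = build_strata(deaths, city, season)
    temps = city["temp"].to_numpy()
    grid = []
    for c in candidates:
        exceed = (temps > c) if side == "hot" else (temps < c)
        if not exceed.any():
            continue
        fit, cb = fit_dichotomy_model(table, city, c, side, lagspec)
        w = cb.cumulative_weights()
        logrr = float(w @ fit.coef[: cb.ncol])
        se = float(np.sqrt(w @ fit.cov[: cb.ncol, : cb.ncol] @ w))
        grid.append((float(c), logrr / se))
    if not grid:
        raise ValueError("no candidate cut-point leaves any exceedance day")
    best = max(grid, key=lambda cz: abs(cz[1]))
    return CutpointResult(best[0], best[1], grid)


def find_mmt(city, deaths, df=4, lagspec=None, resolution=0.1):
    """Minimum-mortality temperature: the argmin over the observed range
    of the cumulative temperature-mortality curve from an all-year
    natural-cubic-spline model (grid search at ``resolution`` degC)."""
    from .casecrossover import build_strata, fit_spline_model

    if lagspec is None:
        lagspec = WINTER_LAG
    table = build_strata(deaths, city, "all")
    temps = city["temp"].to_numpy()
    knots = ncs_knots(temps, df)
    fit, cb = fit_spline_model(table, city, NSVarSpec(tuple(knots)), lagspec)
    xs = np.arange(temps.min(), temps.max() + resolution / 2, resolution)
    curve = cb.cumulative_curve(xs) @ fit.coef[: cb.ncol]
    i = int(np.argmin(curve))
    if i in (0, xs.size - 1):
        warnings.warn(
            "fitted temperature-mortality curve is monotone; returning the boundary",
            stacklevel=2,
        )
    return float(xs[i])
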