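"""Time-stratified case-crossover fitting via conditional Poisson regression.

Daily death counts per UHI-anomaly group are compared within strata of
(year, month, group): each stratum holds one calendar month of days for
one group, so every day acts as its own control set.  The likelihood is
conditioned on the stratum death totals, which removes the stratum
baseline rates exactly — this is the aggregate-count equivalent of
conditional logistic regression on individual case days, and its point
estimates coincide with an unconditional Poisson fit carrying one
indicator per stratum.

Conditioning on totals makes each stratum a multinomial over its days:

    l(beta) = sum_s [ sum_i y_i eta_i  -  Y_s log sum_i exp(eta_i) ]

with eta = X beta.  Newton-Raphson on this objective is the same
computation as iteratively reweighted least squares on the fixed-effects
formulation with the stratum intercepts profiled out in closed form at
every step; we fit the conditional objective directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

log = logging.getLogger("uhiacclim")

from .basis import DichotomyVarSpec, SUMMER_LAG, crossbasis

__all__ = [
    "SEASON_MONTHS",
    "FitResult",
    "ConditionalPoissonRegression",
    "build_strata",
    "covariate_matrix",
    "fit_conditional_poisson",
]


SEASON_MONTHS = {
    "summer": (6, 7, 8),
    "winter": (9, 10, 11, 12, 1, 2, 3, 4, 5),
    "oct-apr": (10, 11, 12, 1, 2, 3, 4),
    "all": tuple(range(1, 13)),
}


@dataclass
class FitResult:
    """Coefficients and inference from one conditional-Poisson fit."""

    coef: np.ndarray
    cov: np.ndarray
    names: list
    loglik: float
    deviance: float
    n_strata: int
    n_days: int
    scale: float  # Pearson dispersion (reported, not applied)
    n_iter: int

    @property
    def se(self):
        return np.sqrt(np.diag(self.cov))

    def summary(self):
        return pd.DataFrame({"coef": self.coef, "se": self.se}, index=self.names)


class ConditionalPoissonRegression:
    """Conditional Poisson regression for stratified count data.

    scikit-learn-style estimator: ``fit(X, y, strata=...)`` maximizes
    the Poisson likelihood conditional on stratum totals by Newton-
    Raphson with step halving.  Counts may be non-integer (expected
    counts define a valid quasi-likelihood and are useful for noiseless
    checks).

    Parameters
    ----------
    max_iter : Newton iteration cap.
    tol : relative log-likelihood convergence tolerance.
    quasi : if True, inflate the covariance by the Pearson dispersion.

    Attributes (after fit)
    ----------------------
    coef_, cov_, loglik_, deviance_, n_strata_, n_obs_, scale_,
    n_iter_, converged_, feature_names_in_, result_ (a FitResult).
    """

    def __init__(self, max_iter=100, tol=1e-10, quasi=False):
        self.max_iter = max_iter
        self.tol = tol
        self.quasi = quasi

    # minimal get/set_params so the estimator composes with sklearn tooling
    def get_params(self, deep=True):
        return {"max_iter": self.max_iter, "tol": self.tol, "quasi": self.quasi}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y, strata, start=None):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = [f"x{j}" for j in range(X.shape[1])]
        y = np.asarray(y, dtype=float)
        strata = np.asarray(strata)
        if X.ndim != 2 or y.shape[0] != X.shape[0] or strata.shape[0] != X.shape[0]:
            raise ValueError("X, y and strata must have matching first dimensions")
        if np.any(y < 0):
            raise ValueError("negative counts")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite design entries")

        codes, _ = pd.factorize(strata, sort=True)
        order = np.argsort(codes, kind="stable")
        Xs, ys, cs = X[order], y[order], codes[order]
        starts = np.flatnonzero(np.r_[True, np.diff(cs) != 0])
        totals = np.add.reduceat(ys, starts)

        # strata with zero deaths carry no conditional information
        keep_stratum = totals > 0
        if not keep_stratum.any():
            raise ValueError("all strata have zero total deaths")
        row_keep = np.repeat(keep_stratum, np.diff(np.r_[starts, ys.size]))
        Xs, ys, cs = Xs[row_keep], ys[row_keep], cs[row_keep]
        cs = pd.factorize(cs, sort=True)[0]
        starts = np.flatnonzero(np.r_[True, np.diff(cs) != 0])
        totals = np.add.reduceat(ys, starts)
        n, p = Xs.shape
        S = starts.size

        self._check_identifiable(Xs, cs, starts)

        seg = np.diff(np.r_[starts, n])

        def parts(beta):
            eta = Xs @ beta
            m = np.maximum.reduceat(eta, starts)
            w = np.exp(eta - np.repeat(m, seg))
            W = np.add.reduceat(w, starts)
            mu = w * np.repeat(totals / W, seg)  # conditional expected counts
            ll = float(ys @ eta - totals @ (np.log(W) + m))
            return mu, ll

        beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
        mu, ll = parts(beta)
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            grad = Xs.T @ (ys - mu)
            XtWX = Xs.T @ (Xs * mu[:, None])
            A = np.add.reduceat(Xs * mu[:, None], starts, axis=0)
            H = XtWX - (A / totals[:, None]).T @ A
            try:
                step = linalg.solve(H, grad, assume_a="pos")
            except linalg.LinAlgError:
                step = linalg.lstsq(H + 1e-8 * np.eye(p), grad)[0]
            # step halving keeps the ascent monotone
            for _ in range(40):
                cand = beta + step
                mu_new, ll_new = parts(cand)
                if ll_new >= ll - 1e-12:
                    break
                step *= 0.5
            else:
                raise RuntimeError(
                    f"conditional Poisson fit: step halving failed, |grad| = "
                    f"{np.linalg.norm(grad):.3e}"
                )
            done = abs(ll_new - ll) <= self.tol * (abs(ll) + 1.0)
            beta, mu, ll = cand, mu_new, ll_new
            if done:
                break
        else:
            grad = Xs.T @ (ys - mu)
            raise RuntimeError(
                f"conditional Poisson fit did not converge in {self.max_iter} "
                f"iterations (|grad| = {np.linalg.norm(grad):.3e})"
            )

        XtWX = Xs.T @ (Xs * mu[:, None])
        A = np.add.reduceat(Xs * mu[:, None], starts, axis=0)
        H = XtWX - (A / totals[:, None]).T @ A
        cov = linalg.inv(H)

        with np.errstate(divide="ignore", invalid="ignore"):
            ll_sat = float(np.sum(np.where(ys > 0, ys * np.log(ys), 0.0))
                           - totals @ np.log(totals))
        pearson = float(np.sum((ys - mu) ** 2 / mu))
        dof = max(n - S - p, 1)
        scale = pearson / dof
        if self.quasi:
            cov = cov * scale

        self.coef_ = beta
        self.cov_ = cov
        self.loglik_ = ll
        self.deviance_ = 2.0 * (ll_sat - ll)
        self.n_strata_ = S
        self.n_obs_ = n
        self.scale_ = scale
        self.n_iter_ = n_iter
        self.converged_ = True
        self.result_ = FitResult(
            beta, cov, self.feature_names_in_, ll, self.deviance_, S, n, scale, n_iter
        )
        return self

    def _check_identifiable(self, X, codes, starts):
        """Reject columns that are constant within every stratum (they are
        conditioned out) or collinear after within-stratum centering."""
        seg = np.diff(np.r_[starts, X.shape[0]])
        means = np.add.reduceat(X, starts, axis=0) / seg[:, None]
        Xc = X - np.repeat(means, seg, axis=0)
        norms = np.linalg.norm(Xc, axis=0)
        scale = np.linalg.norm(X, axis=0) + 1.0
        dead = np.flatnonzero(norms <= 1e-10 * scale)
        if dead.size:
            names = [self.feature_names_in_[j] for j in dead]
            raise ValueError(
                f"column(s) {names} are constant within every stratum and "
                "cannot be estimated in a conditional model"
            )
        # rank check with pivoting to name the redundant columns
        _, R, piv = linalg.qr(Xc, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Xc.shape) * np.finfo(float).eps * 100
        rank = int(np.sum(diag > tol))
        if rank < X.shape[1]:
            names = [self.feature_names_in_[j] for j in piv[rank:]]
            raise ValueError(
                f"design is rank deficient after within-stratum centering; "
                f"redundant column(s): {names}"
            )

    def predict(self, X, strata=None, totals=None):
        """Relative rates exp(X beta); with ``strata`` (and per-stratum
        ``totals``) returns conditional expected counts."""
        X = np.asarray(X, dtype=float)
        rate = np.exp(X @ self.coef_)
        if strata is None:
            return rate
        codes, uniq = pd.factorize(np.asarray(strata), sort=True)
        denom = np.bincount(codes, weights=rate, minlength=len(uniq))
        tot = np.asarray(totals, dtype=float)
        return rate * (tot / denom)[codes]

    def score(self, X, y, strata):
        """Conditional log-likelihood at the fitted coefficients."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        codes, uniq = pd.factorize(np.asarray(strata), sort=True)
        eta = X @ self.coef_
        m = np.full(len(uniq), -np.inf)
        np.maximum.at(m, codes, eta)
        w = np.exp(eta - m[codes])
        W = np.bincount(codes, weights=w, minlength=len(uniq))
        T = np.bincount(codes, weights=y, minlength=len(uniq))
        return float(y @ eta - T @ (np.log(W) + m))


# ---------------------------------------------------------------------------
# stratum-table construction and covariates


def build_strata(deaths, city, season, age_band=None):
    """Assemble the (day, group) stratum table for one seasonal window.

    ``deaths``: columns date, group, deaths (optionally age_band);
    ``city``: daily covariate frame indexed by date (temp, flu, ...).
    Strata are keyed by (year, month, group); the winter window spans
    the calendar year boundary, so its month strata simply keep their
    own calendar year.  Rows carry ``day_index``, the position of the
    date in the city series, through which lagged design blocks are
    attached (lags are computed on the full series before the seasonal
    restriction, so early-season days reach back into the prior months).
    """
    if season not in SEASON_MONTHS:
        raise ValueError(f"unknown season {season!r}; choose from {sorted(SEASON_MONTHS)}")
    months = SEASON_MONTHS[season]
    deaths = deaths.copy()
    deaths["date"] = pd.to_datetime(deaths["date"])
    if age_band is not None:
        if "age_band" not in deaths.columns:
            raise ValueError("deaths table has no age_band column")
        deaths = deaths[deaths["age_band"] == age_band].drop(columns="age_band")
        deaths = deaths.groupby(["date", "group"], as_index=False)["deaths"].sum()
    elif "age_band" in deaths.columns:
        deaths = deaths.groupby(["date", "group"], as_index=False)["deaths"].sum()

    cal = pd.DatetimeIndex(city.index)
    unknown = ~deaths["date"].isin(cal)
    if unknown.any():
        bad = deaths.loc[unknown, "date"].iloc[0].date()
        raise ValueError(f"death record dated outside the city series: {bad}")
    if (deaths["deaths"] < 0).any():
        raise ValueError("negative death counts")

    groups = np.sort(deaths["group"].unique())
    sel = cal[cal.month.isin(months)]
    table = pd.MultiIndex.from_product([sel, groups], names=["date", "group"]).to_frame(
        index=False
    )
    table = table.merge(deaths, on=["date", "group"], how="left")
    table["deaths"] = table["deaths"].fillna(0.0)
    table["year"] = table["date"].dt.year
    table["month"] = table["date"].dt.month
    table["stratum"] = table.groupby(["year", "month", "group"], sort=True).ngroup()
    pos = pd.Series(np.arange(len(cal)), index=cal)
    table["day_index"] = pos.loc[table["date"]].to_numpy()
    n_empty = int((table.groupby("stratum")["deaths"].sum() == 0).sum())
    log.info("built %d strata over %d rows (%s window); %d strata with zero deaths",
             table["stratum"].nunique(), len(table), season, n_empty)
    table["dow"] = table["date"].dt.dayofweek
    for col in city.columns:
        if col != "temp":
            table[col] = city[col].to_numpy()[table["day_index"]]
    return table


def covariate_matrix(table, pollution=False):
    """Day-of-week indicators (Monday reference), linear influenza count,
    and optional linear O3/PM10 terms."""
    cols, names = [], []
    for d in range(1, 7):
        cols.append((table["dow"].to_numpy() == d).astype(float))
        names.append(f"dow{d}")
    if "flu" in table.columns:
        cols.append(table["flu"].to_numpy(dtype=float))
        names.append("flu")
    if pollution:
        for c in ("o3", "pm10"):
            if c not in table.columns:
                raise ValueError(f"pollution adjustment requested but column {c!r} missing")
            cols.append(table[c].to_numpy(dtype=float))
            names.append(c)
    return np.column_stack(cols), names


def design_rows(table, cb_by_group=None, cb=None, min_history=None):
    """Expand full-series cross-basis blocks to (day, group) rows.

    Returns (rows mask respecting lag history, block matrix)."""
    idx = table["day_index"].to_numpy()
    if cb is not None:
        block = cb.values[idx]
        complete = cb.complete[idx]
    else:
        any_cb = next(iter(cb_by_group.values()))
        block = np.empty((len(table), any_cb.ncol))
        complete = any_cb.complete[idx]
        grp = table["group"].to_numpy()
        for g, c in cb_by_group.items():
            m = grp == g
            block[m] = c.values[idx[m]]
    if min_history is not None:
        complete = complete & (idx >= min_history)
    if not complete.all():
        log.info("dropping %d row(s) lacking full lag history", int((~complete).sum()))
    return complete, block


def _fit(table, blocks, names, start=None, quasi=False):
    X = np.column_stack(blocks)
    est = ConditionalPoissonRegression(quasi=quasi)
    est.fit(pd.DataFrame(X, columns=names), table["deaths"].to_numpy(),
            table["stratum"].to_numpy(), start=start)
    return est


def fit_conditional_poisson(table, design, names=None, quasi=False):
    """Fit the case-crossover model for an assembled design matrix
    aligned with ``table`` rows; returns a :class:`FitResult`."""
    X = np.asarray(design, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    est = ConditionalPoissonRegression(quasi=quasi)
    est.fit(pd.DataFrame(X, columns=names), table["deaths"].to_numpy(),
            table["stratum"].to_numpy())
    return est.result_


def fit_dichotomy_model(table, city, cutpoint, side, lagspec, pollution=False):
    """Hot/cold dichotomy model without interactions; used for cut-point
    selection and as the base of the IRR models."""
    cb = crossbasis(city["temp"].to_numpy(), DichotomyVarSpec(cutpoint, side), lagspec)
    complete, block = design_rows(table, cb=cb)
    sub = table[complete]
    cov, covnames = covariate_matrix(sub, pollution=pollution)
    est = _fit(sub, [block[complete], cov], cb.colnames + covnames)
    return est.result_, cb


def fit_spline_model(table, city, varspec, lagspec, pollution=False):
    """All-year (or seasonal) spline temperature model; used for the MMT."""
    cb = crossbasis(city["temp"].to_numpy(), varspec, lagspec)
    complete, block = design_rows(table, cb=cb)
    sub = table[complete]
    cov, covnames = covariate_matrix(sub, pollution=pollution)
    est = _fit(sub, [block[complete], cov], cb.colnames + covnames)
    return est.result_, cb
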