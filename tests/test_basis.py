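"""Spline, dichotomy and cross-basis construction."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import lstsq, null_space

from uhiacclim import (
    LagSpec,
    SUMMER_LAG,
    WINTER_LAG,
    SimulationConfig,
    crossbasis,
    dichotomy_basis,
    find_mmt,
    linear_spline_basis,
    ncs_basis,
    select_cutpoint,
    simulate,
)
from uhiacclim.basis import NSVarSpec, natural_spline, ncs_knots


def truncated_power_natural_span(xs, knots):
    """Independent construction of the natural-cubic-spline space: the
    cubic truncated-power basis with the linear-tail constraints imposed
    through its null space."""
    knots = np.asarray(knots, float)
    cols = [np.ones_like(xs), xs, xs**2, xs**3]
    cols += [np.maximum(xs - k, 0.0) ** 3 for k in knots]
    TP = np.column_stack(cols)
    # natural constraints: a2 = a3 = 0 (linear left tail) and
    # sum b_j = 0, sum b_j xi_j = 0 (linear right tail)
    nk = len(knots)
    C = np.zeros((4, 4 + nk))
    C[0, 2] = 1.0
    C[1, 3] = 1.0
    C[2, 4:] = 1.0
    C[3, 4:] = knots
    return TP @ null_space(C)


class TestNaturalSpline:
    def test_linear_beyond_boundaries(self):
        knots = [0.0, 2.0, 5.0, 9.0, 10.0]
        left = natural_spline(np.linspace(-6, -1, 30), knots)
        right = natural_spline(np.linspace(11, 16, 30), knots)
        for B, xs in ((left, np.linspace(-6, -1, 30)), (right, np.linspace(11, 16, 30))):
            for j in range(B.shape[1]):
                # second finite difference of a linear function vanishes
                assert np.allclose(np.diff(B[:, j], 2), 0, atol=1e-8)

    def test_matches_truncated_power_construction(self):
        knots = [1.0, 3.0, 6.0, 8.5, 12.0]
        xs = np.linspace(-2, 15, 400)
        mine = np.column_stack([np.ones_like(xs), natural_spline(xs, knots)])
        oracle = truncated_power_natural_span(xs, knots)
        assert mine.shape[1] == oracle.shape[1]
        for A, B in ((mine, oracle), (oracle, mine)):
            coef, *_ = lstsq(A, B)
            assert np.abs(A @ coef - B).max() < 1e-8

    def test_df_gives_df_columns(self, rng):
        temps = rng.normal(12, 5, 500)
        cb = ncs_basis(temps, df=4)
        assert cb.values.shape == (500, 4)

    def test_df_exceeding_distinct_values_errors(self):
        with pytest.raises(ValueError, match="duplicate knots|resolution"):
            ncs_basis(np.array([1.0, 1.0, 2.0, 2.0]), df=4)


class TestLinearSpline:
    def test_single_knot_hinge_definition(self):
        cb = linear_spline_basis(np.array([-1.0, 0.0, 1.0]), [0.0])
        assert np.allclose(cb.values[:, 0], [-1, 0, 1])
        assert np.allclose(cb.values[:, 1], [0, 0, 1])

    def test_exact_slope_recovery_on_noiseless_data(self, rng):
        knots = (6.4, 18.6, 22.3)
        slopes = (-0.03, 0.0, 0.0, 0.07)  # per segment, left to right
        x = rng.uniform(0, 30, 400)
        pieces = np.interp(x, [-10, *knots, 40],
                           np.cumsum([0] + [s * d for s, d in zip(
                               slopes, np.diff([-10, *knots, 40]))]).tolist())
        cb = linear_spline_basis(x, list(knots))
        coef, *_ = lstsq(np.column_stack([np.ones_like(x), cb.values]), pieces)
        # segment slopes are cumulative sums of (linear, hinge...) coefficients
        rec = np.cumsum(coef[1:])
        assert np.allclose(rec, slopes, atol=1e-10)

    def test_non_increasing_knots_error(self):
        with pytest.raises(ValueError, match="increasing"):
            linear_spline_basis(np.arange(5.0), [2.0, 2.0])


class TestDichotomy:
    def test_no_exceedance_gives_zero_basis(self):
        with pytest.warns(UserWarning, match="no hot-day"):
            cb = dichotomy_basis(np.full(10, 20.0), 22.3, "hot", SUMMER_LAG)
        assert not cb.values.any()

    def test_degenerate_all_one_cutpoint_errors(self):
        with pytest.raises(ValueError, match="outside observed range"):
            dichotomy_basis(np.full(10, 25.0), 20.0, "hot", SUMMER_LAG)

    def test_hand_shifted_indicator(self):
        cb = dichotomy_basis(np.array([20, 23, 24, 20, 20.0]), 22.3, "hot", SUMMER_LAG)
        assert np.allclose(cb.values[:, 0], [0, 1, 1, 0, 0])  # lag 0
        assert np.allclose(cb.values[1:, 1], [0, 1, 1, 0])  # lag 1
        assert not cb.complete[0] and cb.complete[1:].all()

    def test_spline_lag_cumulative_contract(self):
        # a day preceded by 14 consecutive exceedances carries the full
        # cumulative exposure: its row equals the lag-basis column sums
        x = np.r_[np.full(20, 25.0), np.full(10, 10.0)]
        cb = dichotomy_basis(x, 22.3, "hot", WINTER_LAG)
        assert np.allclose(cb.values[19], cb.lag_weights)
        assert np.allclose(cb.cumulative_weights(), cb.lag_weights)


class TestCrossBasis:
    @pytest.mark.parametrize("varspec,lagspec", [
        (NSVarSpec((2.0, 8.0, 14.0, 20.0, 26.0)), WINTER_LAG),
        (NSVarSpec((2.0, 8.0, 14.0, 20.0, 26.0)), SUMMER_LAG),
    ])
    def test_matches_brute_force_double_loop(self, rng, varspec, lagspec):
        x = rng.uniform(0, 28, 30)
        cb = crossbasis(x, varspec, lagspec)
        V = varspec.design(x)
        C = lagspec.basis()
        L0, L1 = lagspec.lag
        for t in range(L1, 30):
            row = np.zeros((V.shape[1], C.shape[1]))
            for k in range(L0, L1 + 1):
                for v in range(V.shape[1]):
                    for l in range(C.shape[1]):
                        row[v, l] += V[t - k, v] * C[k - L0, l]
            assert np.abs(cb.values[t] - row.ravel()).max() < 1e-10

    def test_deterministic(self, rng):
        x = rng.uniform(0, 28, 60)
        vs = NSVarSpec(tuple(ncs_knots(x, 4)))
        a = crossbasis(x, vs, WINTER_LAG).values
        b = crossbasis(x, vs, WINTER_LAG).values
        assert (a == b).all()


class TestShiftedCrossbasis:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.x = rng.uniform(5, 25, 100)
        self.vs = NSVarSpec(tuple(ncs_knots(self.x, 4)))

    def test_gamma_zero_identical_across_groups(self):
        from uhiacclim import shifted_crossbasis

        cbs = shifted_crossbasis(self.x, 0.0, {1: -0.9, 2: 0.6}, self.vs, SUMMER_LAG)
        assert np.allclose(cbs[1].values, cbs[2].values)

    def test_gamma_one_equals_unshifted_at_displaced_temps(self):
        from uhiacclim import shifted_crossbasis

        cbs = shifted_crossbasis(self.x, 1.0, {1: -0.5, 2: 0.5}, self.vs, SUMMER_LAG)
        for g, u in ((1, -0.5), (2, 0.5)):
            direct = crossbasis(self.x + u, self.vs, SUMMER_LAG)
            assert np.allclose(cbs[g].values, direct.values)

    def test_continuity_in_gamma(self):
        from uhiacclim import shifted_crossbasis

        base = shifted_crossbasis(self.x, 0.5, {1: 0.8}, self.vs, SUMMER_LAG)[1]
        deltas = [1e-2, 1e-4, 1e-6]
        diffs = [np.abs(shifted_crossbasis(self.x, 0.5 + d, {1: 0.8}, self.vs,
                                           SUMMER_LAG)[1].values - base.values).max()
                 for d in deltas]
        assert diffs[0] > diffs[1] > diffs[2]
        assert diffs[2] < 1e-4


class TestCutpointSelection:
    def _step_sim(self, seed, threshold=22.0):
        """Deaths with a genuine step (not hinge) in risk above the
        threshold, so the most-significant dichotomy recovers it."""
        cfg = SimulationConfig.small(heat_slope=0.0, cold_slope=0.0, seed=seed)
        ds = simulate(cfg, noiseless=True)
        rng = np.random.default_rng(seed + 5000)
        hot = (ds.city["temp"].to_numpy() > threshold).astype(float)
        deaths = ds.deaths.copy()
        pos = pd.Series(np.arange(len(ds.city)), index=ds.city.index)
        lift = np.exp(0.15 * hot)[pos.loc[deaths["date"]].to_numpy()]
        deaths["deaths"] = rng.poisson(deaths["deaths"].to_numpy() * lift)
        return ds.city, deaths

    def test_recovers_step_threshold(self):
        candidates = np.arange(20.0, 24.01, 0.5)
        hits = 0
        n = 20
        for seed in range(n):
            city, deaths = self._step_sim(seed)
            res = select_cutpoint(city, deaths, "summer", "hot", candidates)
            hits += abs(res.cutpoint - 22.0) <= 0.5
        assert hits >= int(0.8 * n)

    def test_singleton_candidate_returned(self, small_sim):
        res = select_cutpoint(small_sim.city, small_sim.deaths, "summer", "hot",
                              [22.3])
        assert res.cutpoint == 22.3
        assert np.isfinite(res.wald_z)
        assert len(res.grid) == 1

    def test_grid_z_all_finite(self, small_sim):
        res = select_cutpoint(small_sim.city, small_sim.deaths, "summer", "hot",
                              np.arange(21.0, 24.0, 1.0))
        assert all(np.isfinite(z) for _, z in res.grid)


class TestFindMmt:
    def test_recovers_v_shaped_vertex(self):
        hits = []
        for seed in range(3):
            cfg = SimulationConfig.small(
                heat_knot=18.01, mmt=18.0, cold_knot=17.99,
                heat_slope=0.05, cold_slope=0.05, seed=seed,
            )
            ds = simulate(cfg)
            hits.append(find_mmt(ds.city, ds.deaths))
        assert np.abs(np.asarray(hits) - 18.0).max() < 1.0
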