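"""Shell-hash accumulation model against independent ODE and bisection oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from impactcurves import (
    HARDWATER_LAKE,
    MODERATE_LAKE,
    MODERATE_RIVER,
    ProductionSeries,
    ShellParams,
    equilibrium_stock,
    production_stock_coupling,
    simulate_stock,
    stock_at_time,
    time_to_fraction,
)

CANONICAL = [HARDWATER_LAKE, MODERATE_LAKE, MODERATE_RIVER]


def ode_stock(production: float, k: float, t: float, s0: float = 0.0) -> float:
    """Independent oracle: numerically integrate dS/dt = P - kS."""
    sol = solve_ivp(
        lambda _, s: production - k * s,
        (0.0, t),
        [s0],
        rtol=1e-10,
        atol=1e-12,
        dense_output=True,
    )
    return float(sol.y[0, -1])


class TestEquilibrium:
    @pytest.mark.parametrize(
        "production,k,expected",
        [(0.0, 0.05, 0.0), (0.0, 2.0, 0.0), (1.0, 0.05, 20.0), (1.0, 2.0, 0.5)],
    )
    def test_matches_long_horizon_integration(self, production, k, expected):
        assert equilibrium_stock(production, ShellParams(k)) == pytest.approx(expected)
        # the ODE settles onto the same value after many loss time-constants
        assert ode_stock(production, k, t=30.0 / k) == pytest.approx(expected, rel=1e-6)

    def test_ratio_of_equilibrium_to_annual_production_is_reciprocal_loss_rate(self):
        for params in CANONICAL:
            assert equilibrium_stock(1.0, params) == pytest.approx(1.0 / params.k)

    def test_linear_in_production_at_fixed_loss_rate(self):
        # the within-ecosystem abundance-impact curve is a line through the origin
        base = equilibrium_stock(1.0, MODERATE_LAKE)
        for p in (0.0, 0.5, 2.0, 7.3):
            assert equilibrium_stock(p, MODERATE_LAKE) == pytest.approx(p * base)

    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValueError):
            ShellParams(k=0.0)
        with pytest.raises(ValueError):
            ShellParams(k=-0.3)
        with pytest.raises(ValueError):
            equilibrium_stock(-1.0, MODERATE_LAKE)


class TestStockAtTime:
    @pytest.mark.parametrize("params", CANONICAL, ids=lambda p: f"k={p.k}")
    def test_agrees_with_fine_ode_integration_over_century(self, params):
        for t in (0.5, 1, 5, 10, 25, 50, 100):
            closed = stock_at_time(1.0, params, t, s0=0.0)
            numeric = ode_stock(1.0, params.k, t)
            assert closed == pytest.approx(numeric, rel=1e-3)

    def test_initial_condition_and_asymptote(self):
        assert stock_at_time(1.0, MODERATE_RIVER, 0.0, s0=3.2) == 3.2
        assert stock_at_time(1.0, MODERATE_RIVER, 50.0, s0=0.0) == pytest.approx(0.5)

    def test_slow_system_ten_year_value(self):
        # 20 * (1 - e^-0.5), cross-checked by the ODE oracle
        got = stock_at_time(1.0, HARDWATER_LAKE, 10.0)
        assert got == pytest.approx(20.0 * (1 - math.exp(-0.5)))
        assert got == pytest.approx(ode_stock(1.0, 0.05, 10.0), rel=1e-3)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            stock_at_time(1.0, MODERATE_RIVER, -1.0)


class TestSimulateStock:
    def test_constant_forcing_asymptotes_at_equilibrium(self):
        series = ProductionSeries.constant(1.0, 10)
        traj = simulate_stock(series, MODERATE_RIVER)
        # within 1% of P/k by year 3 (time to 99% is ln(100)/2 ~ 2.3 yr)
        i3 = np.searchsorted(traj.times, 3.0)
        assert traj.stock[i3:] == pytest.approx(0.5, rel=0.01)

    def test_unforced_stock_decays_exponentially(self):
        series = ProductionSeries.constant(0.0, 6)
        traj = simulate_stock(series, MODERATE_RIVER, s0=1.0)
        assert traj.stock == pytest.approx(np.exp(-2.0 * traj.times))

    def test_independent_of_reporting_resolution(self, hudson_like_series):
        """Exponential updates are exact, so refining the grid (same
        piecewise-constant forcing) must not change the stocks at year marks."""
        coarse = simulate_stock(hudson_like_series, HARDWATER_LAKE)
        fine_t = np.arange(0, len(hudson_like_series), 0.25)
        fine_v = hudson_like_series.values[np.floor(fine_t).astype(int)]
        fine = simulate_stock(ProductionSeries(fine_t, fine_v), HARDWATER_LAKE)
        on_years = np.isin(fine.times, coarse.times)
        assert fine.stock[on_years] == pytest.approx(coarse.stock, rel=1e-12)

    def test_variable_forcing_matches_ode_oracle(self, hudson_like_series):
        series = ProductionSeries(
            hudson_like_series.times[:30], hudson_like_series.values[:30]
        )
        traj = simulate_stock(series, MODERATE_LAKE)
        s, k = 0.0, MODERATE_LAKE.k
        for i, p in enumerate(series.values):
            s = ode_stock(p, k, traj.times[i + 1] - traj.times[i], s0=s)
            assert traj.stock[i + 1] == pytest.approx(s, rel=1e-6)

    def test_smooths_production_variability_when_dissolution_is_slow(
        self, hudson_like_series
    ):
        """Slow-dissolving systems integrate decades of production, so the
        stock's relative year-to-year variation is far below the forcing's."""
        traj = simulate_stock(hudson_like_series, HARDWATER_LAKE)
        tail = slice(100, None)
        cv_prod = np.std(hudson_like_series.values[tail]) / np.mean(
            hudson_like_series.values[tail]
        )
        stock_tail = traj.stock[1:][tail]
        cv_stock = np.std(stock_tail) / np.mean(stock_tail)
        assert cv_stock < cv_prod / 3

    def test_mass_balance_in_the_long_run(self):
        """k * time-mean stock equals mean production (steady-state balance).

        The continuous time-mean is computed per interval from the exact
        solution: integral S dt = Seq*dt + (S0-Seq)(1-exp(-k dt))/k.
        """
        from impactcurves import TrajectoryParams, generate_trajectory

        series = generate_trajectory(TrajectoryParams(n_years=2000, seed=7))
        for params in (HARDWATER_LAKE, MODERATE_RIVER):
            traj = simulate_stock(series, params)
            k = params.k
            total = 0.0
            for i, p in enumerate(series.values):
                dt = traj.times[i + 1] - traj.times[i]
                seq = p / k
                total += seq * dt + (traj.stock[i] - seq) * (1 - math.exp(-k * dt)) / k
            mean_stock = total / (traj.times[-1] - traj.times[0])
            assert k * mean_stock == pytest.approx(series.values.mean(), rel=0.02)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ProductionSeries([], [])


class TestTimeToFraction:
    @pytest.mark.parametrize(
        "params,frac,expected",
        [
            (MODERATE_RIVER, 0.95, math.log(20) / 2),  # ~1.50 yr: fast systems within ~5 yr
            (HARDWATER_LAKE, 0.95, math.log(20) / 0.05),  # ~59.9 yr: several decades
        ],
    )
    def test_matches_bisection_on_simulated_stock(self, params, frac, expected):
        got = time_to_fraction(params, frac)
        assert got == pytest.approx(expected, rel=1e-12)
        # independent oracle: bisect stock_at_time for the crossing
        target = frac * equilibrium_stock(1.0, params)
        lo, hi = 0.0, 1000.0
        for _ in range(80):
            mid = (lo + hi) / 2
            if stock_at_time(1.0, params, mid) < target:
                lo = mid
            else:
                hi = mid
        assert got == pytest.approx((lo + hi) / 2, abs=1e-9)

    def test_small_fraction_limit_is_zero(self):
        assert time_to_fraction(MODERATE_RIVER, 1e-12) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_outside_unit_interval_rejected(self, frac):
        with pytest.raises(ValueError):
            time_to_fraction(MODERATE_RIVER, frac)


class TestCoupling:
    def test_fast_dissolution_couples_stock_to_production(self, hudson_like_series):
        res = production_stock_coupling(hudson_like_series, MODERATE_RIVER)
        assert res.defined
        assert res.correlation > 0.95

    def test_slow_dissolution_decouples_stock_from_production(self, hudson_like_series):
        res = production_stock_coupling(hudson_like_series, HARDWATER_LAKE)
        assert res.defined
        assert abs(res.correlation) < 0.5

    def test_burn_in_removes_initialisation_transient(self, hudson_like_series):
        res = production_stock_coupling(hudson_like_series, HARDWATER_LAKE)
        assert res.years[0] - hudson_like_series.times[0] >= res.burn_in_years == 100.0

    def test_constant_production_flagged_undefined(self):
        series = ProductionSeries.constant(1.0, 40)
        res = production_stock_coupling(series, MODERATE_RIVER)
        assert not res.defined
        assert math.isnan(res.correlation)

    def test_too_short_series_rejected(self):
        series = ProductionSeries.constant(1.0, 8)
        with pytest.raises(ValueError):
            production_stock_coupling(series, MODERATE_RIVER)


class TestMonotonicityProperties:
    @given(
        k1=st.floats(0.01, 5.0),
        k2=st.floats(0.01, 5.0),
        p=st.floats(0.01, 10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_equilibrium_strictly_decreasing_in_loss_rate(self, k1, k2, p):
        if k1 == k2:
            return
        lo, hi = sorted((k1, k2))
        assert equilibrium_stock(p, ShellParams(lo)) > equilibrium_stock(p, ShellParams(hi))

    @given(
        k1=st.floats(0.01, 5.0),
        k2=st.floats(0.01, 5.0),
        f1=st.floats(0.01, 0.99),
        f2=st.floats(0.01, 0.99),
    )
    @settings(max_examples=100, deadline=None)
    def test_approach_time_decreasing_in_k_and_increasing_in_fraction(self, k1, k2, f1, f2):
        if k1 != k2:
            lo, hi = sorted((k1, k2))
            assert time_to_fraction(ShellParams(lo), f1) > time_to_fraction(ShellParams(hi), f1)
        if f1 != f2:
            lo_f, hi_f = sorted((f1, f2))
            assert time_to_fraction(ShellParams(k1), lo_f) < time_to_fraction(ShellParams(k1), hi_f)

    @given(
        s0=st.floats(0.0, 50.0),
        p=st.floats(0.0, 10.0),
        t=st.floats(0.0, 200.0),
        k=st.floats(0.01, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_stock_moves_monotonically_toward_equilibrium(self, s0, p, t, k):
        params = ShellParams(k)
        seq = equilibrium_stock(p, params)
        s_t = stock_at_time(p, params, t, s0=s0)
        assert abs(s_t - seq) <= abs(s0 - seq) + 1e-12
        assert s_t >= 0
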