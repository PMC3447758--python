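"""Partial-equilibrium market model: calibration, solving, welfare."""

import numpy as np
import pytest

from pinewilt.market import (
    CalibrationError,
    MarketBaseline,
    ShockError,
    SupplyShock,
    annual_welfare_series,
    calibrate,
    clearing_residual,
    consumer_surplus_change,
    equilibrium_change_table,
    producer_surplus_change,
    shock_from_cumulative_loss,
    solve_equilibrium,
    welfare_change,
    welfare_from_shock,
)


@pytest.fixture(scope="module")
def baseline():
    return MarketBaseline.eu_round_wood()


@pytest.fixture(scope="module")
def market(baseline):
    return calibrate(baseline)


class TestCalibration:
    def test_price_offset(self, market):
        assert market.mu == pytest.approx(50.49 - 54.5)

    def test_demand_curve_reproduces_baseline(self, market, baseline):
        assert market.demand(baseline.producer_price) == pytest.approx(
            249_101.0, rel=1e-12
        )

    def test_supply_curve_reproduces_baseline(self, market, baseline):
        assert market.supply(baseline.producer_price) == pytest.approx(
            242_528.0, rel=1e-12
        )

    def test_trade_curve_reproduces_baseline_net_imports(self, market, baseline):
        wp = baseline.producer_price - market.mu
        assert market.net_imports(baseline.producer_price) == pytest.approx(
            baseline.consumption - baseline.production, rel=1e-12
        )
        assert wp == pytest.approx(baseline.world_price)

    def test_degenerate_trade_rejected(self, baseline):
        closed = MarketBaseline(
            consumption=100.0, production=100.0, producer_price=50.0,
            world_price=50.0, demand_elasticity=-0.11, supply_elasticity=0.8,
            trade_elasticity=6.07,
        )
        with pytest.raises(CalibrationError):
            calibrate(closed)


class TestSupplyShock:
    def test_zero_cumulative_loss_gives_zero_shock(self, baseline):
        assert shock_from_cumulative_loss(0.0, 50.49, baseline).x == 0.0

    def test_reported_fine_resolution_shock(self, baseline):
        # 22,375 M€ at 50.49 €/m³, 1.8% flow rule, 242,528 thousand m³ base
        shock = shock_from_cumulative_loss(22_375.0, 50.49, baseline)
        assert shock.x == pytest.approx(0.0329, abs=2e-4)

    def test_linearity_in_cumulative_loss(self, baseline):
        x1 = shock_from_cumulative_loss(5_000.0, 50.49, baseline).x
        x2 = shock_from_cumulative_loss(10_000.0, 50.49, baseline).x
        assert x2 == pytest.approx(2 * x1, rel=1e-12)

    def test_oversized_shock_rejected(self, baseline):
        with pytest.raises(ShockError):
            shock_from_cumulative_loss(1e9, 50.49, baseline)

    def test_z_h_decomposition_must_be_consistent(self):
        with pytest.raises(ShockError):
            SupplyShock(x=0.05, z=0.5, h=0.2)
        shock = SupplyShock(x=0.1, z=0.5, h=0.2)
        assert shock.supply_multiplier(0.8) == pytest.approx(0.9)


class TestEquilibrium:
    def test_zero_shock_is_baseline_fixed_point(self, market, baseline):
        state = solve_equilibrium(market, SupplyShock(x=0.0))
        assert state.price == pytest.approx(baseline.producer_price, rel=1e-9)
        assert state.demand == pytest.approx(baseline.consumption, rel=1e-9)
        assert state.supply == pytest.approx(baseline.production, rel=1e-9)

    def test_market_clears_at_solution(self, market):
        state = solve_equilibrium(market, SupplyShock(x=0.0329))
        residual = state.supply + market.net_imports(state.price) - state.demand
        assert abs(residual) / state.demand < 1e-9

    def test_solver_matches_grid_search_oracle(self, market):
        """Brute-force 0.001 €/m³ grid scan over price must agree with the
        bracketed root-finder."""
        shock = SupplyShock(x=0.0329)
        grid = np.arange(50.49, 55.0, 0.001)
        residuals = np.abs(clearing_residual(market, shock, grid))
        p_grid = grid[np.argmin(residuals)]
        state = solve_equilibrium(market, shock)
        assert state.price == pytest.approx(p_grid, abs=0.001)

    def test_equilibrium_unique_on_bracket(self, market, baseline):
        """Clearing residual changes sign exactly once on the bracket."""
        shock = SupplyShock(x=0.03)
        p0 = baseline.producer_price
        grid = np.linspace(p0 / 2, 4 * p0, 1000)
        signs = np.sign(clearing_residual(market, shock, grid))
        assert int(np.sum(signs[:-1] != signs[1:])) == 1

    def test_comparative_statics(self, market):
        prices, demands = [], []
        for x in (0.0, 0.01, 0.02, 0.03, 0.04, 0.05):
            state = solve_equilibrium(market, SupplyShock(x=x))
            prices.append(state.price)
            demands.append(state.demand)
        assert all(a < b for a, b in zip(prices, prices[1:]))
        assert all(a > b for a, b in zip(demands, demands[1:]))

    def test_reported_shock_price_in_expected_band(self, market):
        state = solve_equilibrium(market, SupplyShock(x=0.0329))
        assert 1.4 <= state.price - market.baseline.producer_price <= 1.7


class TestConsumerSurplus:
    def test_no_price_change_no_change(self, market, baseline):
        p0 = baseline.producer_price
        assert consumer_surplus_change(market, p0, p0) == 0.0

    def test_reported_fine_resolution_loss(self, market, baseline):
        dcs = consumer_surplus_change(
            market, baseline.producer_price, baseline.producer_price + 1.44
        )
        assert dcs == pytest.approx(-357.0, rel=0.02)

    def test_closed_form_matches_numerical_integration(self, market, baseline):
        p0, p1 = baseline.producer_price, baseline.producer_price + 1.44
        grid = np.linspace(p0, p1, 10_001)
        numeric = -np.trapezoid(market.demand(grid), grid) / 1e3
        closed = consumer_surplus_change(market, p0, p1)
        assert closed == pytest.approx(numeric, rel=1e-6)

    def test_unit_elastic_demand_uses_log_form(self):
        b = MarketBaseline(
            consumption=100.0, production=90.0, producer_price=50.0,
            world_price=55.0, demand_elasticity=-1.0, supply_elasticity=0.8,
            trade_elasticity=2.0,
        )
        m = calibrate(b)
        grid = np.linspace(50.0, 55.0, 20_001)
        numeric = -np.trapezoid(m.demand(grid), grid) / 1e3
        assert consumer_surplus_change(m, 50.0, 55.0) == pytest.approx(
            numeric, rel=1e-6
        )


class TestProducerSurplus:
    def test_zero_shock_zero_change(self, market, baseline):
        dps = producer_surplus_change(
            market, baseline.production, baseline.producer_price
        )
        assert dps == pytest.approx(0.0, abs=1e-9)

    def test_reported_fine_resolution_gain(self, market):
        dps = producer_surplus_change(market, 242_528.0 - 1_890.0, 50.49 + 1.44)
        assert dps == pytest.approx(139.0, rel=0.02)

    def test_closed_form_matches_numerical_integration(self, market, baseline):
        """PS = ∫ (P − inverse-supply) dS equals S·P/(1+θ) for the curve
        through the post-shock point."""
        shock = SupplyShock(x=0.0329)
        state = solve_equilibrium(market, shock)
        theta = baseline.supply_elasticity
        # shifted curve through (state.price, state.supply)
        scale = state.supply / state.price**theta
        s_grid = np.linspace(1e-9, state.supply, 200_001)
        inv_supply = (s_grid / scale) ** (1.0 / theta)
        numeric = (state.supply * state.price - np.trapezoid(inv_supply, s_grid)) / 1e3
        ps_after = state.supply * state.price / (1 + theta) / 1e3
        assert ps_after == pytest.approx(numeric, rel=1e-6)


class TestWelfare:
    def test_additivity_identity(self):
        w = welfare_change(-357.0, 139.0)
        assert w.total == -218.0

    def test_reported_coarse_resolution_sum(self):
        w = welfare_change(-597.0, 228.0)
        assert w.total == -369.0

    def test_loss_magnitude_monotone_in_shock(self, market):
        losses = [
            abs(welfare_from_shock(market, SupplyShock(x=x))[1].total)
            for x in (0.0, 0.01, 0.02, 0.03, 0.05)
        ]
        assert losses == sorted(losses)

    def test_reported_shock_welfare_in_expected_band(self, market):
        _, w = welfare_from_shock(market, SupplyShock(x=0.0329))
        assert -260.0 <= w.total <= -200.0


class TestAnnualSeries:
    def _impacts(self, cumulative_meur):
        import pandas as pd

        years = list(range(2008, 2008 + len(cumulative_meur)))
        cum = np.asarray(cumulative_meur) * 1e6
        return pd.DataFrame(
            {"year": years, "cumulative_eur": cum,
             "marginal_eur": np.diff(cum, prepend=0.0)}
        )

    def test_all_zero_series(self, market):
        df = annual_welfare_series(self._impacts([0.0, 0.0, 0.0]), market, 50.49)
        assert np.allclose(df["total_welfare_meur"], 0.0)

    def test_single_year_matches_one_shot(self, market, baseline):
        df = annual_welfare_series(self._impacts([10_000.0]), market, 50.49)
        shock = shock_from_cumulative_loss(10_000.0, 50.49, baseline)
        _, w = welfare_from_shock(market, shock)
        assert df["total_welfare_meur"].iloc[0] == pytest.approx(w.total, rel=1e-12)

    def test_monotone_cumulative_gives_monotone_welfare_loss(self, market):
        df = annual_welfare_series(
            self._impacts([0.0, 2_000.0, 8_000.0, 15_000.0, 22_375.0]), market, 50.49
        )
        losses = (-df["total_welfare_meur"]).tolist()
        assert losses == sorted(losses)

    def test_decreasing_cumulative_rejected(self, market):
        with pytest.raises(ValueError):
            annual_welfare_series(self._impacts([5_000.0, 1_000.0]), market, 50.49)


class TestChangeTable:
    def test_zero_shock_all_changes_zero(self, market):
        table = equilibrium_change_table(market, SupplyShock(x=0.0))
        assert np.allclose(table["absolute_change"], 0.0, atol=1e-9)

    def test_supply_falls_price_rises(self, market):
        table = equilibrium_change_table(market, SupplyShock(x=0.0329)).set_index(
            "quantity"
        )
        assert table.loc["supply_million_m3", "absolute_change"] < 0
        assert table.loc["price_eur_m3", "absolute_change"] > 0
        assert table.loc["total_welfare_meur", "absolute_change"] < 0
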