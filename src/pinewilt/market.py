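"""Partial-equilibrium model of the EU conifer industrial round-wood market.

Constant-elasticity (log-linear) curves:

* demand          D(P)  = χ P^η              (η < 0)
* domestic supply S(P)  = β g(x, ν) P^θ      (θ > 0)
* net imports     M(WP) = υ WP^ω             (ω > 0)
* price link      P     = WP + µ             (µ from transport costs/tariffs)

where ``g`` is the supply-shift multiplier produced by the pest shock.  With
a fraction ``z`` of producers affected, proportional wood loss ``h`` and a
proportional cost increase ``ν`` for affected producers,

    g = (1 - z) + z (1 - h) (1 - ν)^θ,

which reduces to ``1 - x`` with ``x = z·h`` when ``ν = 0``.  The scale
parameters (χ, β, υ) and the price offset µ are calibrated so the curves
reproduce the baseline consumption, production and net trade exactly.  The
equilibrium price clears the market, S + M = D; welfare changes are measured
as consumer-surplus and producer-surplus changes between equilibria.

Units: quantities in thousand m³, prices in €/m³, surpluses in M€
(thousand m³ × €/m³ = k€, divided by 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import presets


class CalibrationError(ValueError):
    pass


class ShockError(ValueError):
    pass


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class MarketBaseline:
    """Baseline state and elasticities of the round-wood market."""

    consumption: float  # D0, thousand m³
    production: float  # S0, thousand m³
    producer_price: float  # P0, €/m³
    world_price: float  # WP0, €/m³
    demand_elasticity: float  # η < 0
    supply_elasticity: float  # θ > 0
    trade_elasticity: float  # ω > 0
    flow_fraction: float = 0.018  # yearly removals / standing stock

    def __post_init__(self) -> None:
        if min(self.consumption, self.production, self.producer_price,
               self.world_price) <= 0:
            raise ValueError("baseline quantities and prices must be positive")
        if self.demand_elasticity >= 0:
            raise ValueError("demand elasticity must be negative")
        if self.supply_elasticity <= 0 or self.trade_elasticity <= 0:
            raise ValueError("supply and trade elasticities must be positive")
        if not 0.0 < self.flow_fraction < 1.0:
            raise ValueError("flow fraction must be in (0, 1)")

    @classmethod
    def eu_round_wood(cls) -> "MarketBaseline":
        """The published EU conifer industrial round-wood baseline."""
        b = presets.MARKET_BASELINE
        return cls(
            consumption=b["consumption"],
            production=b["production"],
            producer_price=b["producer_price"],
            world_price=b["world_price"],
            demand_elasticity=b["demand_elasticity"],
            supply_elasticity=b["supply_elasticity"],
            trade_elasticity=b["trade_elasticity"],
            flow_fraction=b["flow_fraction"],
        )


@dataclass(frozen=True)
class SupplyShock:
    """Pest-induced supply shift.

    ``x`` is the aggregate proportional supply loss (= z·h); ``nu`` the
    proportional cost increase for affected producers.  The (z, h)
    decomposition is optional and only matters when ``nu > 0``.
    """

    x: float
    nu: float = 0.0
    z: Optional[float] = None
    h: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.x < 1.0:
            raise ShockError("x must be in [0, 1)")
        if not 0.0 <= self.nu < 1.0:
            raise ShockError("nu must be in [0, 1)")
        if (self.z is None) != (self.h is None):
            raise ShockError("z and h must be given together")
        if self.z is not None:
            if not (0.0 <= self.z <= 1.0 and 0.0 <= self.h <= 1.0):
                raise ShockError("z and h must be in [0, 1]")
            if abs(self.z * self.h - self.x) > 1e-9:
                raise ShockError("x must equal z*h")

    def supply_multiplier(self, theta: float) -> float:
        """Multiplier g applied to the unshocked supply curve."""
        if self.nu == 0.0:
            return 1.0 - self.x
        if self.z is None:
            raise ShockError("nu > 0 requires the (z, h) decomposition")
        return (1.0 - self.z) + self.z * (1.0 - self.h) * (1.0 - self.nu) ** theta


@dataclass(frozen=True)
class CalibratedMarket:
    """Curve scale parameters fitted to the baseline."""

    baseline: MarketBaseline
    chi: float  # demand scale
    beta: float  # supply scale
    upsilon: float  # trade scale (sign follows baseline trade direction)
    mu: float  # EU price minus world price, €/m³

    def demand(self, price: float | np.ndarray) -> float | np.ndarray:
        return self.chi * np.power(price, self.baseline.demand_elasticity)

    def supply(
        self, price: float | np.ndarray, shock: Optional[SupplyShock] = None
    ) -> float | np.ndarray:
        g = 1.0 if shock is None else shock.supply_multiplier(
            self.baseline.supply_elasticity
        )
        return g * self.beta * np.power(price, self.baseline.supply_elasticity)

    def net_imports(self, price: float | np.ndarray) -> float | np.ndarray:
        wp = price - self.mu
        return self.upsilon * np.power(wp, self.baseline.trade_elasticity)


@dataclass(frozen=True)
class EquilibriumState:
    price: float  # P, €/m³
    world_price: float  # WP = P − µ
    demand: float  # thousand m³
    supply: float  # domestic, thousand m³
    supply_affected: float
    supply_unaffected: float
    net_trade: float  # X = S − D (negative: net importer)


@dataclass(frozen=True)
class WelfareChange:
    consumer: float  # ΔCS, M€
    producer: float  # ΔPS, M€

    @property
    def total(self) -> float:
        """ΔW = ΔCS + ΔPS, exact by construction."""
        return self.consumer + self.producer


def calibrate(baseline: MarketBaseline) -> CalibratedMarket:
    """Fit scale parameters so each curve reproduces its baseline point.

    χ = D0/P0^η, β = S0/P0^θ, µ = P0 − WP0, and υ = M0/WP0^ω with
    M0 = D0 − S0 the baseline net imports (its sign carries through so the
    trade curve reproduces the baseline trade direction).
    """
    m0 = baseline.consumption - baseline.production
    if m0 == 0:
        raise CalibrationError(
            "baseline consumption equals production: trade curve is degenerate"
        )
    chi = baseline.consumption / baseline.producer_price ** baseline.demand_elasticity
    beta = baseline.production / baseline.producer_price ** baseline.supply_elasticity
    mu = baseline.producer_price - baseline.world_price
    upsilon = m0 / baseline.world_price ** baseline.trade_elasticity
    return CalibratedMarket(baseline=baseline, chi=chi, beta=beta, upsilon=upsilon, mu=mu)


def shock_from_cumulative_loss(
    cumulative_value_meur: float,
    price: float,
    baseline: MarketBaseline,
) -> SupplyShock:
    """Convert a cumulative standing-stock loss into a supply shock.

    The lost stock volume is value/price; the annual flow of round wood lost
    is the flow fraction (yearly removals as a share of standing stock,
    default 1.8%) of that volume; ``x`` is the flow reduction relative to
    baseline production.
    """
    if cumulative_value_meur < 0:
        raise ShockError("cumulative loss must be >= 0")
    if price <= 0:
        raise ValueError("price must be positive")
    lost_volume_thousand_m3 = cumulative_value_meur * 1e6 / price / 1e3
    flow_reduction = baseline.flow_fraction * lost_volume_thousand_m3
    x = flow_reduction / baseline.production
    if x >= 1.0:
        raise ShockError(f"supply shock x={x:.3f} >= 1 exceeds total production")
    return SupplyShock(x=x)


def clearing_residual(
    market: CalibratedMarket, shock: SupplyShock, price: float | np.ndarray
) -> float | np.ndarray:
    """S(P) + M(P) − D(P); the equilibrium price is its root."""
    return (
        market.supply(price, shock) + market.net_imports(price) - market.demand(price)
    )


def solve_equilibrium(
    market: CalibratedMarket,
    shock: SupplyShock,
    bracket: tuple[float, float] | None = None,
    rtol: float = 1e-12,
) -> EquilibriumState:
    """Find the market-clearing price after a supply shock.

    Solves S(P)·g + M(P−µ→WP) = D(P) for P by bracketed root finding on
    [P0/2, 4·P0].  Supply rises and demand falls in P, so the residual is
    strictly increasing and the root unique.  The zero-shock solution is the
    baseline fixed point exactly (by calibration).
    """
    p0 = market.baseline.producer_price
    if shock.x == 0.0 and shock.nu == 0.0:
        # Calibration identity: baseline is the exact fixed point.
        price = p0
    else:
        lo, hi = bracket if bracket is not None else (p0 / 2.0, 4.0 * p0)
        f_lo = clearing_residual(market, shock, lo)
        f_hi = clearing_residual(market, shock, hi)
        if np.sign(f_lo) == np.sign(f_hi):
            raise SolverError(
                f"no sign change in bracket [{lo:.3g}, {hi:.3g}]: "
                f"residuals ({f_lo:.6g}, {f_hi:.6g})"
            )
        price = brentq(
            lambda p: clearing_residual(market, shock, p), lo, hi, rtol=rtol
        )

    theta = market.baseline.supply_elasticity
    g = shock.supply_multiplier(theta)
    supply = market.supply(price, shock)
    if shock.z is not None:
        sn = (1.0 - shock.z) * market.beta * price ** theta
        sa = supply - sn
    else:
        # Aggregate parameterization: attribute the whole shift to one pool.
        sn = (1.0 - shock.x) * market.beta * price ** theta
        sa = supply - sn
    demand = market.demand(price)
    return EquilibriumState(
        price=float(price),
        world_price=float(price - market.mu),
        demand=float(demand),
        supply=float(supply),
        supply_affected=float(sa),
        supply_unaffected=float(sn),
        net_trade=float(supply - demand),
    )


def consumer_surplus_change(
    market: CalibratedMarket, price_before: float, price_after: float
) -> float:
    """ΔCS in M€ between two prices: −∫ χ p^η dp over [before, after].

    Negative when the price rises.  The absolute consumer-surplus integral
    diverges for |η| < 1, so only changes between two prices are defined.
    """
    if price_before <= 0 or price_after <= 0:
        raise ValueError("prices must be positive")
    eta = market.baseline.demand_elasticity
    if eta == -1.0:
        integral = market.chi * np.log(price_after / price_before)
    else:
        integral = market.chi * (
            price_after ** (1.0 + eta) - price_before ** (1.0 + eta)
        ) / (1.0 + eta)
    return -integral / 1e3  # k€ -> M€


def producer_surplus_change(
    market: CalibratedMarket,
    supply_after: float,
    price_after: float,
) -> float:
    """ΔPS in M€ from the baseline to a post-shock state.

    For a constant-elasticity supply curve through (P, S) the producer
    surplus is S·P/(1+θ); the change is evaluated on the shifted curve at
    the new equilibrium against the baseline curve at the baseline point.
    """
    b = market.baseline
    theta = b.supply_elasticity
    ps_after = supply_after * price_after / (1.0 + theta)
    ps_before = b.production * b.producer_price / (1.0 + theta)
    return (ps_after - ps_before) / 1e3  # k€ -> M€


def welfare_change(delta_cs: float, delta_ps: float) -> WelfareChange:
    return WelfareChange(consumer=delta_cs, producer=delta_ps)


def welfare_from_shock(
    market: CalibratedMarket, shock: SupplyShock
) -> tuple[EquilibriumState, WelfareChange]:
    """Solve the post-shock equilibrium and measure the welfare change."""
    state = solve_equilibrium(market, shock)
    dcs = consumer_surplus_change(
        market, market.baseline.producer_price, state.price
    )
    dps = producer_surplus_change(market, state.supply, state.price)
    return state, welfare_change(dcs, dps)


def welfare_from_observed_changes(
    baseline: MarketBaseline, price_change: float, supply_change: float
) -> WelfareChange:
    """Welfare change implied by observed equilibrium price and supply
    changes (price change in €/m³, supply change in thousand m³).

    Used to evaluate the surplus formulas at reported post-shock states
    without re-deriving the shock itself.
    """
    market = calibrate(baseline)
    p_after = baseline.producer_price + price_change
    s_after = baseline.production + supply_change
    dcs = consumer_surplus_change(market, baseline.producer_price, p_after)
    dps = producer_surplus_change(market, s_after, p_after)
    return welfare_change(dcs, dps)


def annual_welfare_series(
    impact: pd.DataFrame,
    market: CalibratedMarket,
    price: float,
) -> pd.DataFrame:
    """Welfare change per year driven by the cumulative direct-loss series.

    For each year the cumulative lost stock value (column
    ``cumulative_eur``) is converted to a supply shock via the yearly-flow
    rule, the equilibrium re-solved, and the welfare change recorded.
    Because the cumulative series is non-decreasing, so is |ΔW|.
    """
    if (np.diff(impact["cumulative_eur"]) < -1e-6).any():
        raise ValueError("cumulative impact series must be non-decreasing")
    rows = []
    for _, row in impact.iterrows():
        shock = shock_from_cumulative_loss(
            row["cumulative_eur"] / 1e6, price, market.baseline
        )
        state, welfare = welfare_from_shock(market, shock)
        rows.append(
            {
                "year": int(row["year"]),
                "x": shock.x,
                "price": state.price,
                "supply": state.supply,
                "demand": state.demand,
                "net_trade": state.net_trade,
                "consumer_surplus_meur": welfare.consumer,
                "producer_surplus_meur": welfare.producer,
                "total_welfare_meur": welfare.total,
            }
        )
    return pd.DataFrame(rows)


def equilibrium_change_table(
    market: CalibratedMarket, shock: SupplyShock
) -> pd.DataFrame:
    """Absolute and percentage changes between the baseline and post-shock
    equilibria (supply, demand, price, net trade, CS, PS, total welfare).

    Quantity changes in million m³, price in €/m³, surpluses in M€.
    Percentage changes are relative to the baseline level; for the
    surpluses the base is the baseline surplus level, and for net trade the
    baseline net trade volume.
    """
    b = market.baseline
    state, welfare = welfare_from_shock(market, shock)
    base_trade = b.production - b.consumption
    theta = b.supply_elasticity
    ps0 = b.production * b.producer_price / (1.0 + theta) / 1e3
    # The absolute CS level diverges for |η| < 1, so percentage changes on
    # the consumer side are reported against baseline consumer expenditure.
    cs_base_scale = b.consumption * b.producer_price / 1e3
    rows = [
        ("supply_million_m3", (state.supply - b.production) / 1e3,
         100.0 * (state.supply - b.production) / b.production),
        ("demand_million_m3", (state.demand - b.consumption) / 1e3,
         100.0 * (state.demand - b.consumption) / b.consumption),
        ("price_eur_m3", state.price - b.producer_price,
         100.0 * (state.price - b.producer_price) / b.producer_price),
        ("net_trade_million_m3", (state.net_trade - base_trade) / 1e3,
         100.0 * (state.net_trade - base_trade) / abs(base_trade)),
        ("consumer_surplus_meur", welfare.consumer,
         100.0 * welfare.consumer / cs_base_scale),
        ("producer_surplus_meur", welfare.producer, 100.0 * welfare.producer / ps0),
        ("total_welfare_meur", welfare.total,
         100.0 * welfare.total / (ps0 + cs_base_scale)),
    ]
    return pd.DataFrame(rows, columns=["quantity", "absolute_change", "percent_change"])
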