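"""Partial-budget computation of direct economic losses.

The direct impact of the invasion in a polygon (a region at coarse
resolution, a 1 km² cell at fine resolution) is the market value of the
standing stock killed by pine wilt disease:

    L_i = p * sum_jk  e_i * m_jk * s_ijk

where ``e_i`` is the exposed fraction of the polygon (``r_i * d_i`` at
coarse resolution — infested proportion times the 0/1 temperature
indicator — or the qualifying-cell fraction at fine resolution), ``m_jk``
the mortality rate for age class j and susceptibility class k, ``s_ijk``
the standing stock in that class (m³) and ``p`` the round-wood price
(€/m³).  Diseased trees are a total loss; surviving trees retain full
value; no discounting and no stock regrowth over the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import presets
from .layers import DEFAULT_THRESHOLD, region_exposures
from .synthetic_data import OccupancySeries, VULNERABILITY_CLASSES, World


@dataclass(frozen=True)
class MortalityTable:
    """Mortality fraction per (age class, susceptibility class)."""

    rates: Mapping[tuple[str, str], float]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = set(VULNERABILITY_CLASSES) - set(self.rates)
        if missing:
            raise ValueError(f"mortality table missing classes: {sorted(missing)}")
        for cls, m in self.rates.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"mortality for {cls} must be in [0, 1], got {m}")

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.rates[key]

    @classmethod
    def preset(cls, name: str) -> "MortalityTable":
        table = {
            "default": presets.MORTALITY_DEFAULT,
            "minimum": presets.MORTALITY_MINIMUM,
            "maximum": presets.MORTALITY_MAXIMUM,
        }
        if name not in table:
            raise KeyError(f"unknown mortality preset {name!r}")
        return cls(rates=dict(table[name]), name=name)


def _mortality_weighted_stock(
    stock_by_class: Mapping[tuple[str, str], float], mortality: MortalityTable
) -> float:
    """sum_jk m_jk * s_jk, validating non-negative stock."""
    total = 0.0
    for cls in VULNERABILITY_CLASSES:
        s = float(stock_by_class.get(cls, 0.0))
        if s < 0:
            raise ValueError(f"negative stock for class {cls}")
        total += mortality[cls] * s
    return total


def direct_impact_polygon(
    exposed_fraction: float,
    stock_by_class: Mapping[tuple[str, str], float],
    mortality: MortalityTable,
    price: float,
) -> tuple[float, float]:
    """Direct loss for one polygon.

    Parameters
    ----------
    exposed_fraction
        ``r * d`` at coarse resolution or the qualifying-cell fraction at
        fine resolution; in [0, 1].
    stock_by_class
        Standing stock (m³) keyed by (age class, susceptibility class).
    mortality
        Mortality-rate table.
    price
        Round-wood price, €/m³; must be positive.

    Returns
    -------
    (value, volume)
        Lost value in € and lost volume in m³.
    """
    if price <= 0:
        raise ValueError("price must be positive")
    if not 0.0 <= exposed_fraction <= 1.0:
        raise ValueError("exposed fraction must be in [0, 1]")
    volume = exposed_fraction * _mortality_weighted_stock(stock_by_class, mortality)
    return price * volume, volume


def regional_impacts(
    world: World,
    exposures: pd.DataFrame,
    mortality: MortalityTable,
    price: float,
    resolution: str = "coarse",
) -> pd.DataFrame:
    """Direct-impact table with one row per region.

    At coarse resolution the exposed fraction is ``r * d`` (regional mean
    temperature gates the whole region); at fine resolution it is the
    qualifying-cell fraction.  Columns: ``proportion_infested``,
    ``exposed_fraction``, ``value_eur``, ``volume_m3``,
    ``value_per_qualifying_km2`` (NaN where no cell qualifies).
    """
    if resolution not in ("coarse", "fine"):
        raise ValueError("resolution must be 'coarse' or 'fine'")
    stock_matrix = world.stock_matrix()
    rows = []
    for rid, exp in exposures.iterrows():
        if resolution == "coarse":
            fraction = exp["proportion_infested"] * exp["pwd_indicator"]
        else:
            fraction = exp["qualifying_fraction"]
        stock_by_class = (
            stock_matrix.loc[rid].to_dict() if rid in stock_matrix.index else {}
        )
        value, volume = direct_impact_polygon(fraction, stock_by_class, mortality, price)
        qual_area = exp["qualifying_area_km2"]
        rows.append(
            {
                "region_id": rid,
                "proportion_infested": exp["proportion_infested"],
                "exposed_fraction": fraction,
                "value_eur": value,
                "volume_m3": volume,
                "value_per_qualifying_km2": value / qual_area if qual_area > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("region_id")


def total_impact(values: Iterable[float]) -> float:
    """Sum of regional direct-impact values (any consistent unit)."""
    return float(np.sum(np.fromiter((float(v) for v in values), dtype=float)))


def impact_series(
    series: OccupancySeries,
    world: World,
    mortality: MortalityTable,
    price: float,
    threshold: float = DEFAULT_THRESHOLD,
    resolution: str = "coarse",
) -> pd.DataFrame:
    """Cumulative and marginal direct-loss series over an occupancy series.

    The exposure is recomputed for every year from that year's occupancy
    grid; the cumulative impact at year t applies the partial-budget
    formula to year-t exposure.  The marginal impact is the first
    difference, with the entry-year marginal equal to the entry-year
    cumulative.  Occupancy monotonicity (and hence a non-decreasing
    cumulative series) is enforced.
    """
    if not series.is_monotone():
        raise ValueError("occupancy series is not monotone in time")
    cumulative = []
    for t in range(len(series.years)):
        exposures = region_exposures(world, series.grids[t], threshold)
        impacts = regional_impacts(world, exposures, mortality, price, resolution)
        cumulative.append(total_impact(impacts["value_eur"]))
    cumulative = np.asarray(cumulative)
    marginal = np.diff(cumulative, prepend=0.0)
    return pd.DataFrame(
        {"year": series.years, "cumulative_eur": cumulative, "marginal_eur": marginal}
    )


def scale_by_price(total: float, new_price: float, old_price: float) -> float:
    """Rescale a direct-impact total to a different round-wood price.

    Direct losses are proportional to price, so a price change rescales the
    total by the price ratio.
    """
    if new_price <= 0 or old_price <= 0:
        raise ValueError("prices must be positive")
    return total * new_price / old_price


def fraction_of_asset_value(
    total_meur: float,
    stock_million_m3: float = presets.SUSCEPTIBLE_STOCK_MILLION_M3,
    price: float = presets.MARKET_BASELINE["producer_price"],
) -> float:
    """Direct-impact total as a percentage of the value of the susceptible
    standing stock (stock in million m³ × price €/m³ gives M€)."""
    asset_value_meur = stock_million_m3 * price
    return 100.0 * total_meur / asset_value_meur
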