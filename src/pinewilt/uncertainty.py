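"""Uncertainty analyses on the direct-impact assessment.

Three analyses, all at coarse (region-level) resolution:

* **single-parameter sweeps** — vary one of spread percentile, temperature
  threshold, mortality preset or round-wood price while holding the rest at
  the base scenario;
* **multi-parameter extremes** — a worst case (95th-percentile spread, low
  threshold, maximum mortality, high price) and a best case (5th-percentile
  spread, high threshold, minimum mortality, low price), reported per
  region in absolute terms and relative to the regional asset value;
* **data-layer removal** — recompute impacts with the temperature
  constraint dropped (disease expressed wherever the pest is present) or
  the spread constraint dropped (pest present wherever the climate
  permits); either relaxation can only enlarge the impact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import presets
from .layers import region_exposures
from .partial_budget import MortalityTable, regional_impacts, total_impact
from .synthetic_data import SpreadReplicateSet, World, select_percentile_replicate


@dataclass(frozen=True)
class ScenarioSpec:
    """One complete parameter setting for the direct-impact computation."""

    spread_percentile: float = 50.0
    threshold: float = 20.0
    mortality_preset: str = "default"
    price: float = presets.MARKET_BASELINE["producer_price"]
    use_temperature: bool = True
    use_spread: bool = True

    def __post_init__(self) -> None:
        if self.price <= 0:
            raise ValueError("price must be positive")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


def scenario_regional_impacts(
    world: World,
    replicates: SpreadReplicateSet,
    spec: ScenarioSpec,
) -> pd.DataFrame:
    """Coarse-resolution regional impact table for one scenario.

    Layer-removal flags relax the corresponding constraint: with
    ``use_temperature=False`` the 0/1 indicator is forced to 1 everywhere;
    with ``use_spread=False`` the infested proportion is forced to 1
    everywhere.
    """
    series = select_percentile_replicate(replicates, spec.spread_percentile)
    exposures = region_exposures(world, series.final, spec.threshold)
    if not spec.use_temperature:
        exposures = exposures.assign(pwd_indicator=1)
    if not spec.use_spread:
        exposures = exposures.assign(proportion_infested=1.0)
    mortality = MortalityTable.preset(spec.mortality_preset)
    return regional_impacts(world, exposures, mortality, spec.price, resolution="coarse")


def scenario_total(
    world: World, replicates: SpreadReplicateSet, spec: ScenarioSpec
) -> float:
    """Total coarse-resolution direct impact (€) for one scenario."""
    return total_impact(
        scenario_regional_impacts(world, replicates, spec)["value_eur"]
    )


@dataclass(frozen=True)
class SweepResult:
    parameter: str
    settings: tuple
    impacts_eur: tuple  # one impact per setting

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameter,
                "setting": [str(s) for s in self.settings],
                "impact_meur": [v / 1e6 for v in self.impacts_eur],
            }
        )


_SWEEP_FIELD = {
    "spread": "spread_percentile",
    "threshold": "threshold",
    "mortality": "mortality_preset",
    "price": "price",
}


def run_single_parameter(
    world: World,
    replicates: SpreadReplicateSet,
    base_spec: ScenarioSpec,
    parameter: str,
    settings: list,
) -> SweepResult:
    """Vary one parameter over ``settings``, holding all others at the base
    scenario; returns one total impact per setting."""
    if parameter not in _SWEEP_FIELD:
        raise ValueError(
            f"unknown sweep parameter {parameter!r}; expected one of "
            f"{sorted(_SWEEP_FIELD)}"
        )
    field_name = _SWEEP_FIELD[parameter]
    impacts = tuple(
        scenario_total(world, replicates, replace(base_spec, **{field_name: s}))
        for s in settings
    )
    return SweepResult(parameter=parameter, settings=tuple(settings), impacts_eur=impacts)


def default_sweeps(
    world: World,
    replicates: SpreadReplicateSet,
    base_spec: ScenarioSpec,
    price_range: tuple[float, float] = presets.PRICE_RANGE_TABLE,
) -> pd.DataFrame:
    """The four standard single-parameter sweeps, stacked into one table."""
    sweeps = [
        run_single_parameter(world, replicates, base_spec, "spread", [5.0, 50.0, 95.0]),
        run_single_parameter(world, replicates, base_spec, "threshold", [18.0, 19.0, 20.0]),
        run_single_parameter(
            world, replicates, base_spec, "mortality", ["minimum", "default", "maximum"]
        ),
        run_single_parameter(world, replicates, base_spec, "price", list(price_range)),
    ]
    return pd.concat([s.as_frame() for s in sweeps], ignore_index=True)


def run_extreme_cases(
    world: World,
    replicates: SpreadReplicateSet,
    base_spec: ScenarioSpec,
    price_range: tuple[float, float] = presets.PRICE_RANGE_TABLE,
) -> tuple[float, float, pd.DataFrame]:
    """Worst-case and best-case impacts with a per-region breakdown.

    Worst: 95th-percentile spread, 18 °C threshold, maximum mortality,
    highest price.  Best: 5th-percentile spread, 20 °C threshold, minimum
    mortality, lowest price.  The per-region table reports each case in M€
    and as a percentage of the regional asset value (regional stock valued
    at that case's price, so the percentage reflects exposure and
    mortality), plus the worst-minus-best percentage-point difference.
    """
    low_price, high_price = sorted(price_range)
    worst_spec = replace(
        base_spec,
        spread_percentile=95.0,
        threshold=18.0,
        mortality_preset="maximum",
        price=high_price,
    )
    best_spec = replace(
        base_spec,
        spread_percentile=5.0,
        threshold=20.0,
        mortality_preset="minimum",
        price=low_price,
    )
    worst = scenario_regional_impacts(world, replicates, worst_spec)
    best = scenario_regional_impacts(world, replicates, best_spec)

    stock_totals = world.stock.groupby("region_id")["stock_m3"].sum()
    table = pd.DataFrame(index=worst.index)
    table["worst_meur"] = worst["value_eur"] / 1e6
    table["best_meur"] = best["value_eur"] / 1e6
    worst_asset = stock_totals.reindex(table.index) * worst_spec.price
    best_asset = stock_totals.reindex(table.index) * best_spec.price
    table["worst_pct"] = 100.0 * worst["value_eur"] / worst_asset
    table["best_pct"] = 100.0 * best["value_eur"] / best_asset
    table["difference_pct"] = table["worst_pct"] - table["best_pct"]
    return (
        total_impact(worst["value_eur"]),
        total_impact(best["value_eur"]),
        table,
    )


def run_layer_removal(
    world: World,
    replicates: SpreadReplicateSet,
    base_spec: ScenarioSpec,
    mode: str,
) -> float:
    """Total impact (€) with one data layer's constraint removed.

    ``no_temperature``: disease expressed wherever the pest is present.
    ``no_spread``: pest assumed present wherever the temperature permits.
    """
    if mode == "no_temperature":
        spec = replace(base_spec, use_temperature=False)
    elif mode == "no_spread":
        spec = replace(base_spec, use_spread=False)
    else:
        raise ValueError(f"unknown layer-removal mode {mode!r}")
    return scenario_total(world, replicates, spec)
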