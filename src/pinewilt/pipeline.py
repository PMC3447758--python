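"""End-to-end run configuration and orchestration.

Ties the modules together: generate the synthetic world, simulate spread
replicates, integrate the layers at both resolutions, compute the
partial-budget impact series, solve the market model year by year, and run
the uncertainty analyses.  All table outputs are written twice: rounded for
reading (M€ to the nearest million) and raw at full precision
(``*_raw.csv``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io, presets
from .layers import region_exposures
from .market import (
    MarketBaseline,
    annual_welfare_series,
    calibrate,
    equilibrium_change_table,
    shock_from_cumulative_loss,
)
from .partial_budget import MortalityTable, impact_series, regional_impacts
from .synthetic_data import (
    DEFAULT_CLASS_MIX,
    GridSpec,
    SyntheticWorldConfig,
    World,
    generate_world,
    select_percentile_replicate,
    simulate_spread,
)
from .uncertainty import ScenarioSpec, default_sweeps, run_extreme_cases, run_layer_removal

log = logging.getLogger("pinewilt")


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending key."""


@dataclass(frozen=True)
class SpreadParams:
    growth_radius: int = 1
    growth_prob: float = 0.3
    jump_rate: float = 0.05
    n_replicates: int = 200


@dataclass
class RunConfig:
    world: SyntheticWorldConfig
    spread: SpreadParams = field(default_factory=SpreadParams)
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    baseline: MarketBaseline = field(default_factory=MarketBaseline.eu_round_wood)
    start_year: int = 2008
    end_year: int = 2030
    resolution: str = "both"  # coarse | fine | both
    seed: int = 0
    price_range: tuple[float, float] = presets.PRICE_RANGE_TABLE

    def __post_init__(self) -> None:
        if self.start_year >= self.end_year:
            raise ConfigError("years: start_year must be < end_year")
        if self.resolution not in ("coarse", "fine", "both"):
            raise ConfigError(f"resolution: unknown value {self.resolution!r}")


def _take(section: Mapping[str, Any], key: str, default: Any) -> Any:
    return section.get(key, default) if section else default


def config_from_dict(raw: Mapping[str, Any]) -> RunConfig:
    """Build a RunConfig from a flat YAML-style mapping.

    Raises :class:`ConfigError` naming the offending key on invalid input.
    """
    try:
        w = raw.get("world", {}) or {}
        grid = GridSpec(
            n_rows=int(_take(w, "n_rows", 100)),
            n_cols=int(_take(w, "n_cols", 100)),
            cell_area=float(_take(w, "cell_area", 1.0)),
            coarse_block=int(_take(w, "coarse_block", 5)),
        )
        seed = int(raw.get("seed", 0))
        world_cfg = SyntheticWorldConfig(
            grid=grid,
            n_regions=int(_take(w, "n_regions", 20)),
            temperature_base=float(_take(w, "temperature_base", 15.8)),
            temperature_south_north_gradient=float(_take(w, "temperature_gradient", 0.12)),
            temperature_noise_sd=float(_take(w, "temperature_noise_sd", 0.4)),
            stock_total_target=float(_take(w, "stock_total_target", 2.46e10)),
            class_mix=tuple(_take(w, "class_mix", DEFAULT_CLASS_MIX)),
            entry_cell=tuple(_take(w, "entry_cell", (grid.coarse_shape[0] - 1, 1))),
            seed=seed,
        )
        sp = raw.get("spread", {}) or {}
        spread = SpreadParams(
            growth_radius=int(_take(sp, "growth_radius", 1)),
            growth_prob=float(_take(sp, "growth_prob", 0.3)),
            jump_rate=float(_take(sp, "jump_rate", 0.05)),
            n_replicates=int(_take(sp, "n_replicates", 200)),
        )
        sc = raw.get("scenario", {}) or {}
        scenario = ScenarioSpec(
            spread_percentile=float(_take(sc, "spread_percentile", 50.0)),
            threshold=float(_take(sc, "threshold", 20.0)),
            mortality_preset=str(_take(sc, "mortality_preset", "default")),
            price=float(_take(sc, "price", presets.MARKET_BASELINE["producer_price"])),
        )
        MortalityTable.preset(scenario.mortality_preset)  # fail fast on bad name
        years = raw.get("years", {}) or {}
        return RunConfig(
            world=world_cfg,
            spread=spread,
            scenario=scenario,
            start_year=int(_take(years, "start", 2008)),
            end_year=int(_take(years, "end", 2030)),
            resolution=str(raw.get("resolution", "both")),
            seed=seed,
            price_range=tuple(raw.get("price_range", presets.PRICE_RANGE_TABLE)),
        )
    except (ValueError, KeyError, TypeError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(raw)


def _round_meur(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        out[c] = out[c].round(0).astype("Int64")
    return out


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute the full assessment and write all output files.

    Returns a mapping of logical output names to written paths.  The run is
    deterministic given ``config.seed``.
    """
    outdir = Path(outdir)
    (outdir / "grids").mkdir(parents=True, exist_ok=True)
    log.info("run seed=%d resolution=%s", config.seed, config.resolution)

    world = generate_world(config.world)
    n_years = config.end_year - config.start_year
    replicates = simulate_spread(
        world,
        entry_cell=config.world.entry_cell,
        years=n_years,
        growth_radius=config.spread.growth_radius,
        jump_rate=config.spread.jump_rate,
        growth_prob=config.spread.growth_prob,
        n_replicates=config.spread.n_replicates,
        seed=config.seed + 1,
        start_year=config.start_year,
    )
    series = select_percentile_replicate(replicates, config.scenario.spread_percentile)

    paths: dict[str, Path] = {}

    def save(name: str, path: Path) -> Path:
        paths[name] = path
        return path

    io.write_esri_ascii(
        save("temperature", outdir / "grids" / "temperature.asc"),
        world.temperature, cellsize=config.world.grid.cell_area,
    )
    io.write_esri_ascii(
        save("region_map", outdir / "grids" / "region_map.asc"),
        world.region_map, cellsize=config.world.grid.cell_area, fmt="%d",
    )
    io.write_esri_ascii(
        save("occupancy_final", outdir / "grids" / "occupancy_final.asc"),
        series.final, fmt="%d",
    )
    io.write_stock_csv(save("stock", outdir / "stock.csv"), world.stock)

    threshold = config.scenario.threshold
    price = config.scenario.price
    mortality = MortalityTable.preset(config.scenario.mortality_preset)
    exposures = region_exposures(world, series.final, threshold)
    io.write_exposures_csv(save("exposures", outdir / "exposures.csv"), exposures)

    # Regional direct impacts at the requested resolution(s).
    resolutions = (
        ("coarse", "fine") if config.resolution == "both" else (config.resolution,)
    )
    table2 = pd.DataFrame(index=exposures.index)
    for res in resolutions:
        imp = regional_impacts(world, exposures, mortality, price, resolution=res)
        table2[f"{res}_proportion_infested_pct"] = 100.0 * imp["proportion_infested"]
        table2[f"{res}_impact_meur"] = imp["value_eur"] / 1e6
        table2[f"{res}_impact_eur_per_km2"] = imp["value_per_qualifying_km2"]
    table2.to_csv(save("table2_raw", outdir / "table2_raw.csv"))
    _round_meur(
        table2, [c for c in table2.columns if c.endswith("_meur")]
    ).to_csv(save("table2", outdir / "table2.csv"))

    # Impact series and market model at the primary resolution.
    primary_res = "fine" if config.resolution in ("fine", "both") else "coarse"
    impacts = impact_series(
        series, world, mortality, price, threshold, resolution=primary_res
    )
    impacts_meur = impacts.assign(
        cumulative_meur=impacts["cumulative_eur"] / 1e6,
        marginal_meur=impacts["marginal_eur"] / 1e6,
    )[["year", "cumulative_meur", "marginal_meur"]]
    impacts_meur.to_csv(save("impact_series_raw", outdir / "impact_series_raw.csv"),
                        index=False)
    _round_meur(impacts_meur, ["cumulative_meur", "marginal_meur"]).to_csv(
        save("impact_series", outdir / "impact_series.csv"), index=False
    )

    market = calibrate(config.baseline)
    welfare = annual_welfare_series(impacts, market, price)
    welfare.to_csv(save("welfare_series_raw", outdir / "welfare_series_raw.csv"),
                   index=False)
    rounded = welfare.copy()
    for c in ("consumer_surplus_meur", "producer_surplus_meur", "total_welfare_meur"):
        rounded[c] = rounded[c].round(1)
    rounded.to_csv(save("welfare_series", outdir / "welfare_series.csv"), index=False)

    final_shock = shock_from_cumulative_loss(
        impacts["cumulative_eur"].iloc[-1] / 1e6, price, config.baseline
    )
    table3 = equilibrium_change_table(market, final_shock)
    table3.to_csv(save("table3_raw", outdir / "table3_raw.csv"), index=False)
    table3.round(3).to_csv(save("table3", outdir / "table3.csv"), index=False)

    # Uncertainty analyses (coarse resolution).
    table4 = default_sweeps(world, replicates, config.scenario, config.price_range)
    table4.to_csv(save("table4_raw", outdir / "table4_raw.csv"), index=False)
    _round_meur(table4, ["impact_meur"]).to_csv(
        save("table4", outdir / "table4.csv"), index=False
    )

    worst, best, table5 = run_extreme_cases(
        world, replicates, config.scenario, config.price_range
    )
    table5.to_csv(save("table5_raw", outdir / "table5_raw.csv"))
    t5r = table5.copy()
    t5r[["worst_meur", "best_meur"]] = t5r[["worst_meur", "best_meur"]].round(0)
    t5r[["worst_pct", "best_pct", "difference_pct"]] = t5r[
        ["worst_pct", "best_pct", "difference_pct"]
    ].round(1)
    t5r.to_csv(save("table5", outdir / "table5.csv"))

    removal = pd.DataFrame(
        {
            "mode": ["constrained", "no_temperature", "no_spread"],
            "impact_meur": [
                table4.loc[
                    (table4["parameter"] == "spread") & (table4["setting"] == "50.0"),
                    "impact_meur",
                ].iloc[0],
                run_layer_removal(world, replicates, config.scenario, "no_temperature") / 1e6,
                run_layer_removal(world, replicates, config.scenario, "no_spread") / 1e6,
            ],
        }
    )
    removal.to_csv(save("layer_removal", outdir / "layer_removal.csv"), index=False)

    log.info(
        "direct impact %.0f M€ (%s), worst %.0f best %.0f, welfare %.1f M€ final year",
        impacts["cumulative_eur"].iloc[-1] / 1e6, primary_res,
        worst / 1e6, best / 1e6, welfare["total_welfare_meur"].iloc[-1],
    )
    return paths
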