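"""Spatial integration of the spread, climate and host data layers.

Two resolutions are supported:

* **coarse** — region level: temperature is averaged over the region's fine
  cells, the infested proportion ``r`` is the fraction of coarse spread
  cells occupied, and a 0/1 indicator ``d`` says whether the regional mean
  summer temperature exceeds the wilt-expression threshold.  The product
  ``r * d`` scales the regional assets at risk.
* **fine** — cell level: a fine cell *qualifies* when its parent coarse
  spread cell is occupied and its own temperature exceeds the threshold;
  the regional assets at risk are scaled by the fraction of qualifying
  cells, and regional losses are spread uniformly over those cells.

Averaging temperature over a large region can flip the indicator relative
to the cell-level decision, which is exactly the coarse/fine discrepancy
the two pipelines are designed to expose.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic_data import GridSpec, World

DEFAULT_THRESHOLD = 20.0  # °C mean July–August temperature for PWD expression


class DimensionError(ValueError):
    """Raised when grids are not congruent with each other or the blocking."""


def expand_coarse(occupancy_coarse: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Replicate a coarse grid to fine resolution (presence in a coarse cell
    implies presence in every fine cell within it)."""
    occ = np.asarray(occupancy_coarse)
    if occ.shape != grid.coarse_shape:
        raise DimensionError(
            f"coarse grid {occ.shape} does not match coarse shape {grid.coarse_shape}"
        )
    return np.kron(occ, np.ones((grid.coarse_block, grid.coarse_block), dtype=occ.dtype))


def _check_fine(arr: np.ndarray, grid: GridSpec, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.shape != grid.fine_shape:
        raise DimensionError(f"{name} shape {arr.shape} != fine shape {grid.fine_shape}")
    return arr


def upscale_temperature(
    temp_fine: np.ndarray, region_map: np.ndarray
) -> pd.Series:
    """Mean temperature per region (arithmetic mean over the region's fine
    cells)."""
    temp_fine = np.asarray(temp_fine, dtype=float)
    region_map = np.asarray(region_map)
    if temp_fine.shape != region_map.shape:
        raise DimensionError("temperature grid and region map shapes differ")
    flat_regions = region_map.ravel()
    sums = np.bincount(flat_regions, weights=temp_fine.ravel())
    counts = np.bincount(flat_regions)
    present = counts > 0
    means = pd.Series(
        sums[present] / counts[present],
        index=np.flatnonzero(present),
        name="mean_summer_temp",
    )
    means.index.name = "region_id"
    return means


def upscale_spread(
    occupancy_coarse: np.ndarray, region_map: np.ndarray, grid: GridSpec
) -> pd.Series:
    """Proportion of infested spread-model cells per region.

    Computed as the area fraction of the region covered by occupied coarse
    cells, which equals the occupied-cell count over total coarse cells
    whenever region boundaries align with the coarse blocking.
    """
    fine_occ = expand_coarse(np.asarray(occupancy_coarse, dtype=float), grid)
    region_map = _check_fine(region_map, grid, "region map")
    flat = region_map.ravel()
    occupied = np.bincount(flat, weights=fine_occ.ravel())
    counts = np.bincount(flat)
    present = counts > 0
    r = pd.Series(
        occupied[present] / counts[present],
        index=np.flatnonzero(present),
        name="proportion_infested",
    )
    r.index.name = "region_id"
    return r


def pwd_indicator(mean_temp: float, threshold: float = DEFAULT_THRESHOLD) -> int:
    """1 if the mean summer temperature is strictly above the wilt-expression
    threshold, else 0.  Equality means no disease expression."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return int(mean_temp > threshold)


def qualifying_cells(
    occupancy_coarse: np.ndarray,
    temp_fine: np.ndarray,
    grid: GridSpec,
    threshold: float = DEFAULT_THRESHOLD,
) -> np.ndarray:
    """Fine boolean grid of cells that are both infested (parent coarse cell
    occupied) and warm enough for disease expression (strict inequality)."""
    fine_occ = expand_coarse(np.asarray(occupancy_coarse, dtype=bool), grid)
    temp_fine = _check_fine(np.asarray(temp_fine, dtype=float), grid, "temperature")
    return fine_occ & (temp_fine > threshold)


def downscale_impact(
    region_impact_value: float, qualifying_mask: np.ndarray
) -> np.ndarray:
    """Distribute a regional impact value uniformly over its qualifying fine
    cells (homogeneous production value within the region).

    The cell values sum to the regional value exactly: any floating-point
    remainder is assigned to the first qualifying cell in row-major order.
    """
    if region_impact_value < 0:
        raise ValueError("region impact must be >= 0")
    mask = np.asarray(qualifying_mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=float)
    n = int(mask.sum())
    if n == 0:
        if region_impact_value > 0:
            raise ValueError(
                "positive regional impact with no qualifying cell violates "
                "the integration invariant (impact must be 0 there)"
            )
        return out
    share = region_impact_value / n
    out[mask] = share
    first = np.flatnonzero(mask.ravel())[0]
    out.ravel()[first] += region_impact_value - share * n
    return out


def region_exposures(
    world: World,
    occupancy_coarse: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Per-region exposure table combining all three layers.

    Columns: ``proportion_infested`` (r), ``mean_summer_temp``,
    ``pwd_indicator`` (d, from the regional mean), ``qualifying_fraction``
    (fraction of fine cells infested *and* warm), ``n_cells``,
    ``n_qualifying``, ``area_km2``.
    """
    grid = world.grid
    r = upscale_spread(occupancy_coarse, world.region_map, grid)
    mean_temp = upscale_temperature(world.temperature, world.region_map)
    qmask = qualifying_cells(occupancy_coarse, world.temperature, grid, threshold)

    flat = world.region_map.ravel()
    n_cells = np.bincount(flat)
    n_qual = np.bincount(flat, weights=qmask.ravel().astype(float))
    present = np.flatnonzero(n_cells > 0)

    df = pd.DataFrame(
        {
            "proportion_infested": r.reindex(present).to_numpy(),
            "mean_summer_temp": mean_temp.reindex(present).to_numpy(),
            "n_cells": n_cells[present],
            "n_qualifying": n_qual[present].astype(int),
        },
        index=pd.Index(present, name="region_id"),
    )
    df["pwd_indicator"] = (df["mean_summer_temp"] > threshold).astype(int)
    df["qualifying_fraction"] = df["n_qualifying"] / df["n_cells"]
    df["area_km2"] = df["n_cells"] * grid.cell_area
    df["qualifying_area_km2"] = df["n_qualifying"] * grid.cell_area
    return df
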