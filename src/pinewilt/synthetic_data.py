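"""Synthetic spread, climate, host and region layers.

The assessment pipeline consumes three spatial data layers: a
presence/absence grid of the invading nematode at the coarse resolution of
the spread model, a fine-resolution mean summer temperature grid, and a
table of conifer standing stock per administrative region split into six
vulnerability classes (two age classes crossed with three susceptibility
levels).  This module generates all three with the statistical structure
the downstream analysis assumes, so the whole pipeline is testable without
any external download.

Conventions
-----------
* Fine cells are indexed ``(row, col)``, 0-based; row 0 is the
  northernmost row.  A fine cell's parent coarse cell is
  ``(row // coarse_block, col // coarse_block)``.
* Occupancy grids live at the coarse resolution; temperature and region
  maps live at the fine resolution.
* All randomness is driven by explicit integer seeds; the same seed yields
  a bit-identical world or replicate set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

AGE_CLASSES = ("young", "old")  # <=20 yr, >20 yr
SUSCEPTIBILITY_CLASSES = ("susceptible", "intermediate", "resistant")

#: (age, susceptibility) pairs in canonical order; matches class_mix order.
VULNERABILITY_CLASSES = tuple(
    (age, susc) for age in AGE_CLASSES for susc in SUSCEPTIBILITY_CLASSES
)


class ConfigurationError(ValueError):
    """Raised when a grid or world configuration violates an invariant."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the fine grid and its coarse (spread-model) blocking.

    Parameters
    ----------
    n_rows, n_cols
        Fine-grid dimensions.
    cell_area
        Area of one fine cell in km².
    coarse_block
        Number of fine cells per side of one coarse spread-model cell.
        ``n_rows`` and ``n_cols`` must be divisible by it.
    """

    n_rows: int
    n_cols: int
    cell_area: float = 1.0
    coarse_block: int = 1

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.coarse_block < 1:
            raise ConfigurationError("grid dimensions must be >= 1")
        if self.cell_area <= 0:
            raise ConfigurationError("cell_area must be positive")
        if self.n_rows % self.coarse_block or self.n_cols % self.coarse_block:
            raise ConfigurationError(
                f"grid {self.n_rows}x{self.n_cols} not divisible by "
                f"coarse_block={self.coarse_block}"
            )

    @property
    def coarse_shape(self) -> tuple[int, int]:
        return (self.n_rows // self.coarse_block, self.n_cols // self.coarse_block)

    @property
    def fine_shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


# Default class mix: mature stands dominate European conifer stock, with the
# bulk of volume in older age classes spread over all susceptibility levels.
DEFAULT_CLASS_MIX = (0.10, 0.08, 0.07, 0.30, 0.25, 0.20)


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Parameters of the synthetic world generator."""

    grid: GridSpec
    n_regions: int = 4
    temperature_base: float = 20.0
    temperature_south_north_gradient: float = 0.1  # °C per row moving south
    temperature_noise_sd: float = 0.5
    stock_total_target: float = 2.46e10  # m³, EU-scale conifer standing stock
    class_mix: Sequence[float] = DEFAULT_CLASS_MIX
    entry_cell: tuple[int, int] = (0, 0)  # coarse (row, col)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.shape != (6,):
            raise ConfigurationError("class_mix must have exactly 6 entries")
        if (mix < 0).any():
            raise ConfigurationError("class_mix entries must be non-negative")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigurationError("class_mix must sum to 1")
        if self.stock_total_target < 0:
            raise ConfigurationError("stock_total_target must be >= 0")
        cr, cc = self.grid.coarse_shape
        er, ec = self.entry_cell
        if not (0 <= er < cr and 0 <= ec < cc):
            raise ConfigurationError(
                f"entry_cell {self.entry_cell} outside coarse grid {cr}x{cc}"
            )


@dataclass
class World:
    """Bundle of generated layers: temperature, regions and host stock."""

    grid: GridSpec
    temperature: np.ndarray  # (n_rows, n_cols) float °C
    region_map: np.ndarray  # (n_rows, n_cols) int region ids 0..n_regions-1
    stock: pd.DataFrame  # columns: region_id, age_class, susceptibility, stock_m3

    @property
    def region_ids(self) -> np.ndarray:
        return np.unique(self.region_map)

    def stock_matrix(self) -> pd.DataFrame:
        """Stock pivoted to one row per region, one column per class."""
        return self.stock.pivot_table(
            index="region_id",
            columns=["age_class", "susceptibility"],
            values="stock_m3",
            aggfunc="sum",
        ).fillna(0.0)


def _region_tiling(n_rows: int, n_cols: int, n_regions: int) -> np.ndarray:
    """Partition the fine grid into ``n_regions`` contiguous rectangular
    blocks, tiled as close to square as the factorization allows."""
    best = (1, n_regions)
    for k in range(1, int(math.isqrt(n_regions)) + 1):
        if n_regions % k == 0:
            best = (k, n_regions // k)
    n_block_rows, n_block_cols = best
    if n_block_rows > n_rows or n_block_cols > n_cols:
        raise ConfigurationError(
            f"cannot tile {n_regions} regions on a {n_rows}x{n_cols} grid"
        )
    row_edges = np.linspace(0, n_rows, n_block_rows + 1).astype(int)
    col_edges = np.linspace(0, n_cols, n_block_cols + 1).astype(int)
    region_map = np.empty((n_rows, n_cols), dtype=np.int64)
    rid = 0
    for i in range(n_block_rows):
        for j in range(n_block_cols):
            region_map[row_edges[i]:row_edges[i + 1],
                       col_edges[j]:col_edges[j + 1]] = rid
            rid += 1
    return region_map


def generate_world(config: SyntheticWorldConfig) -> World:
    """Generate temperature, region and host-stock layers.

    Temperature follows a linear south–north gradient (southern rows are
    warmer when the gradient is positive) centred on ``temperature_base`` at
    the middle row, plus i.i.d. Gaussian noise per fine cell.  Regional
    stock totals are proportional to region area perturbed by lognormal
    noise, then split across the six vulnerability classes exactly in the
    proportions of ``class_mix``; the grand total equals
    ``stock_total_target`` up to floating-point rounding.
    """
    grid = config.grid
    rng = np.random.default_rng(config.seed)

    rows = np.arange(grid.n_rows, dtype=float)
    mid = (grid.n_rows - 1) / 2.0
    gradient_profile = config.temperature_base + (
        config.temperature_south_north_gradient * (rows - mid)
    )
    temperature = np.broadcast_to(
        gradient_profile[:, None], grid.fine_shape
    ).copy()
    if config.temperature_noise_sd > 0:
        temperature += rng.normal(0.0, config.temperature_noise_sd, grid.fine_shape)

    region_map = _region_tiling(grid.n_rows, grid.n_cols, config.n_regions)

    counts = np.bincount(region_map.ravel(), minlength=config.n_regions).astype(float)
    weights = counts * rng.lognormal(mean=0.0, sigma=0.3, size=config.n_regions)
    weights /= weights.sum()
    region_totals = config.stock_total_target * weights

    mix = np.asarray(config.class_mix, dtype=float)
    records = []
    for rid in range(config.n_regions):
        for (age, susc), frac in zip(VULNERABILITY_CLASSES, mix):
            records.append(
                {
                    "region_id": rid,
                    "age_class": age,
                    "susceptibility": susc,
                    "stock_m3": region_totals[rid] * frac,
                }
            )
    stock = pd.DataFrame.from_records(records)

    return World(grid=grid, temperature=temperature, region_map=region_map, stock=stock)


@dataclass
class OccupancySeries:
    """Per-year boolean occupancy grids at coarse resolution.

    ``grids`` has shape ``(n_years, coarse_rows, coarse_cols)``; year index 0
    is the entry year.  Occupancy is monotone: a cell once occupied stays
    occupied.
    """

    years: list[int]
    grids: np.ndarray

    def __post_init__(self) -> None:
        self.grids = np.asarray(self.grids, dtype=bool)
        if self.grids.ndim != 3 or self.grids.shape[0] != len(self.years):
            raise ValueError("grids must be (n_years, rows, cols) matching years")

    @property
    def final(self) -> np.ndarray:
        return self.grids[-1]

    def invaded_counts(self) -> np.ndarray:
        return self.grids.reshape(len(self.years), -1).sum(axis=1)

    def is_monotone(self) -> bool:
        g = self.grids
        return bool(np.all(g[:-1] <= g[1:]))


@dataclass
class SpreadReplicateSet:
    """Stack of replicate occupancy series from the stochastic spread model."""

    years: list[int]
    occupancy: np.ndarray  # (n_replicates, n_years, rows, cols) bool

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 4 or self.occupancy.shape[1] != len(self.years):
            raise ValueError("occupancy must be (n_rep, n_years, rows, cols)")

    @property
    def n_replicates(self) -> int:
        return self.occupancy.shape[0]

    @property
    def invaded_count_final(self) -> np.ndarray:
        """Occupied coarse cells in the final year, per replicate."""
        return self.occupancy[:, -1].reshape(self.n_replicates, -1).sum(axis=1)

    def replicate(self, index: int) -> OccupancySeries:
        return OccupancySeries(years=list(self.years), grids=self.occupancy[index])


def simulate_spread(
    world: World,
    entry_cell: tuple[int, int],
    years: int,
    growth_radius: int = 1,
    jump_rate: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
    growth_prob: float = 1.0,
    start_year: int = 2008,
) -> SpreadReplicateSet:
    """Stochastic cellular range expansion on the coarse grid.

    Each year, every unoccupied cell within Chebyshev distance
    ``growth_radius`` of an occupied cell becomes occupied with probability
    ``growth_prob`` (local beetle-vectored expansion), and a
    Poisson(``jump_rate``) number of uniformly random cells become occupied
    (long-distance, human-mediated jumps).  Occupancy is monotone in time.

    Returns ``years + 1`` grids per replicate: the entry year plus one grid
    per subsequent year.
    """
    coarse_shape = world.grid.coarse_shape
    er, ec = entry_cell
    if not (0 <= er < coarse_shape[0] and 0 <= ec < coarse_shape[1]):
        raise IndexError(f"entry cell {entry_cell} outside coarse grid {coarse_shape}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if years < 0:
        raise ValueError("years must be >= 0")
    if not 0.0 <= growth_prob <= 1.0:
        raise ValueError("growth_prob must be in [0, 1]")

    size = 2 * growth_radius + 1
    structure = np.ones((size, size), dtype=bool)  # Chebyshev neighbourhood
    n_cells = coarse_shape[0] * coarse_shape[1]

    children = np.random.SeedSequence(seed).spawn(n_replicates)
    all_reps = np.zeros((n_replicates, years + 1) + coarse_shape, dtype=bool)
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        occ = np.zeros(coarse_shape, dtype=bool)
        occ[er, ec] = True
        all_reps[rep, 0] = occ
        for t in range(1, years + 1):
            frontier = ndimage.binary_dilation(occ, structure=structure) & ~occ
            if growth_prob >= 1.0:
                new = frontier
            else:
                new = frontier & (rng.random(coarse_shape) < growth_prob)
            occ = occ | new
            n_jumps = rng.poisson(jump_rate) if jump_rate > 0 else 0
            if n_jumps:
                flat = rng.integers(0, n_cells, size=n_jumps)
                occ.ravel()[flat] = True
            all_reps[rep, t] = occ

    return SpreadReplicateSet(
        years=list(range(start_year, start_year + years + 1)), occupancy=all_reps
    )


def select_percentile_replicate(
    replicates: SpreadReplicateSet, q: float
) -> OccupancySeries:
    """Select the replicate at the nearest-rank q-th percentile of
    final-year invaded-cell counts.

    The nearest-rank definition picks the replicate of rank
    ``max(1, ceil(q/100 * n))`` in the ascending ordering of final counts;
    ties are broken by lowest replicate index (stable sort).
    """
    if replicates.n_replicates == 0:
        raise ValueError("replicate set is empty")
    if not 0.0 <= q <= 100.0:
        raise ValueError("percentile q must be in [0, 100]")
    counts = replicates.invaded_count_final
    order = np.argsort(counts, kind="stable")
    rank = max(1, math.ceil(q / 100.0 * len(counts)))
    return replicates.replicate(int(order[rank - 1]))
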