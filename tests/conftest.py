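import numpy as np
import pytest

from pinewilt.synthetic_data import (
    GridSpec,
    SyntheticWorldConfig,
    generate_world,
    simulate_spread,
)


@pytest.fixture
def small_grid():
    return GridSpec(n_rows=12, n_cols=12, cell_area=1.0, coarse_block=3)


@pytest.fixture
def small_config(small_grid):
    return SyntheticWorldConfig(
        grid=small_grid,
        n_regions=4,
        temperature_base=20.0,
        temperature_south_north_gradient=0.5,
        temperature_noise_sd=0.3,
        stock_total_target=1e9,
        entry_cell=(3, 0),  # south-west corner of the 4x4 coarse grid
        seed=7,
    )


@pytest.fixture
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture
def small_replicates(small_world, small_config):
    return simulate_spread(
        small_world,
        entry_cell=small_config.entry_cell,
        years=6,
        growth_radius=1,
        jump_rate=0.3,
        growth_prob=0.7,
        n_replicates=20,
        seed=11,
    )


@pytest.fixture
def uniform_warm_world(small_grid):
    """Deterministic world: every cell at 25 °C, uniform stock."""
    cfg = SyntheticWorldConfig(
        grid=small_grid,
        n_regions=4,
        temperature_base=25.0,
        temperature_south_north_gradient=0.0,
        temperature_noise_sd=0.0,
        stock_total_target=6e6,
        entry_cell=(0, 0),
        seed=1,
    )
    return generate_world(cfg)
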