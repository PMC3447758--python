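# Default synthetic-world demonstration: 100x100 km fine grid, 20x20 coarse
# spread grid, 20 regions, 200 spread replicates, 2008-2030.
seed: 2008
resolution: both

world:
  n_rows: 100
  n_cols: 100
  coarse_block: 5
  n_regions: 20
  temperature_base: 15.8        # °C at the mid-row
  temperature_gradient: 0.12    # °C per row moving south
  temperature_noise_sd: 0.4
  stock_total_target: 2.46e10   # m³ standing stock
  entry_cell: [19, 1]           # coarse (row, col), south-west

spread:
  growth_radius: 1
  growth_prob: 0.3
  jump_rate: 0.05
  n_replicates: 200

scenario:
  spread_percentile: 50
  threshold: 20.0
  mortality_preset: default
  price: 50.49

years:
  start: 2008
  end: 2030
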