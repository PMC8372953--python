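# Default pipeline configuration.  Paths set to null are filled with
# synthetic data generated from the seed, so the pipeline runs end-to-end
# without external inputs.
seed: 1
output_dir: outputs

inventory:
  path: null            # delimited inventory file; null -> synthetic stand
  dbh_min: 5.0          # census threshold, cm
  plot_area_ha: 0.16    # 40 m x 40 m plots

conventions:
  ivi: paper_100        # paper_100 | standard_300
  jaccard: standard     # standard | paper_total
  dbh_edges: [5, 10, 20, 30]
  height_edges: [1.3, 5, 10, 15]

typing:
  linkage: ward         # ward | average | complete | flexible_beta
  k: 2

allometry:
  stem_a: 0.0396
  stem_b: 0.9326
  branch_a: 0.003487
  branch_b: 1.027
  leaf_c: 28.0
  leaf_d: 0.025
  carbon_fraction: 0.47

lulc:
  map_t1: null          # plain-text grid; null -> synthetic pair
  map_t2: null
  cell_area_ha: 0.09    # 30 m pixel
  period_years: 11
  forest_classes: [0, 1]
  filter_size: 5
  n_periods: 2

market:
  co2e_factor: 3.67     # t CO2e per t C (44/12)
  price_usd_per_tco2e: 3.20
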