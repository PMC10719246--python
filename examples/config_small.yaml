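# Bundled desk-scale configuration (20 jurisdictions).
#
# generator: synthetic jurisdiction panels.
#   variant_spans        calendar span per forest-change dataset variant
#   driver_effect_sizes  true coefficients on the log latent deforestation rate
#   ar1_coefficient / process_noise_sd   AR(1) noise on the log rate
#   observation_noise_cv / dataset_bias_factors   per-variant observation model
#   carbon_source_params per-source mean density (Mg/ha) + provider uncertainty
#                        (null -> the 33% default applies); kind is dense /
#                        sparse (GEDI-track style) / ratio (root:shoot of AGB)
#   subdivision_threshold_km2  forest area above which subnational children
#                        are emitted (screening then replaces the national unit)
# grid: which cells of the method grid to evaluate.
#   approaches           hist | linear | poly2 | global | global_s | regional | regional_s
#   start_years: null    means every start year whose window fits the span
#   ensemble_reps        members per random-driver-subset ensemble (study scale: 300)
# importance: bootstrapped random-forest variable importance (study scale:
#   100 models x 200 trees x 900000 rows).
# metrics: uncertainty threshold (%) for the exceedance fraction.
generator:
  n_jurisdictions: 20
  seed: 0
  variant_spans:
    hansen15:
    - 2000
    - 2021
    hansen30:
    - 2000
    - 2021
    hansen60:
    - 2000
    - 2021
    modis:
    - 2001
    - 2020
    esacci:
    - 1992
    - 2020
  n_drivers: 12
  n_active_drivers: 4
  driver_effect_sizes:
  - 0.8
  - -0.6
  - 0.5
  - -0.4
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  driver_common_factor_loading: 0.0
  driver_drift_sd: 0.05
  ar1_coefficient: 0.5
  process_noise_sd: 0.3
  observation_noise_cv:
    hansen15: 0.05
    hansen30: 0.05
    hansen60: 0.05
    modis: 0.15
    esacci: 0.2
  dataset_bias_factors:
    hansen15: 1.15
    hansen30: 1.0
    hansen60: 0.85
    modis: 0.9
    esacci: 1.1
  base_deforestation_fraction: 0.005
  forest_area_median_km2: 3000.0
  forest_area_sigma: 1.2
  forest_area_range_km2:
  - 200.0
  - 200000.0
  cover_range:
  - 0.05
  - 0.8
  noise_area_scaling: false
  noise_area_reference_km2: 3000.0
  carbon_source_params:
    spawn:
      pool: agb
      kind: dense
      mean_density: 180.0
      rel_uncertainty: 0.13
      ratio_by_region: null
    gedi:
      pool: agb
      kind: sparse
      mean_density: 170.0
      rel_uncertainty: 0.15
      ratio_by_region: null
    soto:
      pool: agb
      kind: dense
      mean_density: 160.0
      rel_uncertainty: 0.2
      ratio_by_region: null
    spawn_bgb:
      pool: bgb
      kind: dense
      mean_density: 45.0
      rel_uncertainty: 0.25
      ratio_by_region: null
    soto_bgb:
      pool: bgb
      kind: dense
      mean_density: 40.0
      rel_uncertainty: 0.22
      ratio_by_region: null
    ipcc_ratio:
      pool: bgb
      kind: ratio
      mean_density: 0.0
      rel_uncertainty: null
      ratio_by_region:
        Africa: 0.37
        Asia: 0.37
        Oceania: 0.3
        Latin America: 0.37
        North America: 0.27
        Europe: 0.25
    esdac:
      pool: soc
      kind: dense
      mean_density: 80.0
      rel_uncertainty: null
      ratio_by_region: null
    olm:
      pool: soc
      kind: dense
      mean_density: 90.0
      rel_uncertainty: 0.3
      ratio_by_region: null
  carbon_between_jurisdiction_cv: 0.3
  carbon_cell_cv: 0.3
  sparse_source_sampling_fraction: 0.05
  n_carbon_subunits: 1000
  carbon_mask_cv: 0.03
  region_labels:
  - Africa
  - Asia
  - Oceania
  - Latin America
  - North America
  - Europe
  subdivision_threshold_km2: 10000.0
  children_range:
  - 3
  - 8
  dirichlet_alpha: 1.5
grid:
  approaches:
  - hist
  - linear
  - poly2
  - global
  - global_s
  - regional
  - regional_s
  defor_variants:
  - hansen30
  - modis
  - esacci
  ref_lengths:
  - 5
  - 10
  - 15
  start_years:
  - 2001
  - 2004
  carbon_mask_variants:
  - hansen30
  - modis
  agb_sources:
  - spawn
  - gedi
  - soto
  bgb_sources:
  - spawn_bgb
  - soto_bgb
  - ipcc_ratio
  soc_sources:
  - esdac
  - olm
  ensemble_reps: 30
  ensemble_size_range:
  - 3
  - 11
  member_stepwise: false
  min_fit_margin: 5
  bgb_decay_horizon_years: 10.0
  soc_inclusion_weight: 1.0
importance:
  n_models: 8
  n_trees: 40
  sample_rows: 20000
  include_start_year: false
  min_samples_leaf: 5
metrics:
  uncertainty_threshold_pct: 15.0
  alpha: 0.05
screening_reference_variant: modis
chunk_size: 200000
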