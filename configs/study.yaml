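seed: 1
world:
  lon_min: 20.0
  lon_max: 30.0
  lat_min: -35.0
  lat_max: -25.0
  resolution: 0.05
  n_ridges: 3
  amplitude_m: 2500.0
  base_m: 200.0
  terrain_noise_sd: 50.0
  mountain_elev_cut_m: 1000.0
  sea_level_temp_C: 26.0
  lapse_C_per_km: 6.5
  lat_gradient_C_per_deg: 0.3
  precip_base_mm: 900.0
  orographic_mm_per_km: 400.0
  climate_noise_sd: 0.3
  noise_kernel_cells: 3.0
  gcm_spread_sd: 0.3
  precip_member_sd: 0.02
  n_species: 24
  n_presence: 120
  sampling_bias_exp: 1.0
  tau: 0.5
  sigma_T_range:
  - 0.8
  - 2.0
  sigma_P_range:
  - 150.0
  - 400.0
  temperature_only_niche: false
  niche_elevation_range: null
  landuse_classes:
  - forest
  - grassland
  - shrubland
  - pasture
  - barren
  - corn
  - wheat
  - soybean
  - cotton
  - rice
  - sugar_crop
  - other_crops
  - bioenergy_crop
  - urban
scenarios:
- scenario_id: SSP1.26
  delta_T_C: 1.8
  precip_scale: 1.02
  crop_pressure: 0.5
- scenario_id: SSP3.70
  delta_T_C: 3.7
  precip_scale: 0.95
  crop_pressure: 2.0
- scenario_id: SSP5.85
  delta_T_C: 4.4
  precip_scale: 0.9
  crop_pressure: 3.0
year_min: 1981
buffer_km: 1.0
min_cells: 14
mountain_percentile: 75.0
n_background: 2000
block_km: 250.0
k_folds: 5
auc_min: 0.7
lam: 1.0
horizon_years: 70.0
n_gcm: 5
min_agree: 3
excluded_landuse:
- corn
- wheat
- soybean
- cotton
- rice
- sugar_crop
- other_crops
- bioenergy_crop
- urban
clip_fraction: 0.05
predictors: null
n_perm: 3
mask_current: false
unlimited_dispersal: false
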