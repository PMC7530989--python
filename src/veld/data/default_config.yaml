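# veld default configuration.
# Every scientific parameter of the pipeline appears here with its
# default; any subset may be overridden in a user config file passed
# via --config.  Values shown are the ones the library uses when the
# key is absent.

climate:
  # domain extent (degrees; southern-hemisphere latitudes negative)
  lat_min: -35.0
  lat_max: -10.0
  lon_min: 10.0
  lon_max: 35.0
  resolution: 1.0          # degrees, cell-centre regular grid
  seed: 0                  # RNG seed for the generator noise
  # mean annual temperature structure
  mat_north: 30.0          # MAT at the equatorward edge, degC
  mat_lapse: 0.9           # poleward MAT decrease, degC per degree latitude
  mat_east_gain: 3.0       # west-to-east MAT contrast across the domain, degC
  # seasonal temperature half-amplitude: near-tropical floor, rising
  # poleward of amp_lat0 (degrees south) to floor+rise at the S edge
  amp_floor: 1.2
  amp_rise: 4.3
  amp_lat0: 26.0
  # mean annual precipitation structure (mm/yr)
  map_min: 60.0            # driest interior
  map_range: 1050.0        # extra MAP toward the north-east
  map_winter_bonus: 200.0  # extra MAP in the winter-rainfall corner
  # rainfall seasonality geometry
  mode_power: 2.0          # sharpness of the summer/winter monthly modes
  winter_weight: 0.9       # strength of the winter-rain mode at the SW corner
  winter_spread: 0.35      # spatial reach of the winter-rain zone
  uniform_weight: 0.85     # strength of the year-round mode on the south coast
  uniform_spread: 0.15     # latitudinal reach of the year-round band
  # seeded noise
  noise_pre: 0.10          # lognormal sigma on monthly precipitation
  noise_tas: 0.2           # additive degC s.d. on monthly temperature

experiment:
  co2_levels: [150.0, 250.0]   # ppm: deep post-MPT vs milder pre-MPT glacial
  fire: [true, false]          # fire switched on and off
  variants: [A, B, C, D]       # the four LGM-like climate variants
  spinup_years: 200            # desk-scale spin-up from bare ground
                               # (full-scale protocol: 4000)
  run_years: 50                # averaging window after spin-up
                               # (full-scale protocol: 1380)
  seed: 0

soil:
  capacity: 150.0       # single-layer bucket, mm plant-available water
  infiltration: 0.8     # fraction of monthly rainfall entering the bucket
  evap_rate: 1.8        # bare-soil evaporation, mm/day at saturated soil

fire:
  ignitions: 1.0                # lightning fires per cell per year
  moisture_of_extinction: 0.35  # wet-day fraction above which nothing burns
  fuel_threshold: 200.0         # g C/m2 minimum fine fuel for fire
  spread_factor: 0.45           # mean burned area per fire at dryness 1
  consume_frac: 0.5             # fraction of fuel consumed in the flame
  flame_coef: 0.15              # flame height, m per sqrt(intensity)
  scorch_steepness: 3.0         # logistic steepness of crown-scorch mortality
  cambial_mortality: 0.35       # extra tree kill per unit burned fraction
  litter_frac_tree: 0.2         # tree biomass counted as fine fuel

pfts:
  # traits may be overridden per PFT; photosynthetic-pathway constants
  # live in veld.photosynthesis (calibrated as a set, see docs/methods.md)
  tropical_tree:
    t_coldest_min: 5.5     # degC coldest-month survival limit
    canopy_height: 8.0     # m, for crown scorch
    turnover_rate: 0.05    # background mortality, /yr
    sla: 0.010             # specific leaf area, m2 per g C
    leaf_frac: 0.25        # leaf fraction of biomass
    resp_maint: 0.35       # maintenance respiration, /yr on biomass
  C3_grass:
    t_coldest_min: null    # no lower survival limit
    canopy_height: 0.5
    turnover_rate: 0.5
    sla: 0.012
    leaf_frac: 1.0
    resp_maint: 0.8
  C4_grass:
    t_coldest_min: 15.5    # cannot survive a coldest month below this
    canopy_height: 0.5
    turnover_rate: 0.5
    sla: 0.012
    leaf_frac: 1.0
    resp_maint: 0.8
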