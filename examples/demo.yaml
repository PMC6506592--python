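# Demo run configuration: a reduced study analog that completes in a few
# minutes on one CPU.  Scale population_model / cohort_spec / release_spec
# up to the full study sizes (15 populations, 24 months, 10,000 particles)
# for a complete emulation.
seed: 7
output_dir: out

population_model:
  n_pops: 4
  n_loci: 14
  fst_target: 0.05

cohort_spec:
  sites: [LongKey, BigMunson]
  months: [m01, m02, m03, m04, m05, m06]
  n_per_month: 20
  prop_parent_sampled: 0.3
  error_rate: 0.01
  missing_rate: 0.02

parentage:
  error_rate: 0.01
  n_sim_offspring: 2000     # 10000 in the full analysis
  n_candidates: 98
  prop_sampled: 0.016
  confidence_level: 0.95
  min_loci_compared: 10
  max_mismatches: 2

field_spec:
  lon_min: -84.0
  lon_max: -79.0
  lat_min: 22.0
  lat_max: 26.0
  grid_step: 0.1
  t_span: 2678400.0         # 31 days of daily fields, seconds
  t_step: 86400.0
  pattern: double_gyre
  params: {amplitude: 0.2, period: 2592000.0}

release_spec:
  polygons:
    BigMunson: [-81.387, 24.617, 64.0]   # lon, lat, area km^2 (lower Keys)
    LongKey: [-80.84, 24.803, 64.0]      # middle Keys
  n_particles: 200          # 10000 in the full analysis
  release_times: [2592000.0]
  duration_days: 28         # 196 in the full analysis
  precompetency_days: 20    # 152 in the full analysis
  dt: 1800.0
  direction: backward

ovm_schedule:
  - [0.0, 28.0, 5.0]        # flat 5 m; add bands for age-dependent depth

regions:
  west: [[-84, 22], [-82, 22], [-82, 26], [-84, 26]]
  east: [[-82, 22], [-79, 22], [-79, 26], [-82, 26]]

region_mapping:
  pop1: west
  pop2: west
  pop3: east
  pop4: east

dapc_k_max: 4
fst_n_perm: 0
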