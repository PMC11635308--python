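# Default three-species scenario: S1's optimum at the long-term maximum
# environmental temperature (37°C), S2 above, S3 below. Equal capacities,
# equal small initial densities, peaks normalized to 1 per unit time.
seed: 0
output_dir: out
log_level: INFO

community:
  initial_density: 0.01
  species:
    - {id: S1, form: beta, t_min: 0.0, t_opt: 37.0, t_max: 41.0, r_peak: 1.0, death_slope: 0.1, k: 1.0}
    - {id: S2, form: beta, t_min: 0.0, t_opt: 42.0, t_max: 46.0, r_peak: 1.0, death_slope: 0.1, k: 1.0}
    - {id: S3, form: beta, t_min: 0.0, t_opt: 32.0, t_max: 37.0, r_peak: 1.0, death_slope: 0.1, k: 1.0}

sweep:
  t_start: 25.0
  t_end: 45.0
  step: 0.1
  tie_tol: 1.0e-6

integration:
  method: LSODA
  rtol: 1.0e-8
  atol: 1.0e-12
  deriv_tol: 1.0e-9
  horizon: 1.0e4
  extinction_threshold: 1.0e-9

ensemble:
  skew_range: [0.05, 0.8]
  spacing_range: [2.0, 8.0]
  peak_range: [0.5, 2.0]
  normalize: true
  subset_sizes: [2, 3]
  n_draws: 10
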