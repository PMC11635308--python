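# Degenerate ensemble: near-identical temperature optima (sub-0.01°C
# spacing) produce dominance ties — scenarios flagged non-informative
# rather than ranked on numerically meaningless density differences.
seed: 0
output_dir: out
log_level: INFO

community:
  initial_density: 0.01
  species:
    - {id: S1, form: beta, t_min: 0.0, t_opt: 37.0, t_max: 41.0, r_peak: 1.0, death_slope: 0.1, k: 1.0}
    - {id: S2, form: beta, t_min: 0.0, t_opt: 42.0, t_max: 46.0, r_peak: 1.0, death_slope: 0.1, k: 1.0}
    - {id: S3, form: beta, t_min: 0.0, t_opt: 32.0, t_max: 37.0, r_peak: 1.0, death_slope: 0.1, k: 1.0}

sweep: {t_start: 25.0, t_end: 45.0, step: 0.1, tie_tol: 1.0e-6}

ensemble:
  skew_range: [0.05, 0.8]
  spacing_range: [0.0005, 0.005]
  normalize: true
  subset_sizes: [3]
  n_draws: 10
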