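# Demo configuration for `edhwheat run-all --config examples/demo_config.yaml
# --outdir out/`.  A reduced 8x8 grid keeps the full pipeline under a minute.
synthetic:
  n_lat: 8
  n_lon: 8
  year_start: 1960
  year_end: 2018
  seed: 1
  tillage_effect_regions:
    NT: {row0: 5, row1: 8, col0: 0, col1: 8, beta_scale: 0.3}
    CT: {row0: 0, row1: 3, col0: 0, col1: 8, beta_scale: 0.3}
window_length: 20
heat_threshold: 30.0
aridity_threshold: 0.2
alpha: 0.05
tillage_threshold: 0.75
methods: [pearson]
decision_variable: GHGI
wheat_type: winter
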