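run_dir: .
epochs: ["2000", "2010", "2020"]
seed: 1
weights:
  source: bundled
standardization:
  minmax_policy: global
classification:
  mode: geometric_interval
  K: 5
elevation:
  n_points: 1000
  band_width_m: 50.0
simulate:
  shape: [120, 120]
  epochs: ["2000", "2010", "2020"]
  seed: 1
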