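# Example pipeline configuration for `rxnet run --config examples/config.yaml`
simulate:
  n_physicians: 120
  n_patients: 500
  seed: 7
window_days: 30
exposure_mode: union
random_effects: false
interaction: false
starting_states: [0]
out_dir: rxnet_out
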