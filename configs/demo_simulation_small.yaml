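# Small, fast demo: 2 runs per state, 2 ns each.
master_seed: 0
n_runs_per_state: 2
output_dir: sim_out_small
base_spec:
  n_atoms: [60, 60]
  shape_sds: [[0.9, 0.6, 0.3], [0.9, 0.6, 0.3]]
  distance_model: {kind: constant, value: 2.5}
  rotation_model: {kind: constant, value: 0.0}  # replaced per state
  rotation_axis: v1
  jitter_sd: 0.01
  duration: 2.0
  output_interval: 0.04
  seed: 0
  separation_axis: [1.0, 0.0, 0.0]
  breathing: null
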