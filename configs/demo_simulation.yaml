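# Study-mirror demo: 10 bound + 10 free runs, 40 ns at 0.04 ns per frame.
# Warning: writes ~20 multi-model PDB files of 1000 frames each.
# For a quick look use demo_simulation_small.yaml instead.
master_seed: 0
n_runs_per_state: 10
output_dir: sim_out
base_spec:
  n_atoms: [120, 120]
  shape_sds: [[0.9, 0.6, 0.3], [0.9, 0.6, 0.3]]
  distance_model: {kind: constant, value: 2.5}
  rotation_model: {kind: constant, value: 0.0}  # replaced per state
  rotation_axis: v1
  jitter_sd: 0.01
  duration: 40.0
  output_interval: 0.04
  seed: 0
  separation_axis: [1.0, 0.0, 0.0]
  breathing: null
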