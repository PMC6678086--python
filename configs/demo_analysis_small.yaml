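# Analysis of the small simulation demo. Place this file inside the
# simulation output directory (paths are relative to the config file),
# or copy it there after running:
#   domdyn simulate --config configs/demo_simulation_small.yaml
reference: reference.pdb
states:
  bound:
    - {run_id: bound_run00, path: bound_run00.pdb}
    - {run_id: bound_run01, path: bound_run01.pdb}
  free:
    - {run_id: free_run00, path: free_run00.pdb}
    - {run_id: free_run01, path: free_run01.pdb}
domains:
  - {name: domA, chain_id: A, residue_intervals: [[1, 60]]}
  - {name: domB, chain_id: B, residue_intervals: [[1, 60]]}
pairs:
  - [domA, domB]
fit_selection: all
stride: 0.2
frame_interval: 0.04
output_dir: analysis_out
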