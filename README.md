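# domdyn

Bound-vs-free domain dynamics analysis for protein trajectories.

`domdyn` quantifies how the relative geometry of two quasi-rigid protein
domains changes between two ensemble states (e.g. a receptor bound to its
ligand vs. free in solution):

- **Local frames** — a per-frame PCA eigenvector triad for each domain's
  Cα cloud, sign-standardized against a fixed reference (crystal)
  structure so axes are comparable across frames and independent runs
  (`domdyn.local_frames`).
- **Orientation series** — angles α, β, γ between corresponding
  eigenvectors of two domains, from signed directional cosines
  (`domdyn.orientation_stats`).
- **Inter-domain distances** — Euclidean distance between unweighted
  geometric centers of the Cα selections (`domdyn.kinematics`).
- **Deformation statistics** — RMSD(t) after per-domain least-squares
  fitting, per-residue RMSF about the time-averaged position, per-run and
  pooled summaries with boxplot statistics (`domdyn.deformation_stats`).
- **State comparison** — means, sample SDs and the exact two-sample
  Kolmogorov–Smirnov statistic D between bound and free ensembles,
  used descriptively (no p-values).
- **Synthetic trajectories** — a two-domain rigid-body generator with
  prescribed distance dynamics, relative rotations (constant, sinusoidal
  or Ornstein–Uhlenbeck), per-atom Gaussian jitter and optional breathing
  deformation, with exact per-frame ground truth (`domdyn.synthetic`).
  Every analysis stage is tested closed-loop against it.

Internal units are nm and ns; PDB I/O converts Å↔nm at the boundary.
Global translation/rotation is removed by SVD-based (Kabsch)
superposition with reflection correction.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, one test per
criterion. The crystal-structure parsing criterion is optional and skips
unless a local copy of the structure is placed at `data/3kps.pdb`.

## CLI

```sh
# generate synthetic bound/free ensembles with a manifest
domdyn simulate --config configs/demo_simulation_small.yaml --out sim_out

# run the full analysis (distances, orientations, RMSD/RMSF, comparisons)
cp configs/demo_analysis_small.yaml sim_out/
domdyn analyze --config sim_out/demo_analysis_small.yaml

# compare a scalar column between states across series CSVs
domdyn compare --free f1.csv f2.csv --bound b1.csv --column beta_deg
```

`analyze` is deterministic: rerunning on identical inputs produces
byte-identical CSV outputs, each stamped with the config hash.
`configs/demo_simulation.yaml` mirrors the full study design
(10 + 10 runs of 40 ns at one frame per 0.04 ns, analyzed every 0.2 ns).

Analysis configs are YAML (JSON accepted); paths are relative to the
config file. Domains are named Cα selections: chain id plus inclusive
residue intervals, e.g.

```yaml
domains:
  - {name: Valpha, chain_id: D, residue_intervals: [[1, 104]]}
pairs:
  - [Valpha, Vbeta]
```

## Library example

```python
import domdyn

spec = domdyn.MotionSpec(rotation_model=domdyn.ConstantModel(25.0),
                         rotation_axis="v2", duration=4.0)
traj, truth = domdyn.generate(spec)
top, ref = domdyn.make_reference(spec)
dom_a = domdyn.DomainSpec("A", "A", ((1, 120),))
dom_b = domdyn.DomainSpec("B", "B", ((1, 120),))
frames_a = domdyn.frame_series(traj, dom_a, ref, top)
frames_b = domdyn.frame_series(traj, dom_b, ref, top)
angles = domdyn.orientation_series(frames_a, frames_b, traj.times)
assert abs(angles.alpha - 25.0).max() < 1e-6
```
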