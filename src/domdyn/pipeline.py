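"""Config-driven orchestration: simulate, analyze, compare.

The analyze path is deterministic (no RNG); all randomness lives in the
simulate path and flows from a single master seed. Every output file
carries the config hash in a header comment or sidecar for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deformation_stats import RMSDSeries, rmsd_series, rmsf_profile, summarize_runs
from .kinematics import interdomain_distance_series, remove_global_motion
from .local_frames import frame_series
from .orientation_stats import StateComparison, compare_states, orientation_series
from .structure_io import (
    DomainSpec,
    Frame,
    Topology,
    Trajectory,
    read_structure,
    read_trajectory,
    select_domain,
    write_trajectory,
)
from .synthetic import MotionSpec, generate, make_reference, make_state_ensemble

logger = logging.getLogger(__name__)

_CSV_FLOAT_FORMAT = "%.9g"
_STATES = ("free", "bound")


class ConfigError(ValueError):
    """The analysis configuration is inconsistent; raised before any I/O."""


@dataclass(frozen=True)
class RunInput:
    run_id: str
    paths: tuple[Path, ...]


@dataclass(frozen=True)
class AnalysisConfig:
    """Validated analysis configuration (paths resolved against the config file)."""

    reference: Path
    runs: Mapping[str, tuple[RunInput, ...]]  # state -> runs
    domains: tuple[DomainSpec, ...]
    pairs: tuple[tuple[str, str], ...]
    fit_selection: str = "all"  # "all" (every filtered atom) or a domain name
    stride: float = 0.2  # ns between analysis frames
    frame_interval: float = 0.04  # ns between stored frames (when file has no times)
    output_dir: Path = Path("analysis_out")
    raw: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        names = [d.name for d in self.domains]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigError(f"domain names defined more than once: {sorted(dupes)}")
        defined = set(names)
        for a, b in self.pairs:
            for n in (a, b):
                if n not in defined:
                    raise ConfigError(
                        f"pair ({a}, {b}) references undefined domain {n!r}"
                    )
        if self.fit_selection != "all" and self.fit_selection not in defined:
            raise ConfigError(
                f"fit_selection {self.fit_selection!r} is not a defined domain"
            )
        if self.stride <= 0:
            raise ConfigError("stride must be > 0")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base_dir=path.parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: str | Path = ".") -> "AnalysisConfig":
        base = Path(base_dir)
        try:
            domains = tuple(DomainSpec.from_dict(d) for d in raw["domains"])
            runs = {}
            for state, entries in raw["states"].items():
                if state not in _STATES:
                    raise ConfigError(
                        f"unknown state {state!r}; expected one of {_STATES}"
                    )
                runs[state] = tuple(
                    RunInput(
                        run_id=str(e["run_id"]),
                        paths=tuple(
                            base / p
                            for p in (
                                e["paths"] if "paths" in e else [e["path"]]
                            )
                        ),
                    )
                    for e in entries
                )
            pairs = tuple((p[0], p[1]) for p in raw["pairs"])
            return cls(
                reference=base / raw["reference"],
                runs=runs,
                domains=domains,
                pairs=pairs,
                fit_selection=raw.get("fit_selection", "all"),
                stride=float(raw.get("stride", 0.2)),
                frame_interval=float(raw.get("frame_interval", 0.04)),
                output_dir=base / raw.get("output_dir", "analysis_out"),
                raw=raw,
            )
        except KeyError as exc:
            raise ConfigError(f"missing config key: {exc}") from exc

    def config_hash(self) -> str:
        # output_dir is excluded so reruns into different directories
        # produce byte-identical analysis products
        canon = json.dumps(
            {k: v for k, v in self.raw.items() if k != "output_dir"},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All analysis products of one cmd_analyze invocation."""

    distances: pd.DataFrame
    orientations: pd.DataFrame
    rmsd: pd.DataFrame
    rmsf: pd.DataFrame
    comparisons: dict
    rmsd_summary: pd.DataFrame
    provenance: dict


def stride_frames(traj: Trajectory, stride_ns: float) -> Trajectory:
    """Keep frames spaced ~stride_ns apart (every round(stride/dt)-th frame).

    Frames are taken at k*stride for k = 1.., matching a trajectory
    whose first frame sits one interval after t = 0.
    """
    times = traj.times
    if len(times) < 2:
        return traj
    dt = float(np.median(np.diff(times)))
    step = max(1, int(round(stride_ns / dt)))
    return traj.with_frames(traj.frames[step - 1 :: step])


def _comparison_block(
    free_values: np.ndarray, bound_values: np.ndarray
) -> dict:
    return compare_states(free_values, bound_values).to_dict()


def analyze_trajectories(
    config: AnalysisConfig,
    trajectories: Mapping[str, Sequence[tuple[str, Trajectory]]],
    reference_topology: Topology,
    reference_frame: Frame,
) -> ReportBundle:
    """Core analysis over in-memory trajectories grouped by state.

    ``trajectories`` maps state -> [(run_id, Trajectory), ...]. Used by
    :func:`cmd_analyze` after file loading and directly by callers that
    generate trajectories in memory.
    """
    domains = {d.name: d for d in config.domains}
    if config.fit_selection == "all":
        filters = set().union(*(d.atom_filter for d in config.domains))
        fit_idx = np.array(
            [i for i, a in enumerate(reference_topology.atoms)
             if a.atom_name in filters],
            dtype=np.intp,
        )
    else:
        fit_idx = select_domain(
            reference_topology, domains[config.fit_selection]
        )

    dist_rows, orient_rows, rmsd_rows, rmsf_rows = [], [], [], []
    pooled_angles: dict[tuple, dict[str, list]] = {}
    pooled_dist: dict[tuple, dict[str, list]] = {}
    rmsd_by_run: dict[str, dict[str, np.ndarray]] = {}

    for state, runs in trajectories.items():
        for run_id, traj in runs:
            t0 = time.perf_counter()
            traj = stride_frames(traj, config.stride)
            traj = remove_global_motion(traj, fit_idx, reference_frame)

            lf_cache = {
                name: frame_series(traj, spec, reference_frame,
                                   reference_topology)
                for name, spec in domains.items()
            }
            for a, b in config.pairs:
                ds = interdomain_distance_series(traj, domains[a], domains[b])
                os_ = orientation_series(
                    lf_cache[a], lf_cache[b], times=traj.times,
                    domain_a=a, domain_b=b,
                )
                for t, d in zip(ds.times, ds.d):
                    dist_rows.append(
                        {"time_ns": t, "distance_nm": d, "domain_a": a,
                         "domain_b": b, "run_id": run_id, "state": state}
                    )
                for t, al, be, ga in zip(os_.times, os_.alpha, os_.beta,
                                         os_.gamma):
                    orient_rows.append(
                        {"time_ns": t, "alpha_deg": al, "beta_deg": be,
                         "gamma_deg": ga, "domain_a": a, "domain_b": b,
                         "run_id": run_id, "state": state}
                    )
                pooled_dist.setdefault((a, b), {}).setdefault(
                    state, []
                ).append(ds.d)
                ch = pooled_angles.setdefault((a, b), {})
                for channel in ("alpha", "beta", "gamma"):
                    ch.setdefault((channel, state), []).append(
                        os_.channel(channel)
                    )

            for name, spec in domains.items():
                rs = rmsd_series(traj, spec, run_id=run_id, state=state)
                for t, r in zip(rs.times, rs.rmsd):
                    rmsd_rows.append(
                        {"time_ns": t, "rmsd_nm": r, "domain": name,
                         "run_id": run_id, "state": state}
                    )
                rmsd_by_run.setdefault(name, {})[f"{state}:{run_id}"] = rs.rmsd
                idx = select_domain(traj.topology, spec)
                prof = rmsf_profile(traj, idx, run_id=run_id, state=state)
                for (chain, resnum, resname), r in zip(prof.labels, prof.rmsf):
                    rmsf_rows.append(
                        {"chain": chain, "resnum": resnum, "resname": resname,
                         "rmsf_nm": r, "domain": name, "run_id": run_id,
                         "state": state}
                    )
            logger.info(
                "analyzed %s run %s (%d frames) in %.2f s",
                state, run_id, traj.n_frames, time.perf_counter() - t0,
            )

    comparisons: dict[str, Any] = {}
    have_both = all(s in trajectories and len(trajectories[s]) > 0
                    for s in _STATES)
    if have_both:
        for (a, b), chans in pooled_angles.items():
            block: dict[str, Any] = {}
            for channel in ("alpha", "beta", "gamma"):
                free = np.concatenate(chans[(channel, "free")])
                bound = np.concatenate(chans[(channel, "bound")])
                block[channel] = _comparison_block(free, bound)
            dfree = np.concatenate(pooled_dist[(a, b)]["free"])
            dbound = np.concatenate(pooled_dist[(a, b)]["bound"])
            block["distance"] = _comparison_block(dfree, dbound)
            comparisons[f"{a}|{b}"] = block

    summary_rows = []
    for name, by_run in rmsd_by_run.items():
        summ = summarize_runs(by_run)
        for rid, m, s in zip(summ.run_ids, summ.run_means, summ.run_sds):
            st, _, run = rid.partition(":")
            summary_rows.append(
                {"domain": name, "state": st, "run_id": run,
                 "mean_nm": m, "sd_nm": s}
            )
        summary_rows.append(
            {"domain": name, "state": "pooled", "run_id": "all",
             "mean_nm": summ.pooled_mean, "sd_nm": summ.pooled_sd}
        )

    provenance = {
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "n_runs": {s: len(r) for s, r in trajectories.items()},
        "stride_ns": config.stride,
    }
    return ReportBundle(
        distances=pd.DataFrame(dist_rows),
        orientations=pd.DataFrame(orient_rows),
        rmsd=pd.DataFrame(rmsd_rows),
        rmsf=pd.DataFrame(rmsf_rows),
        comparisons=comparisons,
        rmsd_summary=pd.DataFrame(summary_rows),
        provenance=provenance,
    )


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, float_format=_CSV_FLOAT_FORMAT,
                  lineterminator="\n")


def cmd_analyze(config: AnalysisConfig | str | Path) -> ReportBundle:
    """Run the full analysis described by a config and write all products."""
    if not isinstance(config, AnalysisConfig):
        config = AnalysisConfig.from_file(config)
    ref_top, ref_frame = read_structure(config.reference)
    trajectories: dict[str, list[tuple[str, Trajectory]]] = {}
    for state, runs in config.runs.items():
        for run in runs:
            traj = read_trajectory(run.paths, ref_top, dt=config.frame_interval)
            trajectories.setdefault(state, []).append((run.run_id, traj))

    bundle = analyze_trajectories(config, trajectories, ref_top, ref_frame)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    _write_csv(bundle.distances, out / "distances.csv", h)
    _write_csv(bundle.orientations, out / "orientations.csv", h)
    _write_csv(bundle.rmsd, out / "rmsd.csv", h)
    _write_csv(bundle.rmsf, out / "rmsf.csv", h)
    _write_csv(bundle.rmsd_summary, out / "rmsd_summary.csv", h)
    with open(out / "comparisons.json", "w") as fh:
        json.dump(
            {"provenance": bundle.provenance, "pairs": bundle.comparisons},
            fh, indent=2, sort_keys=True,
        )
    with open(out / "provenance.json", "w") as fh:
        json.dump(bundle.provenance, fh, indent=2, sort_keys=True)
    return bundle


def cmd_simulate(
    sim_config: dict | str | Path,
    out_dir: str | Path | None = None,
    master_seed: int | None = None,
) -> dict:
    """Generate bound/free synthetic ensembles and write them with a manifest."""
    if not isinstance(sim_config, dict):
        with open(sim_config) as fh:
            sim_config = yaml.safe_load(fh)
    cfg = dict(sim_config)
    if master_seed is not None:
        cfg["master_seed"] = master_seed
    seed = int(cfg.get("master_seed", 0))
    n_runs = int(cfg.get("n_runs_per_state", 10))
    base_spec = MotionSpec.from_dict(cfg["base_spec"]) if "base_spec" in cfg \
        else MotionSpec()
    out = Path(out_dir if out_dir is not None else cfg.get("output_dir", "sim_out"))
    out.mkdir(parents=True, exist_ok=True)

    ref_top, ref_frame = make_reference(base_spec)
    ref_path = out / "reference.pdb"
    write_trajectory(Trajectory(ref_top, (ref_frame,)), ref_path)

    manifest: dict[str, Any] = {
        "master_seed": seed,
        "n_runs_per_state": n_runs,
        "base_spec": base_spec.to_dict(),
        "reference": ref_path.name,
        "runs": [],
    }
    for state in _STATES:
        ensemble = make_state_ensemble(state, n_runs, base_spec, seed)
        for i, (traj, truth) in enumerate(ensemble):
            stem = f"{state}_run{i:02d}"
            traj_path = out / f"{stem}.pdb"
            write_trajectory(traj, traj_path)
            gt = pd.DataFrame(
                {"time_ns": truth.times, "distance_nm": truth.distance,
                 "alpha_deg": truth.angles[:, 0],
                 "beta_deg": truth.angles[:, 1],
                 "gamma_deg": truth.angles[:, 2]}
            )
            gt_path = out / f"{stem}_truth.csv"
            gt.to_csv(gt_path, index=False, float_format=_CSV_FLOAT_FORMAT,
                      lineterminator="\n")
            manifest["runs"].append(
                {"state": state, "run_id": stem, "trajectory": traj_path.name,
                 "ground_truth": gt_path.name, "n_frames": traj.n_frames,
                 "sha256": _file_hash(traj_path)}
            )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "spec.yaml", "w") as fh:
        yaml.safe_dump(base_spec.to_dict(), fh, sort_keys=True)
    return manifest


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def cmd_compare(
    free_files: Sequence[str | Path],
    bound_files: Sequence[str | Path],
    value_column: str,
) -> dict:
    """Compare a scalar column between two states across series CSV files.

    Returns the pooled StateComparison plus a per-run table. All files
    must share the value column; mismatching schemas are an error.
    """
    if not free_files or not bound_files:
        raise ValueError("need at least one file per state")

    def load(paths: Sequence[str | Path], state: str):
        frames = []
        for p in paths:
            df = pd.read_csv(p, comment="#")
            if df.empty:
                raise ValueError(f"{p}: empty series file")
            if value_column not in df.columns:
                raise ValueError(
                    f"{p}: missing column {value_column!r} "
                    f"(has {list(df.columns)})"
                )
            if "run_id" not in df.columns:
                df["run_id"] = Path(p).stem
            df["state"] = state
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    free = load(free_files, "free")
    bound = load(bound_files, "bound")
    pooled = compare_states(
        free[value_column].to_numpy(), bound[value_column].to_numpy()
    )
    per_run = []
    for df in (free, bound):
        for (state, run_id), grp in df.groupby(["state", "run_id"], sort=True):
            vals = grp[value_column].to_numpy()
            per_run.append(
                {"state": state, "run_id": run_id, "n": len(vals),
                 "mean": float(np.mean(vals)),
                 "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0}
            )
    return {"pooled": pooled.to_dict(), "per_run": per_run,
            "value_column": value_column}
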