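"""RMSD time series, per-residue RMSF profiles and run summaries.

RMSD(t) of a domain is computed after a least-squares fit of the
domain's own Cα atoms onto the reference (intra-domain deformation);
an alternative fit selection can be supplied to probe rigid-body
readings. RMSF(i) is the per-atom root-mean-square fluctuation about
the atom's time-averaged position, reported per residue through its
Cα atom. Run summaries provide per-run and pooled mean +/- SD plus
Tukey five-number boxplot statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .kinematics import kabsch_fit
from .structure_io import DomainSpec, Frame, Trajectory, select_domain

__all__ = [
    "RMSDSeries",
    "RMSFProfile",
    "BoxplotStats",
    "RunSummary",
    "rmsd_series",
    "rmsf_profile",
    "summarize_runs",
]


@dataclass(frozen=True)
class RMSDSeries:
    times: np.ndarray  # ns
    rmsd: np.ndarray  # nm
    domain: str
    run_id: str = ""
    state: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        rmsd = np.asarray(self.rmsd, dtype=float)
        if times.shape != rmsd.shape:
            raise ValueError("times and rmsd length mismatch")
        if np.any(rmsd < 0):
            raise ValueError("rmsd must be >= 0")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "rmsd", rmsd)

    def __len__(self) -> int:
        return len(self.rmsd)


@dataclass(frozen=True)
class RMSFProfile:
    """Per-residue RMSF (nm); labels are (chain, residue number, residue name)."""

    labels: tuple[tuple[str, int, str], ...]
    rmsf: np.ndarray  # nm
    run_id: str = ""
    state: str = ""

    def __post_init__(self) -> None:
        rmsf = np.asarray(self.rmsf, dtype=float)
        if len(rmsf) != len(self.labels):
            raise ValueError("labels and rmsf length mismatch")
        if np.any(rmsf < 0):
            raise ValueError("rmsf must be >= 0")
        object.__setattr__(self, "rmsf", rmsf)

    def __len__(self) -> int:
        return len(self.rmsf)


@dataclass(frozen=True)
class BoxplotStats:
    """Tukey five-number summary with 1.5*IQR whiskers and listed outliers."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


@dataclass(frozen=True)
class RunSummary:
    """Per-run and pooled mean +/- SD plus boxplot stats for one group of runs."""

    run_ids: tuple[str, ...]
    run_means: np.ndarray
    run_sds: np.ndarray
    run_ns: tuple[int, ...]
    pooled_mean: float
    pooled_sd: float
    pooled_n: int
    boxplots: tuple[BoxplotStats, ...]


def rmsd_series(
    traj: Trajectory,
    spec: DomainSpec,
    reference: Frame | None = None,
    fit_selection: np.ndarray | None = None,
    run_id: str = "",
    state: str = "",
) -> RMSDSeries:
    """Per-frame RMSD (nm) of a domain's Cα atoms vs a reference frame.

    For each analysis frame the fit selection (default: the domain's own
    Cα atoms) is least-squares fitted onto the reference, the fitted
    transform is applied, and the RMSD is the root of the mean squared
    atom displacement over the domain's N atoms. When the reference is
    the first frame (the default), the first value is exactly 0.
    """
    idx = select_domain(traj.topology, spec)
    if idx.size < 3:
        raise ValueError(
            f"domain {spec.name!r} has {idx.size} atoms; need >= 3 for the fit"
        )
    if reference is None:
        reference = traj.frames[0]
    fit_idx = idx if fit_selection is None else np.asarray(fit_selection, dtype=np.intp)
    ref_fit = reference.coordinates[fit_idx]
    ref_dom = reference.coordinates[idx]
    out = np.empty(traj.n_frames)
    for k, fr in enumerate(traj.frames):
        tf = kabsch_fit(fr.coordinates[fit_idx], ref_fit)
        fitted = tf.apply(fr.coordinates[idx])
        out[k] = np.sqrt(np.mean(np.sum((fitted - ref_dom) ** 2, axis=1)))
    return RMSDSeries(times=traj.times, rmsd=out, domain=spec.name,
                      run_id=run_id, state=state)


def rmsf_profile(
    traj: Trajectory,
    selection: np.ndarray,
    run_id: str = "",
    state: str = "",
) -> RMSFProfile:
    """Per-atom RMSF about the time-averaged position, labelled per residue.

    Assumes global motion has already been removed from the trajectory
    (caller responsibility). With Cα-only selections each label is one
    residue.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires >= 2 frames")
    selection = np.asarray(selection, dtype=np.intp)
    coords = traj.coordinate_array()[:, selection, :]  # (T, n, 3)
    mean_pos = coords.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((coords - mean_pos) ** 2, axis=2), axis=0))
    labels = tuple(
        (a.chain_id, a.residue_number, a.residue_name)
        for a in (traj.topology.atoms[i] for i in selection)
    )
    return RMSFProfile(labels=labels, rmsf=rmsf, run_id=run_id, state=state)


def _boxplot_stats(values: np.ndarray) -> BoxplotStats:
    values = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return BoxplotStats(
        minimum=float(values.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(values.max()),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(np.sort(outliers).tolist()),
    )


def summarize_runs(
    runs: Mapping[str, np.ndarray] | Sequence[tuple[str, np.ndarray]],
) -> RunSummary:
    """Per-run mean +/- SD, pooled mean +/- SD and boxplot stats.

    ``runs`` maps run ids to 1-D value arrays (e.g. one domain's RMSD
    series per run). Pooled statistics concatenate all runs; pooled n is
    the sum of per-run n.
    """
    items = list(runs.items()) if isinstance(runs, Mapping) else list(runs)
    if not items:
        raise ValueError("need at least one run")
    run_ids = tuple(rid for rid, _ in items)
    arrays = [np.asarray(v, dtype=float).ravel() for _, v in items]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("runs must be non-empty")
    run_means = np.array([a.mean() for a in arrays])
    run_sds = np.array(
        [np.std(a, ddof=1) if len(a) > 1 else 0.0 for a in arrays]
    )
    pooled = np.concatenate(arrays)
    return RunSummary(
        run_ids=run_ids,
        run_means=run_means,
        run_sds=run_sds,
        run_ns=tuple(len(a) for a in arrays),
        pooled_mean=float(pooled.mean()),
        pooled_sd=float(np.std(pooled, ddof=1)) if len(pooled) > 1 else 0.0,
        pooled_n=len(pooled),
        boxplots=tuple(_boxplot_stats(a) for a in arrays),
    )
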