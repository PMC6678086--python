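"""Rigid-body superposition and inter-domain distance series.

Global translational/rotational motion is removed by an SVD-based
least-squares fit (Kabsch) of a selection onto a reference frame.
Inter-domain distances are Euclidean distances between unweighted
geometric centers of the two domains' selected atoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import DomainSpec, Frame, Trajectory, select_domain

__all__ = [
    "RigidTransform",
    "DistanceSeries",
    "DegenerateFitError",
    "geometric_center",
    "kabsch_fit",
    "remove_global_motion",
    "interdomain_distance_series",
]

_ORTHO_TOL = 1e-10


class DegenerateFitError(ValueError):
    """The point configuration does not determine a unique rigid fit."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R x + t (rotation then translation)."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,), nm

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be (3,3), translation (3,)")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has negative determinant (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame distance (nm) between two named domains' geometric centers."""

    times: np.ndarray  # ns
    d: np.ndarray  # nm
    domain_a: str
    domain_b: str

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        d = np.asarray(self.d, dtype=float)
        if times.shape != d.shape:
            raise ValueError("times and d length mismatch")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "d", d)

    def __len__(self) -> int:
        return len(self.d)


def geometric_center(points: np.ndarray) -> np.ndarray:
    """Unweighted arithmetic mean of a set of 3-D coordinates."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 1:
        raise ValueError("need a non-empty (n, 3) coordinate array")
    return points.mean(axis=0)


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns the proper rigid transform minimizing
    ``sum_i |R m_i + t - r_i|^2`` over rotations R (det +1) and
    translations t, via SVD of the cross-covariance with reflection
    correction.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have equal shapes")
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinates must be (n, 3)")
    if mobile.shape[0] < 3:
        raise DegenerateFitError(
            f"need >= 3 points for a rigid fit, got {mobile.shape[0]}"
        )
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    M = mobile - cm
    Rf = reference - cr
    H = M.T @ Rf
    # collinear clouds leave a free rotation about the common axis
    if np.linalg.matrix_rank(M, tol=1e-9 * max(1.0, np.abs(M).max())) < 2:
        raise DegenerateFitError("mobile points are collinear; fit underdetermined")
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign if sign != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    return RigidTransform(R, t)


def remove_global_motion(
    traj: Trajectory,
    fit_selection: np.ndarray,
    reference: Frame,
) -> Trajectory:
    """Superpose every frame's ``fit_selection`` atoms onto the reference.

    The per-frame transform (fit of the selection) is applied to *all*
    atoms of the frame, removing global translation/rotation while
    preserving internal and inter-domain motion.
    """
    fit_selection = np.asarray(fit_selection, dtype=np.intp)
    if fit_selection.size < 3:
        raise DegenerateFitError("fit selection must contain >= 3 atoms")
    ref_coords = reference.coordinates[fit_selection]
    new_frames = []
    for k, fr in enumerate(traj.frames):
        try:
            tf = kabsch_fit(fr.coordinates[fit_selection], ref_coords)
        except DegenerateFitError as exc:
            raise DegenerateFitError(f"frame {k}: {exc}") from exc
        new_frames.append(Frame(fr.time, tf.apply(fr.coordinates)))
    return traj.with_frames(new_frames)


def interdomain_distance_series(
    traj: Trajectory,
    spec_a: DomainSpec,
    spec_b: DomainSpec,
) -> DistanceSeries:
    """Per-frame distance between the geometric centers of two domains.

    Invariant under any rigid transform applied to whole frames.
    """
    idx_a = select_domain(traj.topology, spec_a)
    idx_b = select_domain(traj.topology, spec_b)
    coords = traj.coordinate_array()
    centers_a = coords[:, idx_a, :].mean(axis=1)
    centers_b = coords[:, idx_b, :].mean(axis=1)
    d = np.linalg.norm(centers_a - centers_b, axis=1)
    return DistanceSeries(times=traj.times, d=d,
                          domain_a=spec_a.name, domain_b=spec_b.name)
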