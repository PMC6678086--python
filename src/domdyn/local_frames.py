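"""Per-frame PCA local coordinate frames for domains.

Each domain's Cα cloud in each frame yields a right-handed orthonormal
eigenvector triad (ordered by descending spatial variance) anchored at
the domain's geometric center. Eigenvector sign ambiguity is resolved in
two stages: a deterministic raw rule (largest-magnitude component made
positive), then standardization against the triad of a fixed reference
structure so that corresponding axes never flip sign between frames or
between independent runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .structure_io import DomainSpec, Frame, Topology, Trajectory, select_domain

__all__ = [
    "LocalFrame",
    "DegenerateCloudError",
    "NearDegenerateWarning",
    "pca_frame",
    "standardize_frame",
    "frame_series",
]

logger = logging.getLogger(__name__)

#: relative eigenvalue-gap threshold below which axes are poorly identified
NEAR_DEGENERACY_RTOL = 1e-3


class DegenerateCloudError(ValueError):
    """The point cloud is (near-)collinear; a PCA triad is not identifiable."""


class NearDegenerateWarning(UserWarning):
    """Two eigenvalues are nearly equal; the corresponding axes are unstable."""


@dataclass(frozen=True)
class LocalFrame:
    """Right-handed orthonormal PCA triad + origin + eigenvalues for a domain.

    ``axes`` rows are v1, v2, v3 ordered by descending eigenvalue.
    """

    origin: np.ndarray  # (3,) nm
    axes: np.ndarray  # (3, 3), rows v1, v2, v3
    eigenvalues: np.ndarray  # (3,), nm^2, descending
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float)
        axes = np.asarray(self.axes, dtype=float)
        evals = np.asarray(self.eigenvalues, dtype=float)
        if axes.shape != (3, 3) or origin.shape != (3,) or evals.shape != (3,):
            raise ValueError("bad shapes for LocalFrame fields")
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-8):
            raise ValueError("axes are not orthonormal")
        if np.dot(np.cross(axes[0], axes[1]), axes[2]) <= 0:
            raise ValueError("axes are not right-handed")
        if not (evals[0] >= evals[1] >= evals[2] >= -1e-12):
            raise ValueError("eigenvalues must be descending and non-negative")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "eigenvalues", np.maximum(evals, 0.0))

    @property
    def v1(self) -> np.ndarray:
        return self.axes[0]

    @property
    def v2(self) -> np.ndarray:
        return self.axes[1]

    @property
    def v3(self) -> np.ndarray:
        return self.axes[2]


def _raw_sign(vec: np.ndarray) -> np.ndarray:
    """Flip so the largest-magnitude component is positive (tie: first such)."""
    idx = int(np.argmax(np.abs(vec)))
    return -vec if vec[idx] < 0 else vec


def pca_frame(coords: np.ndarray) -> LocalFrame:
    """PCA triad of one domain's coordinates in one frame.

    Eigen-decomposes the 3x3 covariance (1/N normalization) of the
    centered coordinates. Eigenvectors are sorted by descending
    eigenvalue, sign-fixed by the raw rule, and v3 is recomputed as
    v1 x v2 to guarantee a right-handed triad.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 3:
        raise ValueError("need >= 3 points of shape (n, 3)")
    origin = coords.mean(axis=0)
    X = coords - origin
    cov = (X.T @ X) / X.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order].T  # rows = eigenvectors, descending eigenvalue
    if evals[1] <= 1e-12 * max(evals[0], 1e-300) or evals[0] <= 0:
        raise DegenerateCloudError(
            "point cloud is collinear or degenerate (lambda_2 ~ 0); "
            "PCA axes are not identifiable"
        )
    frame_warnings: list[str] = []
    for i in range(2):
        if evals[i] - evals[i + 1] < NEAR_DEGENERACY_RTOL * evals[0]:
            msg = (
                f"eigenvalues {i + 1} and {i + 2} nearly degenerate "
                f"(gap {evals[i] - evals[i + 1]:.3e} < "
                f"{NEAR_DEGENERACY_RTOL:g}*lambda_1); axes unstable"
            )
            frame_warnings.append(msg)
            warnings.warn(msg, NearDegenerateWarning, stacklevel=2)
    v1 = _raw_sign(evecs[0])
    v2 = _raw_sign(evecs[1])
    v3 = np.cross(v1, v2)
    return LocalFrame(
        origin=origin,
        axes=np.array([v1, v2, v3]),
        eigenvalues=evals,
        warnings=tuple(frame_warnings),
    )


def standardize_frame(frame: LocalFrame, reference: LocalFrame) -> LocalFrame:
    """Re-orient a triad against a reference so corresponding axes agree in sign.

    v1 and v2 are independently flipped so that dot(v_i, v_i_ref) >= 0;
    v3 is then rebuilt as v1 x v2, restoring right-handedness.
    Eigenvalues are unchanged. An exactly-zero dot product keeps the raw
    sign (logged). Idempotent.
    """
    v1, v2 = frame.axes[0].copy(), frame.axes[1].copy()
    for i, v in enumerate((v1, v2)):
        dot = float(np.dot(v, reference.axes[i]))
        if dot < 0:
            v *= -1.0
        elif dot == 0.0:
            logger.info(
                "standardize_frame: axis %d exactly orthogonal to reference; "
                "raw sign kept", i + 1,
            )
    v3 = np.cross(v1, v2)
    return LocalFrame(
        origin=frame.origin,
        axes=np.array([v1, v2, v3]),
        eigenvalues=frame.eigenvalues,
        warnings=frame.warnings,
    )


def frame_series(
    traj: Trajectory,
    spec: DomainSpec,
    reference_structure: Frame,
    reference_topology: Topology | None = None,
) -> list[LocalFrame]:
    """Standardized per-frame local frames of one domain along a trajectory.

    The reference triad is computed once from ``reference_structure``
    (typically the crystal structure) with the raw sign rule; every
    trajectory frame's triad is standardized against it, which keeps axes
    comparable across frames and across independent runs.
    """
    idx = select_domain(traj.topology, spec)
    ref_top = reference_topology if reference_topology is not None else traj.topology
    ref_idx = select_domain(ref_top, spec)
    ref_frame = pca_frame(reference_structure.coordinates[ref_idx])
    out: list[LocalFrame] = []
    for k, fr in enumerate(traj.frames):
        try:
            lf = pca_frame(fr.coordinates[idx])
        except DegenerateCloudError as exc:
            raise DegenerateCloudError(f"frame {k}: {exc}") from exc
        out.append(standardize_frame(lf, ref_frame))
    return out


def reference_frame_for(
    spec: DomainSpec,
    reference_structure: Frame,
    reference_topology: Topology,
) -> LocalFrame:
    """The raw-sign reference triad of a domain in the reference structure."""
    idx = select_domain(reference_topology, spec)
    return pca_frame(reference_structure.coordinates[idx])
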