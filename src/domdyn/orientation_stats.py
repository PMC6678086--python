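"""Inter-domain orientation angles and bound-vs-free comparisons.

The relative orientation of two domains is tracked through the angles
between corresponding eigenvectors of their standardized local frames:
alpha between (v1, w1), beta between (v2, w2), gamma between (v3, w3).
Angles use the signed (standardized) cosine, so they range over
[0, 180] degrees. Two ensembles are compared descriptively through
means, sample standard deviations and the exact two-sample
Kolmogorov-Smirnov statistic D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .local_frames import LocalFrame

__all__ = [
    "OrientationSeries",
    "KSResult",
    "StateComparison",
    "pair_angles",
    "orientation_series",
    "ks_two_sample",
    "compare_states",
    "angle_histogram",
]


@dataclass(frozen=True)
class OrientationSeries:
    """Per-frame angles (degrees) between corresponding domain eigenvectors."""

    times: np.ndarray  # ns
    alpha: np.ndarray  # deg, angle(v1, w1)
    beta: np.ndarray  # deg, angle(v2, w2)
    gamma: np.ndarray  # deg, angle(v3, w3)
    domain_a: str
    domain_b: str

    def __post_init__(self) -> None:
        arrays = {}
        n = None
        for name in ("times", "alpha", "beta", "gamma"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if n is None:
                n = len(arr)
            elif len(arr) != n:
                raise ValueError("series length mismatch")
            arrays[name] = arr
        for name in ("alpha", "beta", "gamma"):
            a = arrays[name]
            if np.any((a < 0) | (a > 180)):
                raise ValueError(f"{name} outside [0, 180] degrees")
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.times)

    def channel(self, name: str) -> np.ndarray:
        if name not in ("alpha", "beta", "gamma"):
            raise KeyError(name)
        return getattr(self, name)


@dataclass(frozen=True)
class KSResult:
    """Exact two-sample Kolmogorov-Smirnov statistic and sample sizes."""

    D: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.D <= 1.0):
            raise ValueError(f"D = {self.D} outside [0, 1]")


@dataclass(frozen=True)
class StateComparison:
    """Free-vs-bound summary for one scalar series: means, SDs, KS D."""

    mean_free: float
    sd_free: float
    mean_bound: float
    sd_bound: float
    ks: KSResult

    def __post_init__(self) -> None:
        if self.sd_free < 0 or self.sd_bound < 0:
            raise ValueError("standard deviations must be >= 0")

    def to_dict(self) -> dict:
        return {
            "mean_free": self.mean_free,
            "sd_free": self.sd_free,
            "mean_bound": self.mean_bound,
            "sd_bound": self.sd_bound,
            "ks_D": self.ks.D,
            "n_free": self.ks.n1,
            "n_bound": self.ks.n2,
        }


def pair_angles(frame_a: LocalFrame, frame_b: LocalFrame) -> tuple[float, float, float]:
    """Angles (deg) between corresponding eigenvectors of two local frames.

    angle_i = arccos(clamp(dot(v_i, w_i), -1, 1)), evaluated through the
    numerically equivalent atan2(|v_i x w_i|, v_i . w_i) form, which
    stays accurate for angles near 0 and 180 degrees. Uses the signed
    cosine of the standardized axes, not its absolute value. Symmetric
    in its arguments.
    """
    cos = np.clip(np.einsum("ij,ij->i", frame_a.axes, frame_b.axes), -1.0, 1.0)
    sin = np.linalg.norm(np.cross(frame_a.axes, frame_b.axes), axis=1)
    ang = np.degrees(np.arctan2(sin, cos))
    return float(ang[0]), float(ang[1]), float(ang[2])


def orientation_series(
    frames_a: Sequence[LocalFrame],
    frames_b: Sequence[LocalFrame],
    times: np.ndarray | Sequence[float] | None = None,
    domain_a: str = "A",
    domain_b: str = "B",
) -> OrientationSeries:
    """Elementwise :func:`pair_angles` over two matched local-frame series."""
    if len(frames_a) != len(frames_b):
        raise ValueError(
            f"series length mismatch: {len(frames_a)} vs {len(frames_b)}"
        )
    if times is None:
        times = np.arange(len(frames_a), dtype=float)
    angles = np.array([pair_angles(a, b) for a, b in zip(frames_a, frames_b)])
    angles = angles.reshape(-1, 3)
    return OrientationSeries(
        times=np.asarray(times, dtype=float),
        alpha=angles[:, 0],
        beta=angles[:, 1],
        gamma=angles[:, 2],
        domain_a=domain_a,
        domain_b=domain_b,
    )


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> KSResult:
    """Exact two-sample KS statistic D = sup |ECDF_x - ECDF_y|.

    The supremum is taken over the pooled sample points with
    right-continuous ECDFs; no asymptotic approximation is involved,
    so D is an exact ratio of integers.
    """
    x = np.sort(np.asarray(x, dtype=float).ravel())
    y = np.sort(np.asarray(y, dtype=float).ravel())
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / n1
    cdf_y = np.searchsorted(y, pooled, side="right") / n2
    D = float(np.max(np.abs(cdf_x - cdf_y)))
    return KSResult(D=D, n1=n1, n2=n2)


def compare_states(
    free_values: np.ndarray,
    bound_values: np.ndarray,
) -> StateComparison:
    """Means, sample SDs (n-1 denominator) and KS D for free vs bound samples."""
    free = np.asarray(free_values, dtype=float).ravel()
    bound = np.asarray(bound_values, dtype=float).ravel()
    if len(free) < 1 or len(bound) < 1:
        raise ValueError("both samples must be non-empty")

    def _sd(a: np.ndarray) -> float:
        if len(a) < 2:
            warnings.warn(
                "single-element sample: SD reported as 0", UserWarning,
                stacklevel=3,
            )
            return 0.0
        return float(np.std(a, ddof=1))

    return StateComparison(
        mean_free=float(np.mean(free)),
        sd_free=_sd(free),
        mean_bound=float(np.mean(bound)),
        sd_bound=_sd(bound),
        ks=ks_two_sample(free, bound),
    )


def angle_histogram(
    values: np.ndarray,
    bin_width_deg: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of angle values over [0, 180] deg with half-open bins [a, b).

    The last bin is closed so 180 deg is counted. Returns
    (bin_edges, counts) with len(edges) == len(counts) + 1.
    """
    if bin_width_deg <= 0:
        raise ValueError("bin width must be positive")
    values = np.asarray(values, dtype=float).ravel()
    n_bins = int(np.ceil(180.0 / bin_width_deg))
    edges = np.arange(n_bins + 1) * bin_width_deg
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts
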