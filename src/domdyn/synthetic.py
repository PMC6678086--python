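"""Synthetic two-domain Cα trajectories with exact ground truth.

Generates trajectories of two quasi-rigid anisotropic Gaussian point
clouds ("domains") with prescribed center-to-center distance dynamics,
prescribed relative rotation of domain B about a chosen principal axis
(constant, sinusoidal, or Ornstein-Uhlenbeck), i.i.d. per-coordinate
Gaussian jitter, and an optional soft "breathing" deformation. The true
noise-free distance and relative-orientation angles are recorded per
frame, so every downstream analysis stage can be tested closed-loop.

Base clouds are rotated into their exact sample principal axes at
generation time, which makes the reference PCA triads exactly the lab
axes and the ground-truth angles exact functions of the applied
rotation matrix.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structure_io import AtomRecord, Frame, Topology, Trajectory

__all__ = [
    "ConstantModel",
    "SinusoidModel",
    "OUModel",
    "BreathingSpec",
    "MotionSpec",
    "GroundTruth",
    "make_base_clouds",
    "make_reference",
    "generate",
    "make_state_ensemble",
    "BOUND_ROTATION",
    "FREE_ROTATION",
]

#: minimum ratio between successive principal SDs; keeps PCA identifiable
MIN_ANISOTROPY_RATIO = 1.5


@dataclass(frozen=True)
class ConstantModel:
    """x(t) = value."""

    value: float

    @property
    def baseline(self) -> float:
        return self.value

    @property
    def stationary_sd(self) -> float:
        return 0.0

    def sample(self, times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return np.full(len(times), self.value)


@dataclass(frozen=True)
class SinusoidModel:
    """x(t) = base + amplitude * sin(2 pi t / period)."""

    base: float
    amplitude: float
    period: float  # ns

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("sinusoid period must be > 0")

    @property
    def baseline(self) -> float:
        return self.base

    @property
    def stationary_sd(self) -> float:
        return abs(self.amplitude) / np.sqrt(2.0)

    def sample(self, times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return self.base + self.amplitude * np.sin(2 * np.pi * times / self.period)


@dataclass(frozen=True)
class OUModel:
    """Stationary Ornstein-Uhlenbeck process (mean, relaxation time, SD).

    Sampled with the exact discrete-time update
    x_{k+1} = mean + (x_k - mean) rho + sd sqrt(1 - rho^2) z_k,
    rho = exp(-dt / tau), started from the stationary distribution.
    """

    mean: float
    tau: float  # ns
    sd: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("OU relaxation time must be > 0")
        if self.sd < 0:
            raise ValueError("OU stationary SD must be >= 0")

    @property
    def baseline(self) -> float:
        return self.mean

    @property
    def stationary_sd(self) -> float:
        return self.sd

    def sample(self, times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        n = len(times)
        x = np.empty(n)
        x[0] = self.mean + self.sd * rng.standard_normal()
        if n > 1:
            dts = np.diff(times)
            z = rng.standard_normal(n - 1)
            for k in range(n - 1):
                rho = np.exp(-dts[k] / self.tau)
                x[k + 1] = (
                    self.mean
                    + (x[k] - self.mean) * rho
                    + self.sd * np.sqrt(1.0 - rho * rho) * z[k]
                )
        return x


MotionModel = ConstantModel | SinusoidModel | OUModel


@dataclass(frozen=True)
class BreathingSpec:
    """Sinusoidal scaling of one principal axis of one domain (soft deformation)."""

    domain: int  # 0 = A, 1 = B
    axis: int  # 0, 1, 2 (principal axis index)
    amplitude: float  # fractional, e.g. 0.1 -> +/-10 % scaling
    period: float  # ns

    def __post_init__(self) -> None:
        if self.domain not in (0, 1) or self.axis not in (0, 1, 2):
            raise ValueError("breathing domain must be 0/1, axis 0/1/2")
        if self.period <= 0:
            raise ValueError("breathing period must be > 0")


_AXIS_NAMES = {"v1": 0, "v2": 1, "v3": 2}


@dataclass(frozen=True)
class MotionSpec:
    """Full parameterization of a synthetic two-domain trajectory."""

    n_atoms: tuple[int, int] = (120, 120)
    shape_sds: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (0.9, 0.6, 0.3),
        (0.9, 0.6, 0.3),
    )
    distance_model: MotionModel = ConstantModel(2.5)
    rotation_model: MotionModel = ConstantModel(0.0)  # degrees
    rotation_axis: str | tuple[float, float, float] = "v1"
    jitter_sd: float = 0.0  # nm, per coordinate
    duration: float = 40.0  # ns
    output_interval: float = 0.04  # ns
    seed: int = 0
    #: seed for the base clouds only; defaults to ``seed``. Ensemble runs
    #: share one cloud_seed (same molecule) while differing in motion seed.
    cloud_seed: int | None = None
    separation_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    breathing: BreathingSpec | None = None

    def __post_init__(self) -> None:
        errors = []
        if any(n < 4 for n in self.n_atoms):
            errors.append(f"n_atoms: need >= 4 atoms per domain, got {self.n_atoms}")
        for d, sds in enumerate(self.shape_sds):
            if any(s < 0 for s in sds):
                errors.append(f"shape_sds[{d}]: SDs must be >= 0")
            for i in range(2):
                if sds[i + 1] <= 0 or sds[i] / sds[i + 1] < MIN_ANISOTROPY_RATIO:
                    errors.append(
                        f"shape_sds[{d}]: axes {i + 1}/{i + 2} ratio "
                        f"{sds[i]}/{sds[i + 1]} < {MIN_ANISOTROPY_RATIO} "
                        "(near-isotropic clouds break eigenvector identifiability)"
                    )
        if self.jitter_sd < 0:
            errors.append("jitter_sd: must be >= 0")
        if self.duration <= 0:
            errors.append("duration: must be > 0")
        if self.output_interval <= 0:
            errors.append("output_interval: must be > 0")
        if isinstance(self.rotation_axis, str):
            if self.rotation_axis not in _AXIS_NAMES:
                errors.append(
                    f"rotation_axis: {self.rotation_axis!r} not one of "
                    f"{sorted(_AXIS_NAMES)} or a 3-vector"
                )
        elif abs(np.linalg.norm(self.rotation_axis)) < 1e-12:
            errors.append("rotation_axis: zero vector")
        if errors:
            raise ValueError("invalid MotionSpec: " + "; ".join(errors))

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.duration / self.output_interval + 1e-9))

    @property
    def times(self) -> np.ndarray:
        # frames at k * interval for k = 1..N (no frame at t = 0)
        return (np.arange(self.n_frames) + 1) * self.output_interval

    def axis_vector(self) -> np.ndarray:
        if isinstance(self.rotation_axis, str):
            v = np.zeros(3)
            v[_AXIS_NAMES[self.rotation_axis]] = 1.0
            return v
        v = np.asarray(self.rotation_axis, dtype=float)
        return v / np.linalg.norm(v)

    def to_dict(self) -> dict:
        def model_dict(m: MotionModel) -> dict:
            d = dataclasses.asdict(m)
            d["kind"] = type(m).__name__.removesuffix("Model").lower()
            return d

        out = dataclasses.asdict(self)
        out["distance_model"] = model_dict(self.distance_model)
        out["rotation_model"] = model_dict(self.rotation_model)
        if self.breathing is not None:
            out["breathing"] = dataclasses.asdict(self.breathing)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "MotionSpec":
        def model_from(md: dict) -> MotionModel:
            md = dict(md)
            kind = md.pop("kind")
            table = {"constant": ConstantModel, "sinusoid": SinusoidModel,
                     "ou": OUModel}
            return table[kind](**md)

        d = dict(d)
        d["n_atoms"] = tuple(d["n_atoms"])
        d["shape_sds"] = tuple(tuple(s) for s in d["shape_sds"])
        d["distance_model"] = model_from(d["distance_model"])
        d["rotation_model"] = model_from(d["rotation_model"])
        if isinstance(d.get("rotation_axis"), list):
            d["rotation_axis"] = tuple(d["rotation_axis"])
        if isinstance(d.get("separation_axis"), list):
            d["separation_axis"] = tuple(d["separation_axis"])
        if d.get("breathing"):
            d["breathing"] = BreathingSpec(**d["breathing"])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free per-frame truth recorded alongside a generated trajectory."""

    times: np.ndarray  # ns
    distance: np.ndarray  # nm
    angles: np.ndarray  # (n, 3) deg: alpha, beta, gamma
    base_cloud_a: np.ndarray
    base_cloud_b: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


def _rngs(seed: int) -> tuple[np.random.Generator, ...]:
    """Three independent streams (clouds, motion, jitter) from one seed."""
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _principalize(cloud: np.ndarray) -> np.ndarray:
    """Rotate a centered cloud into its exact sample principal axes.

    Afterwards the sample covariance is diagonal with descending
    variance, so the cloud's raw-sign PCA triad is exactly the lab
    basis e1, e2, e3.
    """
    cloud = cloud - cloud.mean(axis=0)
    cov = cloud.T @ cloud / len(cloud)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    if np.linalg.det(evecs) < 0:
        evecs[:, 2] *= -1.0
    out = cloud @ evecs
    return out - out.mean(axis=0)


def make_base_clouds(
    spec: MotionSpec, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the two anisotropic Gaussian base clouds, reproducibly.

    Each cloud is centered and rotated into its exact principal axes, so
    its PCA triad equals the identity and its principal variances are
    the exact sample variances along x, y, z (descending).
    """
    if seed is None:
        seed = spec.cloud_seed if spec.cloud_seed is not None else spec.seed
    rng_clouds = _rngs(seed)[0]
    clouds = []
    for n, sds in zip(spec.n_atoms, spec.shape_sds):
        raw = rng_clouds.normal(0.0, 1.0, size=(n, 3)) * np.asarray(sds)
        clouds.append(_principalize(raw))
    return clouds[0], clouds[1]


def _two_domain_topology(n_a: int, n_b: int) -> Topology:
    atoms = [
        AtomRecord(chain_id="A", residue_number=i + 1, residue_name="ALA",
                   atom_name="CA", element="C")
        for i in range(n_a)
    ] + [
        AtomRecord(chain_id="B", residue_number=i + 1, residue_name="ALA",
                   atom_name="CA", element="C")
        for i in range(n_b)
    ]
    return Topology(tuple(atoms))


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    th = np.radians(angle_deg)
    k = axis
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def make_reference(spec: MotionSpec) -> tuple[Topology, Frame]:
    """Noise-free reference configuration (plays the crystal-structure role).

    Domain A at the origin, domain B at the distance model's baseline
    along the separation axis, zero relative rotation.
    """
    cloud_a, cloud_b = make_base_clouds(spec)
    sep = np.asarray(spec.separation_axis, dtype=float)
    sep = sep / np.linalg.norm(sep)
    coords = np.vstack([cloud_a, cloud_b + spec.distance_model.baseline * sep])
    top = _two_domain_topology(*spec.n_atoms)
    return top, Frame(time=0.0, coordinates=coords)


def generate(spec: MotionSpec) -> tuple[Trajectory, GroundTruth]:
    """Generate a trajectory and its exact ground truth from a MotionSpec.

    Frames sit at times k * output_interval for k = 1..N. Per frame,
    domain B's base cloud is rotated by the model angle about the chosen
    axis and placed at the model distance along the separation axis;
    i.i.d. Gaussian jitter of SD ``jitter_sd`` is then added to every
    coordinate of both domains. Ground truth records the noise-free
    distance and the angles between corresponding domain axes.
    """
    _, rng_motion, rng_jitter = _rngs(spec.seed)
    cloud_a, cloud_b = make_base_clouds(spec)
    times = spec.times
    n = spec.n_frames
    distances = spec.distance_model.sample(times, rng_motion)
    thetas = spec.rotation_model.sample(times, rng_motion)
    if np.any(distances < 0):
        raise ValueError("distance model produced negative distances")
    axis = spec.axis_vector()
    sep = np.asarray(spec.separation_axis, dtype=float)
    sep = sep / np.linalg.norm(sep)

    angles = np.empty((n, 3))
    frames = []
    n_a = spec.n_atoms[0]
    for k in range(n):
        a_k, b_k = cloud_a, cloud_b
        if spec.breathing is not None:
            br = spec.breathing
            scale = 1.0 + br.amplitude * np.sin(2 * np.pi * times[k] / br.period)
            target = a_k if br.domain == 0 else b_k
            scaled = target.copy()
            scaled[:, br.axis] *= scale
            if br.domain == 0:
                a_k = scaled
            else:
                b_k = scaled
        R = _rotation_matrix(axis, thetas[k])
        # domain axes are e1,e2,e3; rotated axes are R e_i -> angle_i = acos(R_ii)
        angles[k] = np.degrees(np.arccos(np.clip(np.diag(R), -1.0, 1.0)))
        b_placed = b_k @ R.T + distances[k] * sep
        coords = np.vstack([a_k, b_placed])
        if spec.jitter_sd > 0:
            coords = coords + rng_jitter.normal(0.0, spec.jitter_sd, coords.shape)
        frames.append(Frame(time=times[k], coordinates=coords))

    top = _two_domain_topology(*spec.n_atoms)
    traj = Trajectory(top, tuple(frames))
    truth = GroundTruth(
        times=times,
        distance=distances,
        angles=angles,
        base_cloud_a=cloud_a,
        base_cloud_b=cloud_b,
    )
    return traj, truth


#: default rotation models emulating the bound/free contrast:
#: bound-like ensembles rotate with small variance, free-like with large
BOUND_ROTATION = OUModel(mean=63.0, tau=2.0, sd=2.0)
FREE_ROTATION = OUModel(mean=57.0, tau=2.0, sd=6.0)

_STATE_CODES = {"bound": 0, "free": 1}


def derive_run_seed(master_seed: int, state: str, run_index: int) -> int:
    """Deterministic per-run seed: SeedSequence([master, state code, index])."""
    code = _STATE_CODES[state]
    ss = np.random.SeedSequence([master_seed, code, run_index])
    return int(ss.generate_state(1)[0])


def make_state_ensemble(
    state: str,
    n_runs: int,
    base_spec: MotionSpec | None = None,
    master_seed: int = 0,
) -> list[tuple[Trajectory, GroundTruth]]:
    """Generate a bound-like or free-like ensemble of independent runs.

    "bound" substitutes the low-variance rotation model, "free" the
    high-variance one; all shape/distance parameters are shared. Run
    seeds derive deterministically from the master seed; the base clouds
    are pinned to the base spec's cloud seed so every run is the same
    pair of molecules (matching the shared reference structure), only
    the motion and jitter differ.
    """
    if state not in _STATE_CODES:
        raise ValueError(f"unknown state {state!r}; expected 'bound' or 'free'")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if base_spec is None:
        base_spec = MotionSpec()
    rotation = BOUND_ROTATION if state == "bound" else FREE_ROTATION
    shared_cloud_seed = (
        base_spec.cloud_seed if base_spec.cloud_seed is not None
        else base_spec.seed
    )
    out = []
    for i in range(n_runs):
        spec_i = dataclasses.replace(
            base_spec,
            rotation_model=rotation,
            seed=derive_run_seed(master_seed, state, i),
            cloud_seed=shared_cloud_seed,
        )
        out.append(generate(spec_i))
    return out


def ensemble_spec(
    state: str, base_spec: MotionSpec | None = None
) -> MotionSpec:
    """The MotionSpec shape used for one run of a state ensemble (seed 0)."""
    if base_spec is None:
        base_spec = MotionSpec()
    rotation = BOUND_ROTATION if state == "bound" else FREE_ROTATION
    return dataclasses.replace(base_spec, rotation_model=rotation)
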