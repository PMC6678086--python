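import numpy as np
import pytest

from domdyn.structure_io import AtomRecord, DomainSpec, Frame, Topology, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_ca_topology(n_residues: int, chain_id: str = "A") -> Topology:
    """One CA atom per residue, residues numbered 1..n."""
    return Topology(tuple(
        AtomRecord(chain_id=chain_id, residue_number=i + 1,
                   residue_name="GLY", atom_name="CA", element="C")
        for i in range(n_residues)
    ))


def make_two_chain_topology(n_a: int, n_b: int) -> Topology:
    atoms = []
    for chain, n in (("A", n_a), ("B", n_b)):
        for i in range(n):
            atoms.append(AtomRecord(chain_id=chain, residue_number=i + 1,
                                    residue_name="ALA", atom_name="CA",
                                    element="C"))
    return Topology(tuple(atoms))


def make_trajectory(coords_per_frame, topology=None, dt: float = 0.04) -> Trajectory:
    """Build a trajectory from an iterable of (n_atoms, 3) arrays."""
    coords_per_frame = [np.asarray(c, dtype=float) for c in coords_per_frame]
    if topology is None:
        topology = make_ca_topology(coords_per_frame[0].shape[0])
    frames = tuple(
        Frame(time=(k + 1) * dt, coordinates=c)
        for k, c in enumerate(coords_per_frame)
    )
    return Trajectory(topology, frames)


def random_rotation(rng: np.random.Generator, max_angle_deg: float = 180.0):
    """Uniform random axis, uniform angle in (0, max_angle]."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_angle_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


@pytest.fixture
def anisotropic_cloud(rng):
    """A well-conditioned 80-point cloud with distinct principal variances."""
    return rng.normal(size=(80, 3)) * np.array([0.9, 0.5, 0.2])
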