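import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from domdyn.kinematics import (
    DegenerateFitError,
    RigidTransform,
    geometric_center,
    interdomain_distance_series,
    kabsch_fit,
    remove_global_motion,
)
from domdyn.structure_io import DomainSpec, Frame
from domdyn.synthetic import ConstantModel, MotionSpec, SinusoidModel, generate

from conftest import make_trajectory, make_two_chain_topology, random_rotation


class TestGeometricCenter:
    def test_two_points(self):
        c = geometric_center(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        np.testing.assert_allclose(c, [1.0, 0, 0])

    def test_single_point_identity(self):
        p = np.array([[1.5, -2.0, 0.25]])
        np.testing.assert_allclose(geometric_center(p), p[0])

    def test_matches_bruteforce_mean(self, rng):
        pts = rng.uniform(size=(100, 3))
        # independent oracle: componentwise sum / n
        oracle = np.array([sum(pts[:, j]) / len(pts) for j in range(3)])
        np.testing.assert_allclose(geometric_center(pts), oracle, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            geometric_center(np.empty((0, 3)))


def _objective(params, mobile, reference):
    R = Rotation.from_rotvec(params[:3]).as_matrix()
    t = params[3:]
    return np.sum((mobile @ R.T + t - reference) ** 2)


class TestKabschFit:
    def test_identity(self, anisotropic_cloud):
        tf = kabsch_fit(anisotropic_cloud, anisotropic_cloud)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-10)

    def test_exact_recovery_90deg(self, anisotropic_cloud):
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = anisotropic_cloud @ Rz.T + np.array([1.0, 2.0, 3.0])
        tf = kabsch_fit(mobile, anisotropic_cloud)
        residual = tf.apply(mobile) - anisotropic_cloud
        assert np.abs(residual).max() <= 1e-10

    def test_noisy_matches_numeric_minimizer(self, rng, anisotropic_cloud):
        # oracle: brute-force numerical minimization of the LSQ objective
        reference = anisotropic_cloud + rng.normal(0, 0.01, anisotropic_cloud.shape)
        tf = kabsch_fit(anisotropic_cloud, reference)
        fitted = tf.apply(anisotropic_cloud)
        rmsd_impl = np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1)))
        x0 = np.concatenate([
            Rotation.from_matrix(tf.rotation).as_rotvec() + 0.05,
            tf.translation + 0.05,
        ])
        res = minimize(_objective, x0, args=(anisotropic_cloud, reference),
                       method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 20000, "maxfev": 20000})
        rmsd_oracle = np.sqrt(res.fun / len(anisotropic_cloud))
        assert abs(rmsd_impl - rmsd_oracle) <= 1e-6
        assert rmsd_impl <= rmsd_oracle + 1e-9  # exact solution is never worse

    def test_reflection_corrected(self, rng, anisotropic_cloud):
        # mirror image: best proper rotation must still have det +1
        mirrored = anisotropic_cloud * np.array([-1.0, 1.0, 1.0])
        tf = kabsch_fit(mirrored, anisotropic_cloud)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_too_few_points(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(DegenerateFitError, match="3 points"):
            kabsch_fit(pts, pts)

    def test_collinear_rejected(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(DegenerateFitError, match="collinear"):
            kabsch_fit(pts, pts)

    def test_objective_not_worse_than_identity(self, rng):
        for _ in range(10):
            a = rng.normal(size=(12, 3))
            b = rng.normal(size=(12, 3))
            tf = kabsch_fit(a, b)
            fit_obj = np.sum((tf.apply(a) - b) ** 2)
            id_obj = np.sum((a - b) ** 2)
            assert fit_obj <= id_obj + 1e-12


class TestRigidTransform:
    def test_orthonormality_enforced(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_reflection_rejected(self):
        R = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            RigidTransform(R, np.zeros(3))

    def test_inverse_roundtrip(self, rng):
        R = random_rotation(rng)
        tf = RigidTransform(R, rng.normal(size=3))
        pts = rng.normal(size=(7, 3))
        np.testing.assert_allclose(tf.inverse().apply(tf.apply(pts)), pts,
                                   atol=1e-12)


class TestRemoveGlobalMotion:
    def _rigid_traj(self, rng, cloud, n_frames=6):
        frames = []
        for _ in range(n_frames):
            R = random_rotation(rng)
            t = rng.normal(size=3)
            frames.append(cloud @ R.T + t)
        return make_trajectory(frames)

    def test_rigid_copies_restored(self, rng, anisotropic_cloud):
        traj = self._rigid_traj(rng, anisotropic_cloud)
        sel = np.arange(len(anisotropic_cloud))
        ref = Frame(0.0, anisotropic_cloud)
        out = remove_global_motion(traj, sel, ref)
        for fr in out.frames:
            assert np.abs(fr.coordinates - anisotropic_cloud).max() <= 1e-10

    def test_identity_on_aligned(self, anisotropic_cloud):
        traj = make_trajectory([anisotropic_cloud] * 3)
        out = remove_global_motion(traj, np.arange(len(anisotropic_cloud)),
                                   Frame(0.0, anisotropic_cloud))
        for fr, orig in zip(out.frames, traj.frames):
            np.testing.assert_allclose(fr.coordinates, orig.coordinates,
                                       atol=1e-12)

    def test_idempotent(self, rng, anisotropic_cloud):
        traj = self._rigid_traj(rng, anisotropic_cloud)
        sel = np.arange(len(anisotropic_cloud))
        ref = Frame(0.0, anisotropic_cloud)
        once = remove_global_motion(traj, sel, ref)
        twice = remove_global_motion(once, sel, ref)
        for a, b in zip(once.frames, twice.frames):
            assert np.abs(a.coordinates - b.coordinates).max() <= 1e-10

    def test_fit_on_domain_a_preserves_relative_motion(self, rng):
        # two-domain generator truth: fitting on A leaves the B-relative
        # distance series equal to ground truth
        spec = MotionSpec(
            n_atoms=(40, 40), duration=2.0, output_interval=0.1,
            distance_model=SinusoidModel(2.5, 0.1, 1.0), seed=7,
        )
        traj, truth = generate(spec)
        # scramble with per-frame global rigid motions first
        frames = []
        for fr in traj.frames:
            R = random_rotation(rng)
            frames.append(fr.coordinates @ R.T + rng.normal(size=3))
        scrambled = traj.with_frames(
            [type(fr)(fr.time, c) for fr, c in zip(traj.frames, frames)]
        )
        sel_a = np.arange(40)
        ref = traj.frames[0]
        out = remove_global_motion(scrambled, sel_a, ref)
        a = DomainSpec("A", "A", ((1, 40),))
        b = DomainSpec("B", "B", ((1, 40),))
        ds = interdomain_distance_series(out, a, b)
        np.testing.assert_allclose(ds.d, truth.distance, atol=1e-9)
        # domain A itself is stationary after the fit
        for fr in out.frames:
            assert np.abs(fr.coordinates[sel_a] -
                          traj.frames[0].coordinates[sel_a]).max() <= 1e-8

    def test_small_selection_rejected(self, anisotropic_cloud):
        traj = make_trajectory([anisotropic_cloud])
        with pytest.raises(DegenerateFitError):
            remove_global_motion(traj, np.array([0, 1]),
                                 Frame(0.0, anisotropic_cloud))


class TestDistanceSeries:
    def _two_atom_traj(self, pa, pb):
        top = make_two_chain_topology(1, 1)
        return make_trajectory([np.array([pa, pb])], topology=top)

    def test_3_4_5(self):
        traj = self._two_atom_traj([0.0, 0, 0], [3.0, 4.0, 0])
        ds = interdomain_distance_series(
            traj, DomainSpec("A", "A", ((1, 1),)), DomainSpec("B", "B", ((1, 1),))
        )
        np.testing.assert_allclose(ds.d, [5.0])

    def test_coincident_zero(self):
        traj = self._two_atom_traj([1.0, 1, 1], [1.0, 1, 1])
        ds = interdomain_distance_series(
            traj, DomainSpec("A", "A", ((1, 1),)), DomainSpec("B", "B", ((1, 1),))
        )
        np.testing.assert_allclose(ds.d, [0.0])

    def test_sinusoid_recovery(self):
        spec = MotionSpec(
            n_atoms=(50, 50), duration=10.0, output_interval=0.1,
            distance_model=SinusoidModel(2.5, 0.1, 10.0),
            rotation_model=ConstantModel(0.0), jitter_sd=0.0, seed=11,
        )
        traj, truth = generate(spec)
        ds = interdomain_distance_series(
            traj, DomainSpec("A", "A", ((1, 50),)), DomainSpec("B", "B", ((1, 50),))
        )
        assert np.abs(ds.d - truth.distance).max() <= 1e-9

    def test_rigid_invariance(self, rng):
        spec = MotionSpec(n_atoms=(30, 30), duration=1.0, output_interval=0.1,
                          seed=5)
        traj, _ = generate(spec)
        a = DomainSpec("A", "A", ((1, 30),))
        b = DomainSpec("B", "B", ((1, 30),))
        d0 = interdomain_distance_series(traj, a, b).d
        frames = []
        for fr in traj.frames:
            R = random_rotation(rng)
            frames.append(type(fr)(fr.time, fr.coordinates @ R.T + rng.normal(size=3)))
        moved = traj.with_frames(frames)
        d1 = interdomain_distance_series(moved, a, b).d
        assert np.abs(d0 - d1).max() <= 1e-9
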