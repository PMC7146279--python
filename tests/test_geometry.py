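import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hingescope import (
    Trajectory,
    axis_angle_rotation,
    center_of_geometry,
    kabsch,
    paired_rmsd,
    rmsd_series,
    rmsf,
    rotation_angle,
)
from hingescope.errors import (
    EmptySelectionError,
    InsufficientFramesError,
    PairingError,
    UnderDeterminedError,
    ValidationError,
)

from conftest import make_frame


class TestCenterOfGeometry:
    def test_two_points(self):
        np.testing.assert_allclose(
            center_of_geometry([[0, 0, 0], [2, 0, 0]]), [1, 0, 0]
        )

    def test_single_point_identity(self):
        p = np.array([[1.5, -2.0, 7.0]])
        np.testing.assert_allclose(center_of_geometry(p), p[0])

    def test_matches_componentwise_mean(self, rng):
        pts = rng.normal(size=(50, 3))
        expected = np.array(
            [sum(pts[:, k]) / 50 for k in range(3)]
        )  # independent per-axis summation
        np.testing.assert_allclose(center_of_geometry(pts), expected, atol=1e-12)

    def test_empty_raises(self):
        with pytest.raises(EmptySelectionError):
            center_of_geometry(np.empty((0, 3)))


class TestKabsch:
    def test_identity_on_equal_sets(self, rng):
        pts = rng.normal(size=(10, 3))
        transform, fitted = kabsch(pts, pts)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(transform.translation, 0.0, atol=1e-10)
        assert fitted == pytest.approx(0.0, abs=1e-12)

    def test_recovers_constructed_motion(self, rng):
        ref = rng.normal(size=(20, 3)) * 5
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R = axis_angle_rotation(axis, 37.0)
        t = np.array([1.0, -2.0, 3.0])
        mobile = ref @ R.T + t
        transform, fitted = kabsch(mobile, ref)
        assert fitted <= 1e-9
        np.testing.assert_allclose(transform.apply(mobile), ref, atol=1e-8)
        assert rotation_angle(transform.rotation) == pytest.approx(37.0, abs=1e-8)

    def test_fitted_rmsd_is_minimal(self, rng, random_rigid):
        ref = rng.normal(size=(30, 3)) * 4
        mobile = ref + rng.normal(0, 0.5, size=ref.shape)
        _, fitted = kabsch(mobile, ref)
        for _ in range(200):
            R, t = random_rigid()
            moved = mobile @ R.T + t
            assert paired_rmsd(moved, ref) >= fitted - 1e-12

    def test_matches_scipy_align_vectors(self, rng):
        # independent implementation of the same least-squares problem
        ref = rng.normal(size=(25, 3)) * 6
        mobile = ref @ axis_angle_rotation([0, 1, 0], 50.0).T + 2.0
        mobile += rng.normal(0, 0.3, size=ref.shape)
        transform, fitted = kabsch(mobile, ref)
        rot, _ = Rotation.align_vectors(
            ref - ref.mean(axis=0), mobile - mobile.mean(axis=0)
        )
        np.testing.assert_allclose(
            transform.rotation, rot.as_matrix(), atol=1e-8
        )

    def test_under_determined(self, rng):
        pts = rng.normal(size=(2, 3))
        with pytest.raises(UnderDeterminedError):
            kabsch(pts, pts)

    def test_size_mismatch(self, rng):
        with pytest.raises(PairingError):
            kabsch(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))

    def test_collinear_warns_but_returns(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.warns(UserWarning, match="collinear"):
            transform, fitted = kabsch(line, line)
        assert fitted == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_common_rigid_motion(self, rng, random_rigid):
        a = rng.normal(size=(15, 3)) * 3
        b = a + rng.normal(0, 0.4, size=a.shape)
        _, fitted = kabsch(a, b)
        R, t = random_rigid()
        _, fitted2 = kabsch(a @ R.T + t, b @ R.T + t)
        assert fitted2 == pytest.approx(fitted, abs=1e-9)


class TestPairedRMSD:
    def test_identical_sets(self, rng):
        pts = rng.normal(size=(8, 3))
        assert paired_rmsd(pts, pts) == 0.0

    def test_uniform_shift(self, rng):
        a = rng.normal(size=(12, 3))
        assert paired_rmsd(a, a + [3.0, 0, 0]) == pytest.approx(3.0)

    def test_matches_per_point_loop(self, rng):
        a = rng.normal(size=(20, 3))
        b = rng.normal(size=(20, 3))
        acc = sum(
            sum((a[i][k] - b[i][k]) ** 2 for k in range(3)) for i in range(20)
        )
        assert paired_rmsd(a, b) == pytest.approx(np.sqrt(acc / 20), abs=1e-12)

    def test_symmetry_and_triangle_bound(self, rng):
        a, b, c = (rng.normal(size=(10, 3)) for _ in range(3))
        assert paired_rmsd(a, b) == paired_rmsd(b, a)
        assert paired_rmsd(a, c) <= paired_rmsd(a, b) + paired_rmsd(b, c) + 1e-12

    def test_mismatch_raises(self, rng):
        with pytest.raises(PairingError):
            paired_rmsd(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))


class TestRotationAngle:
    def test_identity(self):
        assert rotation_angle(np.eye(3)) == 0.0

    def test_quarter_turn_about_z(self):
        assert rotation_angle(axis_angle_rotation([0, 0, 1], 90.0)) == pytest.approx(
            90.0
        )

    def test_rodrigues_construction(self, rng):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        assert rotation_angle(
            axis_angle_rotation(axis, 123.4)
        ) == pytest.approx(123.4, abs=1e-9)

    def test_transpose_invariance(self, rng):
        for _ in range(20):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            R = axis_angle_rotation(axis, rng.uniform(0, 180))
            assert rotation_angle(R) == pytest.approx(
                rotation_angle(R.T), abs=1e-9
            )

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValidationError):
            rotation_angle(np.eye(3) * 1.01)


def _toy_trajectory(frames):
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[1]
    frame = make_frame(
        [("CA", "C", "ALA", i + 1, "A", tuple(frames[0, i])) for i in range(n)]
    )
    return Trajectory(frame.atoms, frames, np.arange(frames.shape[0], dtype=float))


class TestRMSF:
    def test_static_trajectory_is_zero(self, rng):
        base = rng.normal(size=(6, 3)) * 5
        traj = _toy_trajectory(np.repeat(base[None], 4, axis=0))
        profile = rmsf(traj, np.arange(6), np.arange(6))
        np.testing.assert_allclose(profile.rmsf, 0.0, atol=1e-12)

    def test_two_frame_hand_case(self):
        # anchor atoms 0-3 fixed; atom 4 moves 2 A, so it sits +/-1 A
        # about its mean -> RMSF exactly 1.0
        base = np.array(
            [[0.0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4], [2, 2, 2]]
        )
        moved = base.copy()
        moved[4, 0] += 2.0
        traj = _toy_trajectory([base, moved])
        profile = rmsf(traj, np.array([4]), np.arange(4))
        assert profile.rmsf[0] == pytest.approx(1.0, abs=1e-10)

    def test_invariant_under_global_rigid_motion(self, rng, random_rigid):
        frames = rng.normal(size=(10, 8, 3)) * 2 + np.arange(8)[None, :, None]
        traj = _toy_trajectory(frames)
        ref = rmsf(traj, np.arange(8), np.arange(8)).rmsf
        moved = np.empty_like(frames)
        for t in range(10):
            R, trans = random_rigid()
            moved[t] = frames[t] @ R.T + trans
        got = rmsf(_toy_trajectory(moved), np.arange(8), np.arange(8)).rmsf
        np.testing.assert_allclose(got, ref, atol=1e-9)

    def test_single_frame_rejected(self, rng):
        traj = _toy_trajectory(rng.normal(size=(1, 5, 3)))
        with pytest.raises(InsufficientFramesError):
            rmsf(traj, np.arange(5), np.arange(5))


class TestRMSDSeries:
    def test_first_frame_zero_and_rigid_motion_removed(self, rng, random_rigid):
        base = rng.normal(size=(12, 3)) * 5
        frames = [base]
        for _ in range(4):
            R, t = random_rigid()
            frames.append(base @ R.T + t)
        traj = _toy_trajectory(np.array(frames))
        series = rmsd_series(traj, np.arange(12))
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_reflects_internal_motion(self, rng):
        base = rng.normal(size=(12, 3)) * 5
        moved = base.copy()
        moved[0] += [2.0, 0, 0]
        traj = _toy_trajectory(np.array([base, moved]))
        series = rmsd_series(
            traj, np.arange(1, 12), analysis_selection=np.arange(12)
        )
        assert series[1] == pytest.approx(np.sqrt(4.0 / 12), abs=1e-9)
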