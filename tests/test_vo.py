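"""Visual odometry: pose recovery on rendered clips and decomposition oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gazevents.errors import ValidationError
from gazevents.io import SceneVideo
from gazevents.synthetic import _camera_axes, _render_background
from gazevents.vo import (OdometryConfig, RelativePose, _decompose_essential,
                          _decompose_homography, camera_series_from_pose_file,
                          compute_camera_series, estimate_relative_pose,
                          pose_to_motion_features, yaw_pitch_deg)


def _render(texture, intrinsics, yaw_deg, pos):
    img = _render_background(texture, intrinsics.K, yaw_deg,
                             np.asarray(pos, float), (intrinsics.height, intrinsics.width))
    return (np.clip(img, 0, 1) * 255).astype(np.uint8)


@pytest.fixture(scope="module")
def yaw_clip(scene_texture, intrinsics):
    """Frames with exactly 1 degree of camera pan between consecutive frames."""
    return [_render(scene_texture, intrinsics, i * 1.0, [0, 0, 0]) for i in range(8)]


class TestEstimateRelativePose:
    def test_identical_frames_return_identity(self, yaw_clip, intrinsics):
        pose = estimate_relative_pose(yaw_clip[0], yaw_clip[0], intrinsics)
        assert pose.valid
        assert pose.angle_deg < 0.05
        assert pose.n_inliers > 0

    def test_one_degree_yaw_recovered(self, yaw_clip, intrinsics):
        errors = [abs(estimate_relative_pose(yaw_clip[i], yaw_clip[i + 1], intrinsics).angle_deg - 1.0)
                  for i in range(len(yaw_clip) - 1)]
        assert np.mean(errors) <= 0.1

    def test_small_lateral_translation_gives_no_rotation(self, scene_texture, intrinsics):
        # 1% of the background depth, purely lateral
        fa = _render(scene_texture, intrinsics, 0.0, [0, 0, 0])
        fb = _render(scene_texture, intrinsics, 0.0, [0.1, 0, 0])
        pose = estimate_relative_pose(fa, fb, intrinsics)
        assert pose.valid
        assert pose.angle_deg <= 0.1

    def test_quaternion_canonicalized_and_composes(self, yaw_clip, intrinsics):
        total = Rotation.identity()
        for i in range(len(yaw_clip) - 1):
            pose = estimate_relative_pose(yaw_clip[i], yaw_clip[i + 1], intrinsics)
            assert pose.q[0] >= 0
            assert np.linalg.norm(pose.q) == pytest.approx(1.0, abs=1e-9)
            w, x, y, z = pose.q
            total = Rotation.from_quat([x, y, z, w]) * total
        expected = len(yaw_clip) - 1  # degrees of accumulated yaw
        got = np.degrees(np.linalg.norm(total.as_rotvec()))
        assert got == pytest.approx(expected, rel=0.05)

    def test_mismatched_frame_sizes_rejected(self, yaw_clip, intrinsics):
        with pytest.raises(ValidationError):
            estimate_relative_pose(yaw_clip[0], yaw_clip[1][:-10], intrinsics)


class TestTranslationProxy:
    def _proxy(self, fa, fb, intrinsics, dt=1.0):
        pose = estimate_relative_pose(fa, fb, intrinsics)
        assert pose.valid
        inl = pose.inlier_mask
        _, _, btv = pose_to_motion_features(pose, pose.matches_a[inl],
                                            pose.matches_b[inl], intrinsics, dt)
        return btv

    def test_pure_rotation_proxy_small_vs_matched_translation(self, scene_texture, intrinsics):
        # 1 deg yaw moves the image by ~fx*tan(1deg) ~ 4.8 px; a lateral step of
        # 0.175 units at depth 10 produces the same ~4.8 px displacement
        fa = _render(scene_texture, intrinsics, 0.0, [0, 0, 0])
        f_rot = _render(scene_texture, intrinsics, 1.0, [0, 0, 0])
        f_trans = _render(scene_texture, intrinsics, 0.0, [0.175, 0, 0])
        p_rot = self._proxy(fa, f_rot, intrinsics)
        p_trans = self._proxy(fa, f_trans, intrinsics)
        assert p_rot <= 0.05 * p_trans

    def test_proxy_monotone_in_translation_speed(self, scene_texture, intrinsics):
        fa = _render(scene_texture, intrinsics, 0.0, [0, 0, 0])
        proxies = [self._proxy(fa, _render(scene_texture, intrinsics, 0.0, [dx, 0, 0]),
                               intrinsics) for dx in (0.05, 0.1, 0.2)]
        assert proxies[0] < proxies[1] < proxies[2]


class TestPoseToMotionFeatures:
    def test_identity_pose_zero_features(self, intrinsics):
        pose = RelativePose(np.array([1.0, 0, 0, 0]), None, 10, True)
        out = pose_to_motion_features(pose, np.empty((0, 2)), np.empty((0, 2)),
                                      intrinsics, 1 / 30)
        assert out == (0.0, 0.0, 0.0)

    def test_half_degree_yaw_at_30fps(self, intrinsics):
        # camera pans right by 0.5 deg between frames
        R = _camera_axes(0.5).T @ _camera_axes(0.0)
        q = Rotation.from_matrix(R).as_quat()
        pose = RelativePose(np.array([q[3], q[0], q[1], q[2]]), None, 10, True)
        hrv, hrd, _ = pose_to_motion_features(pose, np.empty((0, 2)), np.empty((0, 2)),
                                              intrinsics, 1 / 30)
        assert hrv == pytest.approx(15.0, rel=1e-6)
        assert min(hrd, 360 - hrd) == pytest.approx(0.0, abs=1e-6)

    def test_upward_tilt_direction_is_90(self, intrinsics):
        # tilt up = rotation moving the forward axis toward -y (image y is down)
        R_wc_b = Rotation.from_rotvec(np.radians(0.5) * np.array([1.0, 0, 0])).as_matrix()
        R = R_wc_b.T  # frame a -> frame b
        yaw, pitch = yaw_pitch_deg(R)
        assert pitch == pytest.approx(0.5, abs=1e-9)
        assert abs(yaw) < 1e-9

    def test_nonpositive_dt_rejected(self, intrinsics):
        pose = RelativePose(np.array([1.0, 0, 0, 0]), None, 10, True)
        with pytest.raises(ValidationError):
            pose_to_motion_features(pose, np.empty((0, 2)), np.empty((0, 2)),
                                    intrinsics, 0.0)


class TestDecompositionOracles:
    """Correspondence-level checks against exactly known poses."""

    def test_homography_decomposition_recovers_known_pose(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            R = Rotation.from_rotvec(np.radians(rng.uniform(0.2, 4)) *
                                     _unit(rng.standard_normal(3))).as_matrix()
            t = 0.05 * _unit(rng.standard_normal(3))
            n = _unit(np.array([rng.uniform(-0.2, 0.2), rng.uniform(-0.2, 0.2), 1.0]))
            A = R + np.outer(t, n)
            bearings = np.column_stack([rng.uniform(-0.4, 0.4, 30),
                                        rng.uniform(-0.3, 0.3, 30),
                                        np.ones(30)])
            R_hat, t_hat = _decompose_homography(A, bearings, tol=1e-6)
            err = np.degrees(np.linalg.norm(Rotation.from_matrix(R_hat.T @ R).as_rotvec()))
            assert err < 0.01
            assert t_hat is not None
            assert abs(np.dot(t_hat, _unit(t))) > 0.999

    def test_homography_pure_rotation_case(self):
        R = Rotation.from_euler("y", 2.0, degrees=True).as_matrix()
        bearings = np.array([[0.1, 0.0, 1.0], [-0.2, 0.1, 1.0], [0.0, -0.1, 1.0]])
        R_hat, t_hat = _decompose_homography(R.copy(), bearings, tol=1e-3)
        assert t_hat is None
        err = np.degrees(np.linalg.norm(Rotation.from_matrix(R_hat.T @ R).as_rotvec()))
        assert err < 1e-6

    def test_essential_decomposition_recovers_known_pose(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            R = Rotation.from_rotvec(np.radians(rng.uniform(0.5, 5)) *
                                     _unit(rng.standard_normal(3))).as_matrix()
            t = _unit(rng.standard_normal(3))
            X = np.column_stack([rng.uniform(-2, 2, 40), rng.uniform(-2, 2, 40),
                                 rng.uniform(4, 10, 40)])
            X2 = (R @ X.T).T + t
            x1 = X[:, :2] / X[:, 2:]
            x2 = X2[:, :2] / X2[:, 2:]
            E = _skew(t) @ R
            R_hat, t_hat = _decompose_essential(E, x1, x2)
            err = np.degrees(np.linalg.norm(Rotation.from_matrix(R_hat.T @ R).as_rotvec()))
            assert err < 1e-6
            assert np.dot(t_hat, t) > 0.999


class TestCameraSeries:
    def test_static_clip_is_still(self, scene_texture, intrinsics):
        frames = [_render(scene_texture, intrinsics, 0.0, [0, 0, 0])] * 10
        video = SceneVideo(frames, np.arange(10) / 30.0, intrinsics)
        series = compute_camera_series(video)
        assert series.valid.all()
        assert np.all(series.head_rot_vel < 0.5)

    def test_constant_yaw_rate_recovered(self, scene_texture, intrinsics):
        # 10 deg/s at 30 fps = 1/3 deg per frame
        frames = [_render(scene_texture, intrinsics, i * 10.0 / 30.0, [0, 0, 0])
                  for i in range(15)]
        video = SceneVideo(frames, np.arange(15) / 30.0, intrinsics)
        series = compute_camera_series(video)
        assert abs(np.mean(series.head_rot_vel[series.valid]) - 10.0) <= 1.0

    def test_two_identical_frames(self, scene_texture, intrinsics):
        f = _render(scene_texture, intrinsics, 0.0, [0, 0, 0])
        video = SceneVideo([f, f], np.array([0.0, 1 / 30.0]), intrinsics)
        series = compute_camera_series(video)
        assert len(series) == 1
        assert series.head_rot_vel[0] == pytest.approx(0.0, abs=0.05 * 30)

    def test_mock_backend_contract(self, intrinsics):
        """Any backend honoring the RelativePose contract drives the same downstream math."""
        R = _camera_axes(0.5).T @ _camera_axes(0.0)
        q = Rotation.from_matrix(R).as_quat()
        pose = RelativePose(np.array([q[3], q[0], q[1], q[2]]), None, 50, True,
                            matches_a=np.empty((0, 2)), matches_b=np.empty((0, 2)),
                            inlier_mask=np.empty(0, bool))
        frames = [np.zeros((intrinsics.height, intrinsics.width), np.uint8)] * 4
        video = SceneVideo(frames, np.arange(4) / 30.0, intrinsics)
        series = compute_camera_series(video, backend=lambda a, b, K, cfg: pose)
        np.testing.assert_allclose(series.head_rot_vel, 15.0, rtol=1e-9)
        assert series.valid.all()

    def test_pose_injection_file(self, tmp_path):
        path = tmp_path / "poses.csv"
        q = Rotation.from_euler("y", 1.0, degrees=True).as_quat()
        path.write_text("frame_pair_index,qw,qx,qy,qz,trans_proxy\n"
                        f"0,{q[3]},{q[0]},{q[1]},{q[2]},12.5\n"
                        f"1,1,0,0,0,0.0\n")
        series = camera_series_from_pose_file(path, np.arange(3) / 30.0)
        assert series.head_rot_vel[0] == pytest.approx(30.0, rel=1e-9)
        assert series.body_trans_vel[0] == 12.5
        assert series.head_rot_vel[1] == 0.0


def _unit(v):
    return np.asarray(v, float) / np.linalg.norm(v)


def _skew(t):
    return np.array([[0, -t[2], t[1]], [t[2], 0, -t[0]], [-t[1], t[0], 0.0]])
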