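"""Classical monocular visual odometry for head/body motion features.

Each consecutive scene-camera frame pair yields a relative pose: a unit
quaternion for the head rotation and a scale-free translation direction.
Monocular geometry cannot observe metric translation, so the body-motion
feature is a *derotated parallax proxy*: the median image displacement of
matched points after removing the flow predicted by the recovered rotation,
in pixels per second.  It is zero for a stationary or purely rotating head
and grows with walking speed, which is the property the classifier needs.

Pipeline per frame pair
-----------------------
1. grayscale + block-mean downscale, Shi-Tomasi corners in frame A
2. block matching (SSD over a local search window, sub-pixel parabola
   refinement), optionally pre-shifted by global phase correlation
3. robust model selection:
   * negligible median displacement  -> identity rotation
   * RANSAC homography explains most matches (planar-dominant scene or
     rotation-only motion, where essential-matrix estimation is degenerate)
     -> SVD homography decomposition (pure-rotation special case included)
   * otherwise -> RANSAC essential matrix + cheirality decomposition

The convention throughout: the pose maps frame-A camera coordinates into
frame-B coordinates, ``x_b = R x_a + t``.  Quaternions are (w, x, y, z) with
w >= 0.  Any backend producing this contract can replace the classical one
(see :func:`compute_camera_series` and :func:`camera_series_from_pose_file`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from skimage.feature import corner_peaks, corner_shi_tomasi
from skimage.measure import ransac
from skimage.registration import phase_cross_correlation
from skimage.transform import EssentialMatrixTransform, ProjectiveTransform, downscale_local_mean

from .errors import PipelineError, ValidationError
from .io import CameraIntrinsics, SceneVideo

log = logging.getLogger(__name__)


@dataclass
class OdometryConfig:
    """Settings of the classical odometry backend.

    ``ransac_threshold_px`` and ``min_displacement_px`` are in full-resolution
    pixels; corner detection and matching run on the image downscaled by
    ``downscale`` (block mean) for speed.
    """

    n_corners: int = 150
    block_radius: int = 5
    search_radius: int = 8
    downscale: int = 2
    ransac_threshold_px: float = 1.0
    min_inliers: int = 15
    min_displacement_px: float = 0.2
    homography_inlier_frac: float = 0.6
    max_trials: int = 100
    pure_rotation_tol: float = 1e-3
    use_phase_preshift: bool = True


@dataclass
class RelativePose:
    """Relative pose of frame B w.r.t. frame A: ``x_b = q * x_a + t``.

    ``t_unit`` is None when translation is unobservable (identity / pure
    rotation).  ``matches_a/b`` hold the full-resolution matched point
    coordinates (x, y) and ``inlier_mask`` the robust-consensus inliers.
    """

    q: np.ndarray  # (w, x, y, z), unit, w >= 0
    t_unit: np.ndarray | None
    n_inliers: int
    valid: bool
    matches_a: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    matches_b: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    inlier_mask: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    @property
    def angle_deg(self) -> float:
        """Rotation angle of the pose in degrees."""
        return float(np.degrees(2.0 * np.arctan2(np.linalg.norm(self.q[1:]), self.q[0])))

    @property
    def R(self) -> np.ndarray:
        w, x, y, z = self.q
        return Rotation.from_quat([x, y, z, w]).as_matrix()


@dataclass
class CameraMotionSeries:
    """Per-frame-pair head-rotation and body-translation features."""

    t_mid: np.ndarray
    head_rot_vel: np.ndarray   # deg/s, >= 0
    head_rot_dir: np.ndarray   # deg in [0, 360)
    body_trans_vel: np.ndarray  # derotated parallax proxy, px/s, >= 0
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.t_mid)


_IDENTITY_Q = np.array([1.0, 0.0, 0.0, 0.0])


def _canonical_quat_from_matrix(R: np.ndarray) -> np.ndarray:
    x, y, z, w = Rotation.from_matrix(R).as_quat()
    q = np.array([w, x, y, z])
    return -q if q[0] < 0 else q


def _project_to_rotation(M: np.ndarray) -> np.ndarray:
    U, _, Vt = np.linalg.svd(M)
    D = np.diag([1.0, 1.0, np.linalg.det(U @ Vt)])
    return U @ D @ Vt


def _to_gray(frame: np.ndarray) -> np.ndarray:
    f = np.asarray(frame, dtype=float)
    if f.ndim == 3:
        f = f.mean(axis=2)
    return f


def _detect_corners(img: np.ndarray, cfg: OdometryConfig) -> np.ndarray:
    margin = cfg.block_radius + cfg.search_radius + 1
    resp = corner_shi_tomasi(img)
    return corner_peaks(resp, min_distance=5, threshold_rel=0.01,
                        num_peaks=cfg.n_corners, exclude_border=margin)


def _block_match(img_a, img_b, corners, cfg: OdometryConfig,
                 preshift=(0, 0)) -> tuple[np.ndarray, np.ndarray]:
    """Match template blocks around corners of A inside search windows of B.

    Returns matched (row, col) coordinates in A and sub-pixel refined
    coordinates in B, at the working (downscaled) resolution.
    """
    r, s = cfg.block_radius, cfg.search_radius
    H, W = img_b.shape
    out_a, out_b = [], []
    for row, col in corners:
        ta = img_a[row - r:row + r + 1, col - r:col + r + 1]
        brow, bcol = row + preshift[0], col + preshift[1]
        if not (r + s <= brow < H - r - s and r + s <= bcol < W - r - s):
            continue
        region = img_b[brow - r - s:brow + r + s + 1, bcol - r - s:bcol + r + s + 1]
        win = np.lib.stride_tricks.sliding_window_view(region, (2 * r + 1, 2 * r + 1))
        cost = ((win - ta) ** 2).sum(axis=(2, 3))
        ij = np.unravel_index(np.argmin(cost), cost.shape)
        dr, dc = float(ij[0]), float(ij[1])
        # sub-pixel parabola refinement along each axis
        for axis, pos in ((0, ij[0]), (1, ij[1])):
            if 0 < pos < cost.shape[axis] - 1:
                if axis == 0:
                    c0, c1, c2 = cost[pos - 1, ij[1]], cost[pos, ij[1]], cost[pos + 1, ij[1]]
                else:
                    c0, c1, c2 = cost[ij[0], pos - 1], cost[ij[0], pos], cost[ij[0], pos + 1]
                denom = c0 - 2 * c1 + c2
                if denom > 1e-12:
                    delta = 0.5 * (c0 - c2) / denom
                    if axis == 0:
                        dr = pos + np.clip(delta, -0.5, 0.5)
                    else:
                        dc = pos + np.clip(delta, -0.5, 0.5)
        out_a.append((row, col))
        out_b.append((brow - s + dr, bcol - s + dc))
    return np.asarray(out_a, dtype=float), np.asarray(out_b, dtype=float)


def _refine_matches_full_res(img_a, img_b, pa, pb, r: int = 5, s: int = 2):
    """Second matching pass at full resolution around coarse matches.

    Re-localizes each match with a small SSD search (+- ``s`` px) and
    sub-pixel parabola fit; matches too close to the border keep their
    coarse position.
    """
    H, W = img_a.shape
    pa_out = pa.copy()
    pb_out = pb.copy()
    for k in range(len(pa)):
        ax, ay = int(round(pa[k, 0])), int(round(pa[k, 1]))
        bx, by = int(round(pb[k, 0])), int(round(pb[k, 1]))
        if not (r <= ay < H - r and r <= ax < W - r
                and r + s <= by < H - r - s and r + s <= bx < W - r - s):
            continue
        ta = img_a[ay - r:ay + r + 1, ax - r:ax + r + 1]
        region = img_b[by - r - s:by + r + s + 1, bx - r - s:bx + r + s + 1]
        win = np.lib.stride_tricks.sliding_window_view(region, (2 * r + 1, 2 * r + 1))
        cost = ((win - ta) ** 2).sum(axis=(2, 3))
        ij = np.unravel_index(np.argmin(cost), cost.shape)
        dr, dc = float(ij[0]), float(ij[1])
        for axis, pos in ((0, ij[0]), (1, ij[1])):
            if 0 < pos < cost.shape[axis] - 1:
                if axis == 0:
                    c0, c1, c2 = cost[pos - 1, ij[1]], cost[pos, ij[1]], cost[pos + 1, ij[1]]
                else:
                    c0, c1, c2 = cost[ij[0], pos - 1], cost[ij[0], pos], cost[ij[0], pos + 1]
                denom = c0 - 2 * c1 + c2
                if denom > 1e-12:
                    delta = 0.5 * (c0 - c2) / denom
                    if axis == 0:
                        dr = pos + np.clip(delta, -0.5, 0.5)
                    else:
                        dc = pos + np.clip(delta, -0.5, 0.5)
        pa_out[k] = (ax, ay)
        pb_out[k] = (bx - s + dc, by - s + dr)
    return pa_out, pb_out


def _decompose_homography(A: np.ndarray, bearings_a: np.ndarray,
                          tol: float) -> tuple[np.ndarray, np.ndarray | None]:
    """Decompose a calibrated homography ``A ~ R + t n^T / d`` into (R, t_unit).

    SVD-based planar decomposition.  Of the four algebraic solutions, those
    whose plane normal points away from the matched bearings are discarded;
    the remaining two-fold ambiguity is broken with a fronto-parallel prior
    (normal closest to the mean viewing direction).  When the singular
    values are (numerically) equal the motion is a pure rotation and
    ``t_unit`` is None.
    """
    # sign: bearings must map to bearings with positive z
    z_med = np.median((A @ bearings_a.T)[2])
    if z_med < 0:
        A = -A
    sv = np.linalg.svd(A, compute_uv=False)
    A = A / sv[1]
    s1, s3 = sv[0] / sv[1], sv[2] / sv[1]
    if s1 - s3 < tol:
        return _project_to_rotation(A), None
    _, S2, Vt = np.linalg.svd(A.T @ A)
    V = Vt.T
    if np.linalg.det(V) < 0:
        V = -V
    sig1, sig3 = np.sqrt(S2[0]), np.sqrt(S2[2])
    v1, v2, v3 = V[:, 0], V[:, 1], V[:, 2]
    a = np.sqrt(max(1.0 - sig3 ** 2, 0.0))
    b = np.sqrt(max(sig1 ** 2 - 1.0, 0.0))
    norm = np.sqrt(max(sig1 ** 2 - sig3 ** 2, 1e-18))
    u1 = (a * v1 + b * v3) / norm
    u2 = (a * v1 - b * v3) / norm
    candidates = []
    for u in (u1, u2):
        U_m = np.column_stack([v2, u, np.cross(v2, u)])
        W_m = np.column_stack([A @ v2, A @ u, np.cross(A @ v2, A @ u)])
        R = W_m @ U_m.T
        n = np.cross(v2, u)
        t = (A - R) @ n
        for sign in (1.0, -1.0):
            candidates.append((R, sign * t, sign * n))
    # keep solutions whose plane lies in front of camera A
    mean_bearing = bearings_a.mean(axis=0)
    mean_bearing /= np.linalg.norm(mean_bearing)
    scored = [(float(n @ mean_bearing), R, t) for R, t, n in candidates]
    scored.sort(key=lambda c: -c[0])
    _, R, t = scored[0]
    R = _project_to_rotation(R)
    nt = np.linalg.norm(t)
    return R, (t / nt if nt > 1e-12 else None)


def _triangulate_depths(R, t, x1, x2):
    """Depths in both cameras for normalized correspondences (DLT)."""
    z1 = np.empty(len(x1))
    z2 = np.empty(len(x1))
    P1 = np.hstack([np.eye(3), np.zeros((3, 1))])
    P2 = np.hstack([R, t[:, None]])
    for i, (a, b) in enumerate(zip(x1, x2)):
        Amat = np.vstack([
            a[0] * P1[2] - P1[0], a[1] * P1[2] - P1[1],
            b[0] * P2[2] - P2[0], b[1] * P2[2] - P2[1],
        ])
        _, _, Vt = np.linalg.svd(Amat)
        X = Vt[-1]
        X = X[:3] / X[3] if abs(X[3]) > 1e-12 else X[:3] * np.inf
        z1[i] = X[2]
        z2[i] = (R @ X + t)[2]
    return z1, z2


def _decompose_essential(E: np.ndarray, x1n: np.ndarray,
                         x2n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decompose an essential matrix into (R, t_unit) using the cheirality check."""
    U, _, Vt = np.linalg.svd(E)
    if np.linalg.det(U) < 0:
        U = -U
    if np.linalg.det(Vt) < 0:
        Vt = -Vt
    W = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    t = U[:, 2]
    sel = slice(0, min(len(x1n), 25))
    h1 = np.column_stack([x1n[sel], np.ones(len(x1n[sel]))])
    h2 = np.column_stack([x2n[sel], np.ones(len(x2n[sel]))])
    best, best_count = None, -1
    for R in (U @ W @ Vt, U @ W.T @ Vt):
        for tc in (t, -t):
            z1, z2 = _triangulate_depths(R, tc, h1[:, :2], h2[:, :2])
            count = int(np.sum((z1 > 0) & (z2 > 0)))
            if count > best_count:
                best, best_count = (R, tc), count
    R, tc = best
    return R, tc / np.linalg.norm(tc)


def estimate_relative_pose(frame_a: np.ndarray, frame_b: np.ndarray,
                           K: CameraIntrinsics,
                           cfg: OdometryConfig | None = None) -> RelativePose:
    """Estimate the relative camera pose between two frames.

    Identical (or displacement-free) frames return the identity rotation
    with ``valid=True``; too few matches or degenerate geometry return an
    invalid pose, never raise.
    """
    cfg = cfg or OdometryConfig()
    a, b = _to_gray(frame_a), _to_gray(frame_b)
    if a.shape != b.shape:
        raise ValidationError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if a.shape != (K.height, K.width):
        raise ValidationError(f"frames {a.shape} do not match intrinsics "
                              f"({K.height}, {K.width})")
    d = max(int(cfg.downscale), 1)
    if d > 1:
        a_s = downscale_local_mean(a, (d, d))
        b_s = downscale_local_mean(b, (d, d))
    else:
        a_s, b_s = a, b
    corners = _detect_corners(a_s, cfg)
    if len(corners) < 8:
        return RelativePose(_IDENTITY_Q.copy(), None, 0, False)
    preshift = (0, 0)
    if cfg.use_phase_preshift:
        shift = phase_cross_correlation(a_s, b_s, normalization=None)[0]
        # shift = displacement of b relative to a in (row, col); a corner at p in a
        # appears near p - shift... phase_cross_correlation returns the shift that
        # registers b onto a, so the corner moves by -shift.
        preshift = (int(round(-shift[0])), int(round(-shift[1])))
    pa_rc, pb_rc = _block_match(a_s, b_s, corners, cfg, preshift)
    if len(pa_rc) < 8:
        return RelativePose(_IDENTITY_Q.copy(), None, 0, False)
    # working-resolution (row, col) -> full-resolution (x, y)
    def to_full_xy(p_rc):
        xy = p_rc[:, ::-1]
        return (xy + 0.5) * d - 0.5 if d > 1 else xy.copy()
    pa = to_full_xy(pa_rc)
    pb = to_full_xy(pb_rc)
    if d > 1:
        pa, pb = _refine_matches_full_res(a, b, pa, pb)
    disp = np.linalg.norm(pb - pa, axis=1)
    if np.median(disp) < cfg.min_displacement_px:
        mask = disp < max(cfg.ransac_threshold_px, cfg.min_displacement_px)
        return RelativePose(_IDENTITY_Q.copy(), None, len(pa), True,
                            pa, pb, mask)
    try:
        model, inliers = ransac((pa, pb), ProjectiveTransform, min_samples=4,
                                residual_threshold=cfg.ransac_threshold_px,
                                max_trials=cfg.max_trials, rng=0)
    except Exception:  # degenerate sample sets
        model, inliers = None, None
    if model is None or inliers is None or inliers.sum() < cfg.min_inliers:
        return RelativePose(_IDENTITY_Q.copy(), None,
                            0 if inliers is None else int(inliers.sum()), False,
                            pa, pb, np.zeros(len(pa), bool))
    n_inl = int(inliers.sum())
    Kmat = K.K
    Kinv = np.linalg.inv(Kmat)
    bearings_a = (Kinv @ np.column_stack([pa[inliers], np.ones(n_inl)]).T).T
    if n_inl / len(pa) >= cfg.homography_inlier_frac:
        A = Kinv @ model.params @ Kmat
        R, t_unit = _decompose_homography(A, bearings_a, cfg.pure_rotation_tol)
    else:
        x1n = (Kinv @ np.column_stack([pa, np.ones(len(pa))]).T).T[:, :2]
        x2n = (Kinv @ np.column_stack([pb, np.ones(len(pb))]).T).T[:, :2]
        thresh_n = cfg.ransac_threshold_px / float(K.fx)
        try:
            emodel, einl = ransac((x1n, x2n), EssentialMatrixTransform, min_samples=8,
                                  residual_threshold=thresh_n,
                                  max_trials=cfg.max_trials, rng=0)
        except Exception:
            emodel, einl = None, None
        if emodel is None or einl is None or einl.sum() < cfg.min_inliers:
            return RelativePose(_IDENTITY_Q.copy(), None, n_inl, False,
                                pa, pb, inliers)
        inliers = einl
        n_inl = int(einl.sum())
        R, t_unit = _decompose_essential(emodel.params, x1n[einl], x2n[einl])
    return RelativePose(_canonical_quat_from_matrix(R), t_unit, n_inl, True,
                        pa, pb, inliers)


def yaw_pitch_deg(R: np.ndarray) -> tuple[float, float]:
    """Pan/tilt (degrees) of the camera-orientation change encoded by ``R``.

    ``R`` maps frame-A coordinates to frame-B coordinates.  Pan (yaw) is
    positive when the camera turns rightward, tilt (pitch) positive upward
    (image y runs downward); roll is ignored.
    """
    fwd = R.T[:, 2]  # frame-B forward axis expressed in frame A
    yaw = np.degrees(np.arctan2(fwd[0], fwd[2]))
    pitch = np.degrees(np.arctan2(-fwd[1], np.hypot(fwd[0], fwd[2])))
    return float(yaw), float(pitch)


def pose_to_motion_features(pose: RelativePose, inlier_a: np.ndarray,
                            inlier_b: np.ndarray, K: CameraIntrinsics,
                            dt: float) -> tuple[float, float, float]:
    """Head-rotation velocity/direction and body-translation proxy of one pose.

    Returns ``(head_rot_vel [deg/s], head_rot_dir [deg], body_trans_vel [px/s])``.
    The body proxy is the median matched-point displacement remaining after
    the rotational flow predicted by the pose is removed.
    """
    if dt <= 0:
        raise ValidationError(f"dt must be positive, got {dt}")
    angle = pose.angle_deg
    head_rot_vel = angle / dt
    if angle < 1e-9:
        head_rot_dir = 0.0
        R = np.eye(3)
    else:
        R = pose.R
        yaw, pitch = yaw_pitch_deg(R)
        head_rot_dir = float(np.degrees(np.arctan2(pitch, yaw)) % 360.0)
    if len(inlier_a) == 0:
        return head_rot_vel, head_rot_dir, 0.0
    Kmat, Kinv = K.K, np.linalg.inv(K.K)
    xa = (Kinv @ np.column_stack([inlier_a, np.ones(len(inlier_a))]).T)
    pred = Kmat @ (R @ xa)
    pred_px = (pred[:2] / pred[2]).T
    resid = np.linalg.norm(inlier_b - pred_px, axis=1)
    return head_rot_vel, head_rot_dir, float(np.median(resid)) / dt


def compute_camera_series(video: SceneVideo, cfg: OdometryConfig | None = None,
                          backend=None) -> CameraMotionSeries:
    """Run odometry over all consecutive frame pairs of a video.

    ``backend`` is any callable with the :func:`estimate_relative_pose`
    signature; invalid pairs are marked (and later bridged by channel
    interpolation), never fabricated as zero motion.
    """
    if len(video) < 2:
        raise ValidationError("need at least 2 frames for camera motion")
    cfg = cfg or OdometryConfig()
    backend = backend or estimate_relative_pose
    K = video.intrinsics
    n = len(video) - 1
    t_mid = 0.5 * (video.frame_times[:-1] + video.frame_times[1:])
    hrv = np.full(n, np.nan)
    hrd = np.full(n, np.nan)
    btv = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        pose = backend(video.frames[i], video.frames[i + 1], K, cfg)
        if not pose.valid:
            continue
        dt = video.frame_times[i + 1] - video.frame_times[i]
        inl = pose.inlier_mask
        hrv[i], hrd[i], btv[i] = pose_to_motion_features(
            pose, pose.matches_a[inl], pose.matches_b[inl], K, dt)
        valid[i] = True
    n_invalid = int(n - valid.sum())
    if n_invalid:
        log.info("camera motion: %d/%d frame pairs invalid", n_invalid, n)
    if not valid.any():
        raise PipelineError("all frame pairs failed odometry; "
                            "check scene texture and lighting")
    return CameraMotionSeries(t_mid, hrv, hrd, btv, valid)


def camera_series_from_pose_file(path, frame_times: np.ndarray) -> CameraMotionSeries:
    """Build a camera-motion series from an external pose file.

    CSV columns: ``frame_pair_index, qw, qx, qy, qz, trans_proxy`` where
    ``trans_proxy`` is already in px/s-compatible units.  This bypasses the
    classical backend entirely, e.g. to inject an external VO tool's output.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    df = pd.read_csv(path)
    need = {"frame_pair_index", "qw", "qx", "qy", "qz", "trans_proxy"}
    if not need.issubset(df.columns):
        raise ValidationError(f"pose file missing columns {sorted(need - set(df.columns))}")
    n = len(frame_times) - 1
    t_mid = 0.5 * (frame_times[:-1] + frame_times[1:])
    hrv = np.full(n, np.nan)
    hrd = np.full(n, np.nan)
    btv = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for _, row in df.iterrows():
        i = int(row["frame_pair_index"])
        if not 0 <= i < n:
            raise ValidationError(f"frame_pair_index {i} out of range 0..{n - 1}")
        q = np.array([row["qw"], row["qx"], row["qy"], row["qz"]])
        q = q / np.linalg.norm(q)
        if q[0] < 0:
            q = -q
        pose = RelativePose(q, None, 0, True)
        dt = frame_times[i + 1] - frame_times[i]
        hrv[i] = pose.angle_deg / dt
        if pose.angle_deg < 1e-9:
            hrd[i] = 0.0
        else:
            yaw, pitch = yaw_pitch_deg(pose.R)
            hrd[i] = float(np.degrees(np.arctan2(pitch, yaw)) % 360.0)
        btv[i] = float(row["trans_proxy"])
        valid[i] = True
    return CameraMotionSeries(t_mid, hrv, hrd, btv, valid)
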