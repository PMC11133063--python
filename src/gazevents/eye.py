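"""Head-centered eye-movement kinematics.

Velocity and movement direction are computed from consecutive sample pairs
(a window of two samples), which keeps the feature count low.  Velocity is
the great-circle angle between the two unit gaze vectors divided by the time
step; direction is the angle of the (Δazimuth, Δelevation) step, with
0° = rightward, 90° = upward, reported in [0, 360).  Each pair feature is
assigned the midpoint time of the pair and later interpolated back to the
sample timestamps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import GazeRecording

log = logging.getLogger(__name__)


def azimuth_elevation(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal/vertical angular coordinates (degrees) of gaze vectors.

    The head frame is x right, y up, z forward; azimuth is positive to the
    right, elevation positive upward.
    """
    v = np.asarray(v, dtype=float)
    az = np.degrees(np.arctan2(v[..., 0], v[..., 2]))
    el = np.degrees(np.arctan2(v[..., 1], np.hypot(v[..., 0], v[..., 2])))
    return az, el


def direction_deg(d_az: float, d_el: float) -> float:
    """Angle of an (Δaz, Δel) step mapped to [0, 360); 0 for a zero step."""
    if d_az == 0.0 and d_el == 0.0:
        return 0.0
    return float(np.degrees(np.arctan2(d_el, d_az)) % 360.0)


def pairwise_eye_kinematics(g_i: np.ndarray, g_j: np.ndarray, dt: float) -> tuple[float, float]:
    """Angular velocity (deg/s) and movement direction (deg) of one sample pair.

    Velocity uses the numerically robust great-circle angle
    ``atan2(|g_i x g_j|, g_i . g_j)``.  Zero-motion pairs get direction 0 by
    convention so the feature matrix stays dense.
    """
    if dt <= 0:
        raise ValidationError(f"dt must be positive, got {dt}")
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    for name, g in (("g_i", g_i), ("g_j", g_j)):
        if abs(np.linalg.norm(g) - 1.0) > 1e-6:
            raise ValidationError(f"{name} is not unit length (|{name}| = {np.linalg.norm(g):.6f})")
    angle = np.arctan2(np.linalg.norm(np.cross(g_i, g_j)), float(np.dot(g_i, g_j)))
    velocity = float(np.degrees(angle)) / dt
    if angle == 0.0:
        return 0.0, 0.0
    az_i, el_i = azimuth_elevation(g_i)
    az_j, el_j = azimuth_elevation(g_j)
    d_az = (az_j - az_i + 180.0) % 360.0 - 180.0
    d_el = el_j - el_i
    return velocity, direction_deg(d_az, d_el)


@dataclass
class EyeKinematicsSeries:
    """Per-pair eye velocity/direction at pair-midpoint times.

    ``segment`` carries the index of the contiguous (un-cut) span each pair
    belongs to, so downstream interpolation never bridges a removed block.
    """

    t_mid: np.ndarray
    eye_vel: np.ndarray
    eye_dir: np.ndarray
    segment: np.ndarray

    def __len__(self) -> int:
        return len(self.t_mid)


def compute_eye_series(rec: GazeRecording) -> EyeKinematicsSeries:
    """Eye kinematics for every within-segment consecutive sample pair.

    Segments are delimited by ``cut_before`` flags; pairs never straddle a
    cut.  A segment of length 1 contributes no pairs (logged, not an error).
    """
    seg_id = np.cumsum(rec.cut_before)
    t_mid, vel, dirn, seg_out = [], [], [], []
    az, el = azimuth_elevation(rec.gaze_dir)
    n_single = 0
    for s in np.unique(seg_id):
        idx = np.flatnonzero(seg_id == s)
        if idx.size < 2:
            n_single += 1
            continue
        for a, b in zip(idx[:-1], idx[1:]):
            dt = rec.t[b] - rec.t[a]
            g_a, g_b = rec.gaze_dir[a], rec.gaze_dir[b]
            angle = np.arctan2(np.linalg.norm(np.cross(g_a, g_b)), float(np.dot(g_a, g_b)))
            v = float(np.degrees(angle)) / dt
            if angle == 0.0:
                d = 0.0
            else:
                d_az = (az[b] - az[a] + 180.0) % 360.0 - 180.0
                d = direction_deg(d_az, el[b] - el[a])
            t_mid.append(0.5 * (rec.t[a] + rec.t[b]))
            vel.append(v)
            dirn.append(d)
            seg_out.append(s)
    if n_single:
        log.warning("recording %s: %d single-sample segment(s) contributed no eye-feature pairs",
                    rec.recording_id, n_single)
    return EyeKinematicsSeries(
        t_mid=np.asarray(t_mid, dtype=float),
        eye_vel=np.asarray(vel, dtype=float),
        eye_dir=np.asarray(dirn, dtype=float),
        segment=np.asarray(seg_out, dtype=int),
    )
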