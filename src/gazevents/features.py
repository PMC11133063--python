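"""Feature interpolation and assembly of the per-sample feature matrix.

Frame-rate channels (camera motion, patch similarity) and pair-based eye
channels are brought to the gaze timestamps with a not-a-knot cubic spline
fit through their valid knots; invalid knots (failed odometry pairs,
off-frame patches) are dropped before fitting, which is how gaps are
bridged.  Queries outside the knot span are clamped to the boundary knot
value to avoid cubic blow-up at recording edges.  Circular channels
(movement directions in degrees) are unwrapped before interpolation and
re-wrapped to [0, 360) afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ChannelError, SynchronizationError

log = logging.getLogger(__name__)

#: fixed feature order of the six-vector
FEATURE_NAMES = ("eye_vel", "eye_dir", "head_rot_vel", "head_rot_dir",
                 "body_trans_vel", "patch_sim")
#: channels that live on a 360-degree circle
CIRCULAR_FEATURES = ("eye_dir", "head_rot_dir")


@dataclass
class FeatureMatrix:
    """Per-sample six-feature matrix aligned to gaze timestamps."""

    t: np.ndarray
    features: np.ndarray  # (n, 6) in FEATURE_NAMES order
    label: np.ndarray
    cut_before: np.ndarray
    recording_id: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.features = np.asarray(self.features, dtype=float)
        self.label = np.asarray(self.label, dtype=int)
        self.cut_before = np.asarray(self.cut_before, dtype=bool)
        if self.features.ndim != 2 or self.features.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"features must be (n, {len(FEATURE_NAMES)})")

    def __len__(self) -> int:
        return len(self.t)

    def column(self, name: str) -> np.ndarray:
        return self.features[:, FEATURE_NAMES.index(name)]

    def take(self, idx: np.ndarray, cut_before: np.ndarray | None = None) -> "FeatureMatrix":
        idx = np.asarray(idx, dtype=int)
        cuts = self.cut_before[idx] if cut_before is None else np.asarray(cut_before, bool)
        return FeatureMatrix(self.t[idx], self.features[idx], self.label[idx],
                             cuts, self.recording_id)


def interpolate_channel(t_knots: np.ndarray, values: np.ndarray, t_query: np.ndarray,
                        valid: np.ndarray | None = None,
                        name: str = "channel") -> np.ndarray:
    """Evaluate a cubic interpolant through the valid knots at ``t_query``.

    Not-a-knot cubic spline for >= 4 knots; linear interpolation for 2-3
    knots.  Queries outside [first, last] knot are clamped to the boundary
    knot value.  Fewer than 2 valid knots raises :class:`ChannelError`.
    """
    t_knots = np.asarray(t_knots, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    if valid is not None:
        keep &= np.asarray(valid, dtype=bool)
    t_k, v_k = t_knots[keep], values[keep]
    if t_k.size < 2:
        raise ChannelError(name, f"only {t_k.size} valid knot(s), need >= 2")
    if np.any(np.diff(t_k) <= 0):
        raise ChannelError(name, "knot times not strictly increasing")
    tq = np.clip(np.asarray(t_query, dtype=float), t_k[0], t_k[-1])
    if t_k.size < 4:
        return np.interp(tq, t_k, v_k)
    return CubicSpline(t_k, v_k, bc_type="not-a-knot")(tq)


def _interp_circular(t_knots, values_deg, t_query, valid=None, name="channel"):
    unwrapped = np.unwrap(np.asarray(values_deg, dtype=float), period=360.0)
    out = interpolate_channel(t_knots, unwrapped, t_query, valid=valid, name=name)
    return np.mod(out, 360.0)


def _interp_segmented(t_knots, values, seg_knots, t_query, seg_query, *,
                      circular: bool, name: str) -> np.ndarray:
    """Interpolate per contiguous segment so cuts are never bridged.

    Segments with a single knot yield that constant; segments with no knots
    fall back to the nearest knot of the whole series (logged).
    """
    out = np.empty(len(t_query), dtype=float)
    fn = _interp_circular if circular else interpolate_channel
    n_fallback = 0
    for s in np.unique(seg_query):
        q = seg_query == s
        k = seg_knots == s
        if k.sum() >= 2:
            out[q] = fn(t_knots[k], values[k], t_query[q], name=name)
        elif k.sum() == 1:
            out[q] = values[k][0]
        else:
            if len(t_knots) == 0:
                raise ChannelError(name, "no knots at all")
            nearest = np.argmin(np.abs(t_knots[:, None] - t_query[None, q]), axis=0)
            out[q] = values[nearest]
            n_fallback += 1
    if n_fallback:
        log.warning("channel %s: %d segment(s) had no knots; nearest-knot fallback used",
                    name, n_fallback)
    return out


def assemble_feature_matrix(rec, eye, cam, patch) -> FeatureMatrix:
    """Assemble the per-sample feature matrix from the three feature series.

    Parameters
    ----------
    rec : cleaned :class:`~gazevents.io.GazeRecording`
    eye : :class:`~gazevents.eye.EyeKinematicsSeries`
    cam : :class:`~gazevents.vo.CameraMotionSeries`
    patch : :class:`~gazevents.patches.PatchSimilaritySeries`

    Eye channels are interpolated per contiguous gaze segment; frame-rate
    channels over their full valid knot sets.  Labels and cut flags are
    carried over unchanged, so the row count equals the cleaned sample count.
    """
    t = rec.t
    if len(cam.t_mid) and (cam.t_mid[0] > t[-1] or cam.t_mid[-1] < t[0]):
        raise SynchronizationError(
            f"video span [{cam.t_mid[0]:.3f}, {cam.t_mid[-1]:.3f}] does not overlap "
            f"gaze span [{t[0]:.3f}, {t[-1]:.3f}]")
    seg_query = np.cumsum(rec.cut_before)
    cols = {}
    cols["eye_vel"] = _interp_segmented(eye.t_mid, eye.eye_vel, eye.segment, t, seg_query,
                                        circular=False, name="eye_vel")
    cols["eye_dir"] = _interp_segmented(eye.t_mid, eye.eye_dir, eye.segment, t, seg_query,
                                        circular=True, name="eye_dir")
    cols["head_rot_vel"] = interpolate_channel(cam.t_mid, cam.head_rot_vel, t,
                                               valid=cam.valid, name="head_rot_vel")
    cols["head_rot_dir"] = _interp_circular(cam.t_mid, cam.head_rot_dir, t,
                                            valid=cam.valid, name="head_rot_dir")
    cols["body_trans_vel"] = interpolate_channel(cam.t_mid, cam.body_trans_vel, t,
                                                 valid=cam.valid, name="body_trans_vel")
    cols["patch_sim"] = interpolate_channel(patch.t_mid, patch.score, t,
                                            valid=patch.valid, name="patch_sim")
    # spline undershoot can take non-negative channels slightly negative and
    # ZNCC scores slightly outside [-1, 1]; clamp to the channels' ranges
    for name in ("eye_vel", "head_rot_vel", "body_trans_vel"):
        np.maximum(cols[name], 0.0, out=cols[name])
    np.clip(cols["patch_sim"], -1.0, 1.0, out=cols["patch_sim"])
    X = np.column_stack([cols[name] for name in FEATURE_NAMES])
    if not np.all(np.isfinite(X)):
        bad = np.flatnonzero(~np.isfinite(X).all(axis=1))
        raise ChannelError("assembly", f"non-finite features at rows {bad[:5].tolist()}")
    return FeatureMatrix(t=t, features=X, label=rec.label.copy(),
                         cut_before=rec.cut_before.copy(), recording_id=rec.recording_id)


def concat_matrices(mats) -> tuple[np.ndarray, np.ndarray]:
    """Stack features and labels of several matrices for classifier training."""
    X = np.vstack([m.features for m in mats])
    y = np.concatenate([m.label for m in mats])
    return X, y
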