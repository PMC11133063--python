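"""Gaze-patch extraction and frame-to-frame content similarity.

A fixed-size grayscale patch (default 64x64 px) is cut out around the gaze
point of each scene frame; consecutive patches are scored with
zero-normalized cross-correlation (ZNCC, range [-1, 1]).  When gaze rests
on one object the score stays high; when gaze lands on a new object the
score drops, which is the signal the classifier uses.  Other similarity
backends can be plugged in through the same two-patch score contract
(each backend documents its own score range).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import PipelineError, ValidationError
from .io import GazeRecording, SceneVideo

DEFAULT_PATCH_SIZE = 64
#: a patch is usable if at least this fraction of its area is inside the frame
VALIDITY_THRESHOLD = 0.5


@dataclass
class GazePatch:
    """Square grayscale patch centered on the (rounded) gaze point.

    Out-of-frame pixels are zero-filled; ``frac_inside`` is the fraction of
    the patch area that fell inside the frame.
    """

    pixels: np.ndarray
    center_px: tuple[float, float]
    frac_inside: float
    valid: bool


@dataclass
class PatchSimilaritySeries:
    """Similarity score per consecutive frame pair at midpoint times."""

    t_mid: np.ndarray
    score: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.t_mid)


def extract_patch(frame: np.ndarray, gaze_px: tuple[float, float],
                  size: int = DEFAULT_PATCH_SIZE) -> GazePatch:
    """Extract a ``size`` x ``size`` window centered at the gaze point.

    Never raises on off-frame gaze; the patch is simply marked invalid when
    less than half its area lies inside the frame.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 3:
        frame = frame.mean(axis=2)
    x, y = gaze_px
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValidationError(f"gaze point must be finite, got {gaze_px}")
    half = size // 2
    cx, cy = int(round(x)), int(round(y))
    out = np.zeros((size, size), dtype=float)
    h, w = frame.shape
    y0, y1 = cy - half, cy - half + size
    x0, x1 = cx - half, cx - half + size
    sy0, sy1 = max(y0, 0), min(y1, h)
    sx0, sx1 = max(x0, 0), min(x1, w)
    inside = 0.0
    if sy1 > sy0 and sx1 > sx0:
        out[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = frame[sy0:sy1, sx0:sx1]
        inside = (sy1 - sy0) * (sx1 - sx0) / float(size * size)
    return GazePatch(out, (float(x), float(y)), inside, inside >= VALIDITY_THRESHOLD)


def patch_score(p: GazePatch, q: GazePatch) -> float:
    """Zero-normalized cross-correlation of two valid patches, in [-1, 1].

    Symmetric; 1 for identical non-constant patches, -1 for
    contrast-inverted ones.  A constant (zero-variance) patch cannot be
    normalized and scores 0 by convention.
    """
    for name, patch in (("p", p), ("q", q)):
        if not patch.valid:
            raise ValidationError(f"patch {name} is invalid (frac_inside={patch.frac_inside})")
    a = p.pixels - p.pixels.mean()
    b = q.pixels - q.pixels.mean()
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        return 0.0
    return float(np.clip((a * b).mean() / (sa * sb), -1.0, 1.0))


def gaze_at_frames(rec: GazeRecording, frame_times: np.ndarray) -> np.ndarray:
    """Gaze pixel nearest in time to each frame timestamp, shape (n_frames, 2)."""
    frame_times = np.asarray(frame_times, dtype=float)
    idx = np.searchsorted(rec.t, frame_times)
    idx = np.clip(idx, 1, len(rec.t) - 1)
    left = frame_times - rec.t[idx - 1] <= rec.t[idx] - frame_times
    idx = np.where(left, idx - 1, idx)
    return rec.gaze_px[idx]


def compute_similarity_series(video: SceneVideo, gaze_px_per_frame: np.ndarray,
                              size: int = DEFAULT_PATCH_SIZE,
                              score_fn: Callable[[GazePatch, GazePatch], float] = patch_score,
                              ) -> PatchSimilaritySeries:
    """Score the gaze patches of every consecutive frame pair.

    Pairs with an off-frame (invalid) patch are marked invalid and later
    bridged by channel interpolation.
    """
    gaze_px_per_frame = np.asarray(gaze_px_per_frame, dtype=float)
    if len(gaze_px_per_frame) != len(video):
        raise ValidationError(
            f"{len(gaze_px_per_frame)} gaze points for {len(video)} frames")
    n = len(video) - 1
    t_mid = 0.5 * (video.frame_times[:-1] + video.frame_times[1:])
    score = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    prev = extract_patch(video.frames[0], gaze_px_per_frame[0], size)
    for i in range(n):
        cur = extract_patch(video.frames[i + 1], gaze_px_per_frame[i + 1], size)
        if prev.valid and cur.valid:
            score[i] = score_fn(prev, cur)
            valid[i] = True
        prev = cur
    if n and not valid.any():
        raise PipelineError("all patch pairs invalid; gaze never inside the frame")
    return PatchSimilaritySeries(t_mid, score, valid)
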