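"""Reading, writing and preprocessing of gaze recordings, scene video and feature tables.

On-disk formats
---------------
Gaze file
    CSV with header ``t,gx,gy,gz,px,py,label`` (optionally ``cut_before``),
    UTF-8, '.' decimal.  ``(gx, gy, gz)`` is the head-centered gaze direction
    (x right, y up, z forward); it is renormalized to unit length on read.
Video
    Directory of zero-padded numbered PNG frames plus a ``frame_times.csv``
    sidecar (column ``t``) or a ``meta.json`` with ``{"frame_rate": <Hz>}``.
Intrinsics
    JSON with keys ``fx, fy, cx, cy, width, height`` (pinhole, pixels).
Feature table
    CSV with the fixed header
    ``t,eye_vel,eye_dir,head_rot_vel,head_rot_dir,body_trans_vel,patch_sim,label,cut_before``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ValidationError
from .features import FEATURE_NAMES, FeatureMatrix

GAZE_COLUMNS = ("t", "gx", "gy", "gz", "px", "py", "label")
VALID_LABELS = frozenset(range(6))
#: labels removed during preprocessing: 0 = unlabeled, 5 = blink
REMOVED_LABELS = (0, 5)


@dataclass
class CameraIntrinsics:
    """Pinhole camera model of the scene camera (all units: pixels)."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValidationError(f"focal lengths must be positive, got fx={self.fx}, fy={self.fy}")
        if not (0 <= self.cx < self.width) or not (0 <= self.cy < self.height):
            raise ValidationError(
                f"principal point ({self.cx}, {self.cy}) outside frame {self.width}x{self.height}"
            )

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    def to_dict(self) -> dict:
        return {
            "fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
            "width": self.width, "height": self.height,
        }


@dataclass
class GazeRecording:
    """Time-ordered gaze samples of one recording.

    Attributes
    ----------
    t : (n,) float seconds, strictly increasing
    gaze_dir : (n, 3) unit vectors, head-centered (x right, y up, z forward)
    gaze_px : (n, 2) gaze point in scene-image pixel coordinates (x right, y down)
    label : (n,) int in 0..5
    cut_before : (n,) bool, True marks a discontinuity immediately before the sample
    """

    recording_id: str
    t: np.ndarray
    gaze_dir: np.ndarray
    gaze_px: np.ndarray
    label: np.ndarray
    cut_before: np.ndarray = None
    nominal_rate: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.gaze_dir = np.asarray(self.gaze_dir, dtype=float)
        self.gaze_px = np.asarray(self.gaze_px, dtype=float)
        self.label = np.asarray(self.label, dtype=int)
        if self.cut_before is None:
            self.cut_before = np.zeros(len(self.t), dtype=bool)
        self.cut_before = np.asarray(self.cut_before, dtype=bool)
        n = len(self.t)
        for name, arr in (("gaze_dir", self.gaze_dir), ("gaze_px", self.gaze_px),
                          ("label", self.label), ("cut_before", self.cut_before)):
            if len(arr) != n:
                raise DataError(f"{name} has {len(arr)} rows, expected {n}")
        if n:
            bad = np.flatnonzero(np.diff(self.t) <= 0)
            if bad.size:
                raise DataError(f"timestamps not strictly increasing at index {bad[0] + 1}")
            bad_label = np.flatnonzero(~np.isin(self.label, list(VALID_LABELS)))
            if bad_label.size:
                i = bad_label[0]
                raise DataError(f"label {self.label[i]} out of range 0..5 at row {i}")
            norms = np.linalg.norm(self.gaze_dir, axis=1)
            if np.any(norms < 1e-12):
                raise DataError(f"zero-norm gaze direction at row {np.argmin(norms)}")
            self.gaze_dir = self.gaze_dir / norms[:, None]

    def __len__(self) -> int:
        return len(self.t)

    def segment_bounds(self) -> np.ndarray:
        """Start indices of contiguous (un-cut) spans, including index 0."""
        return np.flatnonzero(np.r_[True, self.cut_before[1:]])


@dataclass
class SceneVideo:
    """Timestamped grayscale frames with the camera's pinhole intrinsics."""

    frames: Sequence[np.ndarray]
    frame_times: np.ndarray
    intrinsics: CameraIntrinsics

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if len(self.frames) != len(self.frame_times):
            raise FormatError(
                f"{len(self.frames)} frames but {len(self.frame_times)} timestamps"
            )
        if len(self.frame_times) and np.any(np.diff(self.frame_times) <= 0):
            raise DataError("frame timestamps not strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


def read_gaze_csv(path, recording_id: str | None = None,
                  nominal_rate: float | None = None) -> GazeRecording:
    """Read a gaze CSV (header ``t,gx,gy,gz,px,py,label``) into a :class:`GazeRecording`.

    Gaze directions are renormalized to unit length; rows are kept in file
    order.  Missing columns raise :class:`FormatError`; invariant violations
    (non-monotonic time, out-of-range label) raise :class:`DataError`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in GAZE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    cuts = df["cut_before"].to_numpy(dtype=bool) if "cut_before" in df.columns else None
    return GazeRecording(
        recording_id=recording_id or path.stem,
        t=df["t"].to_numpy(),
        gaze_dir=df[["gx", "gy", "gz"]].to_numpy(),
        gaze_px=df[["px", "py"]].to_numpy(),
        label=df["label"].to_numpy(),
        cut_before=cuts,
        nominal_rate=nominal_rate,
    )


def write_gaze_csv(rec: GazeRecording, path) -> None:
    df = pd.DataFrame({
        "t": rec.t,
        "gx": rec.gaze_dir[:, 0], "gy": rec.gaze_dir[:, 1], "gz": rec.gaze_dir[:, 2],
        "px": rec.gaze_px[:, 0], "py": rec.gaze_px[:, 1],
        "label": rec.label,
        "cut_before": rec.cut_before.astype(int),
    })
    df.to_csv(path, index=False)


def read_intrinsics(path) -> CameraIntrinsics:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    try:
        return CameraIntrinsics(
            fx=float(data["fx"]), fy=float(data["fy"]),
            cx=float(data["cx"]), cy=float(data["cy"]),
            width=int(data["width"]), height=int(data["height"]),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing intrinsics key {exc}") from exc


def write_intrinsics(intr: CameraIntrinsics, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(intr.to_dict(), fh, indent=1)


_FRAME_RE = re.compile(r"(\d+)\.png$")


def read_scene_video(path, intrinsics_path) -> SceneVideo:
    """Read a directory of numbered PNG frames plus a timestamp sidecar.

    Timestamps come from ``frame_times.csv`` (column ``t``) if present,
    otherwise from a constant-rate declaration ``meta.json``
    (``{"frame_rate": <Hz>}``) giving times 0, 1/rate, 2/rate, ...
    """
    path = Path(path)
    intr = read_intrinsics(intrinsics_path)
    files = sorted(
        (p for p in path.iterdir() if _FRAME_RE.search(p.name)),
        key=lambda p: int(_FRAME_RE.search(p.name).group(1)),
    )
    if not files:
        raise FormatError(f"{path}: no numbered .png frames found")
    frames = []
    for i, p in enumerate(files):
        try:
            img = iio.imread(p)
        except Exception as exc:  # noqa: BLE001 - re-raise with frame index
            raise IOError(f"unreadable frame index {i} ({p.name}): {exc}") from exc
        if img.ndim == 3:
            img = img.mean(axis=2)
        frames.append(np.asarray(img))
    times_file = path / "frame_times.csv"
    meta_file = path / "meta.json"
    if times_file.exists():
        tdf = pd.read_csv(times_file)
        if "t" not in tdf.columns:
            raise FormatError(f"{times_file}: missing column 't'")
        frame_times = tdf["t"].to_numpy(dtype=float)
    elif meta_file.exists():
        with open(meta_file, encoding="utf-8") as fh:
            rate = float(json.load(fh)["frame_rate"])
        frame_times = np.arange(len(frames)) / rate
    else:
        raise FormatError(f"{path}: no frame_times.csv or meta.json timestamp source")
    return SceneVideo(frames=frames, frame_times=frame_times, intrinsics=intr)


def clean_recording(rec: GazeRecording,
                    calibration_windows: Sequence[tuple[float, float]] = ()) -> GazeRecording:
    """Remove unlabeled (0) and blink (5) samples and calibration windows.

    The first retained sample after every removed block gets
    ``cut_before = True`` so that difference-based features and event
    segmentation never straddle a removed span.  Idempotent.
    """
    if len(rec) == 0:
        raise DataError("cannot clean an empty recording")
    remove = np.isin(rec.label, REMOVED_LABELS)
    for t0, t1 in calibration_windows:
        remove |= (rec.t >= t0) & (rec.t <= t1)
    keep = np.flatnonzero(~remove)
    if keep.size == 0:
        raise DataError(f"recording '{rec.recording_id}': all samples removed by cleaning")
    if keep.size < 2:
        raise DataError(f"recording '{rec.recording_id}': fewer than 2 samples after cleaning")
    # a kept sample is cut if its own flag was set or if any sample was
    # removed between it and the previous kept one
    new_cuts = rec.cut_before[keep].copy()
    new_cuts[1:] |= np.diff(keep) > 1
    return GazeRecording(
        recording_id=rec.recording_id,
        t=rec.t[keep],
        gaze_dir=rec.gaze_dir[keep],
        gaze_px=rec.gaze_px[keep],
        label=rec.label[keep],
        cut_before=new_cuts,
        nominal_rate=rec.nominal_rate,
    )


FEATURE_TABLE_COLUMNS = ("t",) + FEATURE_NAMES + ("label", "cut_before")


def write_feature_table(matrix: FeatureMatrix, path) -> None:
    df = pd.DataFrame({"t": matrix.t})
    for j, name in enumerate(FEATURE_NAMES):
        df[name] = matrix.features[:, j]
    df["label"] = matrix.label
    df["cut_before"] = matrix.cut_before.astype(int)
    df.to_csv(path, index=False)


def read_feature_table(path, recording_id: str | None = None) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    if tuple(df.columns) != FEATURE_TABLE_COLUMNS:
        raise FormatError(
            f"{path}: feature-table columns {tuple(df.columns)} != {FEATURE_TABLE_COLUMNS}"
        )
    n = len(df)
    feats = df[list(FEATURE_NAMES)].to_numpy(dtype=float) if n else np.empty((0, len(FEATURE_NAMES)))
    return FeatureMatrix(
        t=df["t"].to_numpy(dtype=float),
        features=feats,
        label=df["label"].to_numpy(dtype=int),
        cut_before=df["cut_before"].to_numpy(dtype=bool),
        recording_id=recording_id or path.stem,
    )
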