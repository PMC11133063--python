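"""End-to-end feature extraction: recording + video -> per-sample feature matrix."""

from __future__ import annotations

from .eye import compute_eye_series
from .features import FeatureMatrix, assemble_feature_matrix
from .io import GazeRecording, SceneVideo, clean_recording
from .patches import compute_similarity_series, gaze_at_frames
from .vo import OdometryConfig, compute_camera_series


def extract_features(rec: GazeRecording, video: SceneVideo,
                     odometry: OdometryConfig | None = None,
                     patch_size: int = 64,
                     vo_backend=None,
                     camera_series=None) -> FeatureMatrix:
    """Compute the six-feature matrix for one *cleaned* recording.

    ``camera_series`` may carry a precomputed
    :class:`~gazevents.vo.CameraMotionSeries` (e.g. from an injected pose
    file), bypassing the odometry backend.
    """
    eye = compute_eye_series(rec)
    if camera_series is None:
        camera_series = compute_camera_series(video, odometry, backend=vo_backend)
    patch = compute_similarity_series(video, gaze_at_frames(rec, video.frame_times),
                                      size=patch_size)
    return assemble_feature_matrix(rec, eye, camera_series, patch)


def process_recording(rec: GazeRecording, video: SceneVideo,
                      calibration_windows=(),
                      odometry: OdometryConfig | None = None,
                      patch_size: int = 64) -> FeatureMatrix:
    """Clean a raw recording (blinks, unlabeled, calibration) and extract features."""
    cleaned = clean_recording(rec, calibration_windows)
    return extract_features(cleaned, video, odometry=odometry, patch_size=patch_size)
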