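"""Shared fixtures: small simulated recordings reused across test modules."""

import numpy as np
import pytest

from gazevents.io import CameraIntrinsics
from gazevents.pipeline import process_recording
from gazevents.synthetic import (SimulationConfig, build_scene_texture,
                                 default_event_script, simulate_recording)


@pytest.fixture(scope="session")
def intrinsics():
    return CameraIntrinsics(277.0, 277.0, 159.5, 119.5, 320, 240)


@pytest.fixture(scope="session")
def scene_texture():
    return build_scene_texture(7)


@pytest.fixture(scope="session")
def demo_recording():
    """One 8 s synthetic recording containing all four event types."""
    rng = np.random.default_rng(5)
    cfg = SimulationConfig(event_script=default_event_script(8.0, rng), seed=5)
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def demo_features(demo_recording):
    """Feature matrix of the demo recording (full pipeline output)."""
    return process_recording(demo_recording.gaze, demo_recording.video)


@pytest.fixture(scope="session")
def small_dataset():
    """Four 12 s recordings with features, enough for quick validation runs."""
    mats = []
    for i in range(4):
        rng = np.random.default_rng(100 + i)
        cfg = SimulationConfig(event_script=default_event_script(12.0, rng), seed=100 + i)
        gt = simulate_recording(cfg)
        mats.append(process_recording(gt.gaze, gt.video))
    return mats


def random_labeled_recording(rng, n_classes=4, n_runs=12, min_len=4, max_len=20):
    """Random label sequence made of same-class runs, with occasional cut flags."""
    labels = []
    for _ in range(n_runs):
        labels.extend([int(rng.integers(1, n_classes + 1))] * int(rng.integers(min_len, max_len)))
    labels = np.asarray(labels)
    cuts = rng.random(labels.size) < 0.02
    cuts[0] = False
    return labels, cuts
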