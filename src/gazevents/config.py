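"""Declarative run configuration: YAML file + command-line overrides.

Unknown keys are rejected (with their full field path) rather than ignored,
and a parsed config echoes back identically, so a run manifest fully
determines a run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .errors import ValidationError

#: every known key with its default; nested dicts define sections
DEFAULTS: dict = {
    "paths": {
        "dataset": "dataset",
        "features": "features",
        "model": "model.joblib",
        "predictions": "predictions",
        "report": "report",
    },
    "simulate": {
        "n_recordings": 6,
        "duration": 60.0,
        "gaze_rate": 120.0,
        "frame_rate": 30.0,
        "noise_deg": 0.1,
        "blink_fraction": 0.0,
        "seed": 0,
    },
    "odometry": {
        "n_corners": 150,
        "block_radius": 5,
        "search_radius": 8,
        "downscale": 2,
        "ransac_threshold_px": 1.0,
        "min_inliers": 15,
    },
    "features": {
        "patch_size": 64,
    },
    "evaluate": {
        "mode": "loo",
        "test_fraction": 0.2,
        "seed": 0,
        "label_merge": {},
    },
    "classifier": {
        "seed": 0,
        "hyperparameters": {},
    },
    "verbosity": "info",
}

#: keys whose values are free-form mappings (not validated recursively)
_OPEN_MAPPINGS = {("evaluate", "label_merge"), ("classifier", "hyperparameters")}


def _merge(defaults: dict, user: dict, path: tuple = ()) -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in user:
            uval = user[key]
            if isinstance(dval, dict) and (path + (key,)) not in _OPEN_MAPPINGS:
                if not isinstance(uval, dict):
                    raise ValidationError(f"config field '{'.'.join(path + (key,))}' "
                                          f"must be a mapping")
                out[key] = _merge(dval, uval, path + (key,))
            else:
                out[key] = uval
        else:
            out[key] = {k: v for k, v in dval.items()} if isinstance(dval, dict) else dval
            if isinstance(dval, dict) and (path + (key,)) not in _OPEN_MAPPINGS:
                out[key] = _merge(dval, {}, path + (key,))
    for key in user:
        if key not in defaults:
            raise ValidationError(f"unknown config key '{'.'.join(path + (key,))}'")
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load, validate and default-fill a run configuration."""
    user: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValidationError(f"{path}: config root must be a mapping")
    cfg = _merge(DEFAULTS, user)
    for dotted, value in (overrides or {}).items():
        node = cfg
        parts = dotted.split(".")
        probe = DEFAULTS
        for p in parts[:-1]:
            if not isinstance(probe, dict) or p not in probe:
                raise ValidationError(f"unknown config key '{dotted}'")
            probe = probe[p]
            node = node.setdefault(p, {})
        if not isinstance(probe, dict) or parts[-1] not in probe:
            raise ValidationError(f"unknown config key '{dotted}'")
        node[parts[-1]] = yaml.safe_load(value) if isinstance(value, str) else value
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def write_manifest(path, cfg: dict, extra: dict | None = None) -> None:
    import numpy
    import sklearn
    import skimage

    from . import __version__

    manifest = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "versions": {
            "gazevents": __version__,
            "numpy": numpy.__version__,
            "scikit-learn": sklearn.__version__,
            "scikit-image": skimage.__version__,
        },
    }
    manifest.update(extra or {})
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
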