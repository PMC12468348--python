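"""YAML run configuration with per-section defaults."""

from __future__ import annotations

import copy
import pathlib

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config"]

DEFAULT_CONFIG: dict = {
    "preprocess": {
        "target_size": [224, 224],
        "roi_threshold": 0.05,
        "sigma": None,            # null -> width / 30
        "blur_enabled": True,
        "blend": [0.0, 1.0, 0.0],
    },
    "sr": {
        "n_blocks": 4,
        "channels": 32,
        "patch_side": 2,
        "scale": 2,
        "psgm_deformable": True,
        "ipgm_residual": True,
        "epochs": 5,
        "batch_size": 8,
        "lr": 1e-3,
        "crop_size": 48,
    },
    "classifier": {
        "model": "refinenet_u",
        "input_side": 448,
        "encoder_filters": [64, 128, 256, 512],
        "epochs": 3,
        "batch_size": 20,
        "lr": 5e-4,
    },
    "synth": {
        "image_side": 448,
        "n_per_grade": 10,
        "noise_sigma": 4.0,
        "illumination_gradient": 0.1,
    },
    "eval": {
        "average": "macro",
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None) -> dict:
    """Load a YAML config, overlaying user values onto the defaults."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    text = pathlib.Path(path).read_text()
    user = yaml.safe_load(text) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return _merge(DEFAULT_CONFIG, user)
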