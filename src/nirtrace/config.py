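"""Declarative run configuration (YAML).

A run config collects the knobs of the full pipeline — wavelength window,
preprocessing preset, OPS settings, classifier Q and PC subset, seeds — so a
complete analysis is reproducible from one file.  Only keys that are present
override the defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

DEFAULTS = {
    "working_range_nm": [1000.0, 1798.0],
    "preprocess": "SG17-SD",
    "split": {"plan": "random_fraction", "n_calibration": 148, "seed": 0},
    "ops": {
        "informative": "regression_vector",
        "l_model": None,  # None: LOO-CV-selected on the full wavelength set
        "l_eval": None,
        "window": 20,
        "increment": 5,
    },
    "pls": {"l_max": 15},
    "classify": {
        "q": 0.25,
        "used_components": [1, 2, 3],  # zero-based: PC2, PC3, PC4
        "shrinkage": 0.1,
        "step1_preprocess": "SG17-SD",
        "step2_preprocess": "SD+VN",
    },
    "generator": {"seed": 0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path=None) -> dict:
    """Load a YAML run config, filling unspecified keys with defaults."""
    if path is None:
        return _merge(DEFAULTS, {})
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"{path} is not a mapping")
    return _merge(DEFAULTS, user)


def save_config(cfg: dict, path) -> str:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return str(path)
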