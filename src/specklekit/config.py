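"""Run configuration: YAML loading, validation, seed resolution."""

from __future__ import annotations

from pathlib import Path

import yaml

__all__ = ["load_config", "resolve_config", "DEFAULTS"]

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "specklekit_out",
    "log_level": "INFO",
    "simulate": {
        "grid_size": 128,
        "object_fraction": 0.08,
        "n_blobs": 6,
        "density_range": [0.3, 1.0],
        "pixel_nm": 13.7,
        "n_steps": 4,
        "high_decay": 0.08,
        "low_swell": 0.35,
        "swell_peak_step": 2,
        "photon_budget": 1.0e6,
        "stop_halfwidth": 3,
        "stop_offset": [1, 2],
        "bin_factor": 1,
    },
    "reconstruct": {
        "n_runs": 24,
        "n_iterations": 2000,
        "n_stages": 10,
        "beta": 0.9,
        "constraint": "real_nonneg",
        "support_threshold": 0.1,
    },
    "cluster": {
        "backbone": "random-conv",
        "n_components": 10,
        "k": 4,
        "n_best": 24,
    },
    "metrics": {
        "shell_width": 1,
        "tail_fraction": 0.1,
        "resolution_threshold": 0.36787944117144233,  # 1/e
    },
    "damage": {
        "calibration": 1.0,
        "regions": [],
    },
}

# seeds derived from the global seed so every stochastic stage is explicit
_STAGE_SEED_OFFSETS = {"simulate": 0, "reconstruct": 1009, "cluster": 2003}


def _check_keys(given: dict, allowed: dict, where: str) -> None:
    unknown = set(given) - set(allowed)
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def resolve_config(overrides: dict | None = None, seed: int | None = None) -> dict:
    """Merge overrides onto the defaults, rejecting unknown keys, and give
    every stochastic stage an explicit seed."""
    overrides = overrides or {}
    _check_keys(overrides, DEFAULTS, "top level")
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
    for key, val in overrides.items():
        if isinstance(DEFAULTS[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            _check_keys(val, DEFAULTS[key], f"section {key!r}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    if seed is not None:
        cfg["seed"] = int(seed)
    base = int(cfg["seed"])
    cfg["stage_seeds"] = {
        stage: base + off for stage, off in _STAGE_SEED_OFFSETS.items()
    }
    return cfg


def load_config(path, seed: int | None = None) -> dict:
    """Load and validate a YAML run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return resolve_config(data, seed=seed)
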