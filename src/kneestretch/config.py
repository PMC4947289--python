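"""Run configuration: YAML schema with strict key validation.

Every CLI entry point accepts an optional config file; unknown keys are
rejected up front so typos fail before any computation starts.
"""

from __future__ import annotations

from pathlib import Path

import yaml

__all__ = ["SCHEMA", "validate_config", "load_config"]

# allowed keys -> nested schema (None = scalar leaf)
SCHEMA = {
    "seed": None,
    "output_dir": None,
    "tendon_mode": None,
    "trials": {"slow": None, "fast": None},
    "anthropometry": {"height": None, "mass": None, "leg_length": None,
                      "tibia_length": None},
    "reflex": {"G": None, "T": None, "t_d": None, "target_muscle": None,
               "enabled": None},
    "sim": {"dt": None, "duration": None, "initial_velocity_deg_s": None},
    "fit": {"start": None, "max_iter": None, "xatol": None, "fatol": None},
    "evaluation": {"stretch_end": None, "hold_end": None},
    "synth": {"n_td": None, "n_cp": None, "slow_duration_s": None,
              "fast_stretch_s": None, "angle_noise_deg": None,
              "force_noise_N": None, "emg_background": None,
              "emg_burst_gain": None, "tendon_mode": None},
}


def validate_config(cfg: dict, schema=None, path="") -> dict:
    """Recursively reject unknown keys; returns the config unchanged."""
    schema = SCHEMA if schema is None else schema
    if not isinstance(cfg, dict):
        raise ValueError(f"config section '{path or '<root>'}' must be a mapping")
    for key, value in cfg.items():
        if key not in schema:
            raise ValueError(f"unknown config key '{path}{key}'")
        sub = schema[key]
        if sub is not None:
            validate_config(value, sub, f"{path}{key}.")
    return cfg


def load_config(path) -> dict:
    """Load and validate a YAML run configuration."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    return validate_config(cfg)
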