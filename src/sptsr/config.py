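"""Run configuration: YAML schema, protocol presets, seed control.

Two presets map the package's two experimental regimes:

``t2w_tse_2d``
    the clinical multi-slice 2D protocol (0.625 x 0.625 mm in-plane,
    320 x 320 matrix, 20 slices of 3 mm thickness at 3.6 mm spacing,
    SI crop 320 -> 110, 5.5x through-plane SR);
``sim_3d``
    the simulation protocol (isotropic 1 mm^3 grid, 3 mm-FWHM truncated
    sinc profile, 4 mm slice spacing, 4x downsampling).

Unknown keys are rejected so typos fail loudly, and the effective
configuration of a run is persisted verbatim next to its outputs.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

__all__ = ["PRESETS", "load_config", "resolve_config", "persist_config"]

PRESETS: dict[str, dict] = {
    "t2w_tse_2d": {
        "protocol": {
            "in_plane_spacing_mm": 0.625,
            "matrix": 320,
            "n_slices": 20,
            "slice_thickness_mm": 3.0,
            "slice_spacing_mm": 3.6,
            "crop_si": 110,
            "upsample_factor": 5.5,
            "profile_family": "truncated_sinc",
        },
    },
    "sim_3d": {
        "protocol": {
            "in_plane_spacing_mm": 1.0,
            "matrix": 64,
            "n_slices": 16,
            "slice_thickness_mm": 3.0,
            "slice_spacing_mm": 4.0,
            "crop_si": None,
            "upsample_factor": 4.0,
            "profile_family": "truncated_sinc",
        },
    },
}

_SCHEMA = {
    "preset": str,
    "seed": int,
    "protocol": {
        "in_plane_spacing_mm": float,
        "matrix": int,
        "n_slices": int,
        "slice_thickness_mm": float,
        "slice_spacing_mm": float,
        "crop_si": (int, type(None)),
        "upsample_factor": float,
        "profile_family": str,
        "profile_support_mm": (float, type(None)),
    },
    "phantom": {
        "size": list,
        "noise_model": str,
        "noise_sigma": float,
        "n_ellipsoids": int,
        "n_thin_plates": int,
        "n_rods": int,
    },
    "train": {
        "epochs": int,
        "batch_size": int,
        "learning_rate": float,
        "loss_weights": list,
        "gp_weight": float,
        "critic_steps_per_gen_step": int,
        "base_channels": int,
        "n_residual_blocks": int,
    },
    "deconv": {
        "n_iterations": int,
        "damping_threshold": float,
        "boundary": str,
    },
    "metrics": {
        "ssim_plane": str,
        "psnr_peak": (float, type(None)),
    },
}


def _validate(node, schema, path="") -> None:
    if not isinstance(node, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    for key, value in node.items():
        where = f"{path}.{key}" if path else key
        if key not in schema:
            raise ValueError(f"unknown config key: {where}")
        expected = schema[key]
        if isinstance(expected, dict):
            _validate(value, expected, where)
        elif expected is float:
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ValueError(f"config key {where} must be a number")
        elif not isinstance(value, expected):
            raise ValueError(f"config key {where} has the wrong type")


def resolve_config(raw: dict) -> dict:
    """Validate a raw mapping and merge in its preset (if any)."""
    _validate(raw, _SCHEMA)
    preset_name = raw.get("preset")
    merged: dict = {}
    if preset_name is not None:
        if preset_name not in PRESETS:
            raise ValueError(f"unknown preset {preset_name!r}")
        merged = copy.deepcopy(PRESETS[preset_name])
    for key, value in raw.items():
        if key == "preset":
            continue
        if isinstance(value, dict):
            merged.setdefault(key, {}).update(value)
        else:
            merged[key] = value
    merged.setdefault("seed", 0)
    return merged


def load_config(path) -> dict:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return resolve_config(raw)


def persist_config(config: dict, out_dir) -> Path:
    out = Path(out_dir) / "effective_config.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(config, indent=2, sort_keys=True))
    return out
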