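"""Pipeline configuration: nested defaults, YAML loading, strict key checking."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "merge_config", "dump_config"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "log_level": "INFO",
    "simulate": {
        "field_size_px": 120,
        "pixel_size_um": 0.16,
        "frame_interval_s": 0.005,
        "n_frames": 6000,
        "flash_frame": 400,
        "flash_artifact_frames": 2,
        "baseline_level": 1000.0,
        "noise_sd": 20.0,
        "site_positions_um": None,
        "n_sites": 10,
        "min_separation_um": 2.5,
        "event_rate_per_site_hz": 0.2,
        "amplitude_mean_dFF0": 1.0,
        "amplitude_cv": 0.3,
        "rise_ms": 25.0,
        "decay_tau_ms": 40.0,
        "plateau_ms": 100.0,
        "square_fraction": 0.0,
        "spatial_sigma_um": 0.4,
        "global_rise_per_s": 0.0,
    },
    "simulate_puncta": {
        "field_size_px": 120,
        "pixel_size_um": 0.16,
        "n_spots": 50,
        "colocalized_fraction": 1.0,
        "intensity_correlation": 1.0,
        "spot_sigma_um": 0.2,
        "intensity_range": [100.0, 500.0],
        "min_separation_um": 1.0,
        "noise_sd": 0.0,
    },
    "preprocess": {
        "background": 0.0,
        "baseline_frames": 390,
        "flash_artifact_frames": 2,
        "blur_sigma_px": 2.0,
        "detrend": False,
        "butterworth_cutoff": 0.01,
        "butterworth_order": 2,
    },
    "detection": {
        # threshold in baseline-SD units on the blurred detection stack; the
        # historical 0.25 presumes a different internal scaling and manual
        # curation, see docs/methods.md
        "threshold": 3.0,
        "min_voxels": 4,
        "patch_px": 9,
        "roi_side_um": 1.76,
    },
    "kinetics": {
        "baseline_window_frames": 20,
        "plateau_frac": 0.9,
        "plateau_min_ms": 50.0,
        "obscured_level": 1.5,
        "latency_reference": "peak",
    },
    "sites": {
        "radius_um": 1.0,
        "method": "centroid_update",
    },
    "coloc": {
        "threshold_a": 0.0,
        "threshold_b": 0.0,
        "block_px": 5,
        "n_iter": 100,
        "est_diameter_um": 0.6,
        "quality_min": 0.0,
        "max_diameter_um": 0.6,
        "pixel_size_um": 0.16,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise TypeError(f"config key {here} must be a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


def merge_config(overrides: dict | None = None) -> dict:
    """Defaults merged with overrides; unknown keys are rejected by name."""
    return _merge(DEFAULT_CONFIG, overrides or {})


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML config file over the defaults, then apply overrides."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return copy.deepcopy(cfg)


def dump_config(config: dict, path: str | Path) -> None:
    """Write the fully resolved config next to the run outputs."""
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))
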