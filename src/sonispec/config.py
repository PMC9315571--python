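"""Run configuration: one JSON document for the whole pipeline.

Defaults for every tunable live here, in one place. A config file may
override any subset; unknown keys are rejected rather than ignored, so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

from .phantom import PhantomConfig
from .ratio import DEFAULT_EPS, BinSelection
from .synth import FMParams

__all__ = ["DEFAULTS", "load_config", "merge_config",
           "bins_from_config", "fm_from_config", "phantom_from_config"]

DEFAULTS: dict = {
    "bins": {
        "low_nm": [640, 650, 660, 670],
        "mid_nm": [710, 720, 730, 740],
        "eps": DEFAULT_EPS,
    },
    "fm": {
        "carrier_hz": 220.0,
        "modulator_hz": 110.0,
        "index_scale": 1.0,
        "duration_s": 1.0,
        "sample_rate": 44100,
        "peak_amplitude": 0.8,
        "fade_ms": 10.0,
    },
    "phantom": {
        "rows": 128,
        "cols": 128,
        "wavelengths_nm": [float(w) for w in range(640, 811, 10)],
        "background_level": 100.0,
        "background_slope": 0.01,
        "tumor_center": [64.0, 80.0],
        "tumor_axes": [12.0, 9.0],
        "tumor_amplitude": 300.0,
        "tumor_peak_nm": 720.0,
        "tumor_width_nm": 25.0,
        "skull_roi": [20.0, 20.0, 36.0, 36.0],
        "flank_roi": [90.0, 20.0, 106.0, 36.0],
        "noise_sd": 5.0,
        "noise_model": "gaussian",
        "seed": 0,
    },
    "render": {
        "clip_percentiles": None,   # e.g. [1, 99] to clip a noisy map
        "overlay_threshold": 0.5,
        "overlay_alpha": 0.6,
        "smooth_sigma": 1.5,
    },
    "stats": {
        "paired": False,
        "exact_limit": 12,
    },
}


def merge_config(overrides: dict, defaults: dict | None = None) -> dict:
    """Deep-merge ``overrides`` into the defaults, rejecting unknown keys."""
    merged = copy.deepcopy(DEFAULTS if defaults is None else defaults)

    def _merge(dst: dict, src: dict, path: str) -> None:
        for key, value in src.items():
            if key not in dst:
                raise ValueError(f"unknown config key: {path}{key}")
            if isinstance(dst[key], dict) and isinstance(value, dict):
                _merge(dst[key], value, f"{path}{key}.")
            else:
                dst[key] = value

    _merge(merged, overrides, "")
    return merged


def load_config(path: str | Path | None) -> dict:
    """Load a JSON config file merged over the defaults (None = defaults)."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    return merge_config(json.loads(Path(path).read_text()))


def bins_from_config(config: dict) -> BinSelection:
    section = config["bins"]
    return BinSelection(low_bins_nm=tuple(section["low_nm"]),
                        mid_bins_nm=tuple(section["mid_nm"]))


def fm_from_config(config: dict) -> FMParams:
    section = config["fm"]
    return FMParams(
        carrier_hz=section["carrier_hz"],
        modulator_hz=section["modulator_hz"],
        index_scale=section["index_scale"],
        duration_s=section["duration_s"],
        sample_rate_hz=int(section["sample_rate"]),
        peak_amplitude=section["peak_amplitude"],
        fade_ms=section["fade_ms"],
    )


def phantom_from_config(config: dict, seed: int | None = None) -> PhantomConfig:
    section = config["phantom"]
    return PhantomConfig(
        rows=int(section["rows"]),
        cols=int(section["cols"]),
        wavelengths_nm=tuple(float(w) for w in section["wavelengths_nm"]),
        background_level=section["background_level"],
        background_slope=section["background_slope"],
        tumor_center=tuple(section["tumor_center"]),
        tumor_axes=tuple(section["tumor_axes"]),
        tumor_amplitude=section["tumor_amplitude"],
        tumor_peak_nm=section["tumor_peak_nm"],
        tumor_width_nm=section["tumor_width_nm"],
        skull_roi=tuple(section["skull_roi"]),
        flank_roi=tuple(section["flank_roi"]),
        noise_sd=section["noise_sd"],
        noise_model=section["noise_model"],
        seed=int(section["seed"] if seed is None else seed),
    )
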