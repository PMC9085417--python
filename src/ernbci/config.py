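"""Flat run configuration: every tunable constant under one YAML-able key."""

from __future__ import annotations

from dataclasses import asdict

import yaml

from ernbci.async_detect import DetectorConfig
from ernbci.io_core import EDF_PHYSICAL_RANGE_UV, ValidationError
from ernbci.preprocess import PreprocConfig

#: package-wide defaults; keys mirror the dataclass fields they feed
DEFAULTS = {
    "edf_physical_range_uv": EDF_PHYSICAL_RANGE_UV,
    "band_hz": [0.1, 50.0],
    "l_trans_hz": 0.1,
    "h_trans_hz": 10.0,
    "notch_hz": 50.0,
    "target_fs": 250.0,
    "channel_reject_z": 3.0,
    "max_channel_reject_frac": 0.25,
    "epoch_reject_uv": 100.0,
    "analysis_window_ms": [-100.0, 800.0],
    "classify_window_ms": [0.0, 500.0],
    "interp_neighbors": 4,
    "n_xdawn_filters": 5,
    "pca_retain": 0.99,
    "svm_c": 1.0,
    "window_ms": 500.0,
    "step_ms": 20.0,
    "n_consecutive": 1,
    "latency_tolerance_ms": 200.0,
    "background_region_ms": [-2000.0, -500.0],
    "n_background_per_block": 4,
    "retrigger": True,
    "cluster_alpha": 0.05,
    "n_permutations": 4000,
}


def load_config(path=None) -> dict:
    """Defaults overlaid with the keys of a YAML file (if given)."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def preproc_config(cfg: dict) -> PreprocConfig:
    return PreprocConfig(
        band_hz=tuple(cfg["band_hz"]),
        l_trans_hz=cfg["l_trans_hz"], h_trans_hz=cfg["h_trans_hz"],
        notch_hz=cfg["notch_hz"], target_fs=cfg["target_fs"],
        channel_reject_z=cfg["channel_reject_z"],
        max_channel_reject_frac=cfg["max_channel_reject_frac"],
        epoch_reject_uv=cfg["epoch_reject_uv"],
        analysis_window_ms=tuple(cfg["analysis_window_ms"]),
        classify_window_ms=tuple(cfg["classify_window_ms"]),
        interp_neighbors=cfg["interp_neighbors"],
    )


def detector_config(cfg: dict) -> DetectorConfig:
    return DetectorConfig(
        window_ms=cfg["window_ms"], step_ms=cfg["step_ms"],
        n_consecutive=cfg["n_consecutive"],
        latency_tolerance_ms=cfg["latency_tolerance_ms"],
        background_region_ms=tuple(cfg["background_region_ms"]),
        n_background_per_block=cfg["n_background_per_block"],
        retrigger=cfg["retrigger"], svm_c=cfg["svm_c"],
    )
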