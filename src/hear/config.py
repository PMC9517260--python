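"""Pipeline configuration: defaults, YAML overrides, object builders.

Every default reproduces the study settings: 50-sample windows with step
25, 2 sensors x 9 channels, 7 activity classes, one-level db4 smoothing,
learning rate 2e-4, batch size 128, focal loss with alpha 0.25 and
gamma 2.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .generate import DEFAULT_MAJORITY, DEFAULT_MINORITY
from .losses import LossConfig
from .nn import NetworkSpec
from .train import TrainConfig
from .wavelet import WaveletConfig

DEFAULTS: dict = {
    "seed": 0,
    "data": {"window_length": 50, "step": 25, "n_sensors": 2, "n_channels": 9},
    "generate": {
        "majority": DEFAULT_MAJORITY,
        "minority": DEFAULT_MINORITY,
        "noise_std": 1.0,
        "phase_jitter": 0.8,
        "profile_seed": 0,
    },
    "wavelet": {"family": "db4", "level": 1, "padding": "symmetric"},
    "model": {
        "lstm_units": 32,
        "conv1d_filters": 8,
        "conv1d_kernel": 5,
        "conv2d_sensor_filters": 8,
        "conv2d_fused_filters": 32,
        "conv2d_kernel": [3, 3],
        "head": [64, 32, 16, 8],
        "dropout": 0.5,
    },
    "loss": {"kind": "focal", "alpha": 0.25, "gamma": 2.0},
    "train": {
        "learning_rate": 2.0e-4,
        "batch_size": 128,
        "max_epochs": 200,
        "patience": 10,
        "split_fraction": 0.8,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if k in out and isinstance(out[k], dict) and isinstance(v, dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Defaults, optionally overlaid with a YAML file and then a dict."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def wavelet_config(cfg: dict) -> WaveletConfig:
    w = cfg["wavelet"]
    return WaveletConfig(w["family"], w["level"], w["padding"])


def loss_config(cfg: dict) -> LossConfig:
    l = cfg["loss"]
    if l["kind"] == "cross_entropy":
        return LossConfig.cross_entropy()
    return LossConfig(kind=l["kind"], alpha=l["alpha"], gamma=l["gamma"])


def train_config(cfg: dict, seed: int | None = None) -> TrainConfig:
    t = cfg["train"]
    return TrainConfig(
        learning_rate=t["learning_rate"],
        batch_size=t["batch_size"],
        max_epochs=t["max_epochs"],
        patience=t["patience"],
        split_fraction=t["split_fraction"],
        seed=cfg["seed"] if seed is None else seed,
    )


def network_spec(cfg: dict, t_in: int, n_classes: int) -> NetworkSpec:
    m = cfg["model"]
    d = cfg["data"]
    return NetworkSpec(
        t_in=t_in,
        n_sensors=d["n_sensors"],
        n_channels=d["n_channels"],
        lstm_units=m["lstm_units"],
        conv1d_filters=m["conv1d_filters"],
        conv1d_kernel=m["conv1d_kernel"],
        conv2d_sensor_filters=m["conv2d_sensor_filters"],
        conv2d_fused_filters=m["conv2d_fused_filters"],
        conv2d_kernel=tuple(m["conv2d_kernel"]),
        head=tuple(m["head"]),
        dropout=m["dropout"],
        n_classes=n_classes,
    )
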