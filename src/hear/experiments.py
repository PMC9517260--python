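"""Experiment harnesses: focal vs cross-entropy comparison and gamma sweep.

Both harnesses hold everything except the loss function fixed within a
run: one base seed fans out (with fixed offsets) to data generation, the
stratified split, and weight initialization, so two losses compared under
the same seed see identical data, split and initial weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import WindowedDataset, normalize
from .generate import Scenario, make_profiles, generate_dataset, minority_classes
from .losses import LossConfig
from .nn import NetworkSpec, build_model
from .train import TrainConfig, EvaluationReport, evaluate, split_holdout, train
from .wavelet import WaveletConfig, smooth_dataset

logger = logging.getLogger(__name__)

# fixed seed offsets isolating each randomness source
_DATA_OFFSET = 0
_SPLIT_OFFSET = 100_003
_INIT_OFFSET = 200_003
_SHUFFLE_OFFSET = 300_007


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared settings for one harness run."""

    window_length: int = 50
    n_sensors: int = 2
    profile_seed: int = 0
    wavelet: WaveletConfig = WaveletConfig()
    train: TrainConfig = TrainConfig()
    spec: NetworkSpec | None = None  # derived from the data when None


def prepare_split(
    scen: Scenario, seed: int, cfg: ExperimentConfig
) -> tuple[WindowedDataset, WindowedDataset]:
    """Generate, wavelet-smooth, split and normalize one scenario draw.

    Normalization statistics are fitted on the training side only and
    reused on validation.
    """
    profiles = make_profiles(
        M=scen.n_classes, seed=cfg.profile_seed, n_sensors=cfg.n_sensors
    )
    ds = generate_dataset(
        profiles, scen, T=cfg.window_length, S=cfg.n_sensors,
        seed=seed + _DATA_OFFSET,
    )
    ds = smooth_dataset(ds, cfg.wavelet)
    split_cfg = replace(cfg.train, seed=seed + _SPLIT_OFFSET)
    train_ds, val_ds = split_holdout(ds, split_cfg)
    train_ds, stats = normalize(train_ds, "fit")
    val_ds, _ = normalize(val_ds, stats)
    return train_ds, val_ds


def _spec_for(train_ds: WindowedDataset, cfg: ExperimentConfig) -> NetworkSpec:
    if cfg.spec is not None:
        return cfg.spec
    _, t_in, S, C = train_ds.X.shape
    return NetworkSpec(
        t_in=t_in, n_sensors=S, n_channels=C, n_classes=train_ds.n_classes
    )


def run_single(
    scen: Scenario,
    seed: int,
    loss: LossConfig,
    cfg: ExperimentConfig = ExperimentConfig(),
    prepared: tuple[WindowedDataset, WindowedDataset] | None = None,
) -> tuple[EvaluationReport, pd.DataFrame]:
    """Train one model under one scenario/seed/loss; report on the hold-out."""
    train_ds, val_ds = prepared if prepared is not None else prepare_split(
        scen, seed, cfg)
    spec = _spec_for(train_ds, cfg)
    model = build_model(spec, seed=seed + _INIT_OFFSET)
    fit_cfg = replace(cfg.train, seed=seed + _SHUFFLE_OFFSET)
    history = train(model, train_ds, val_ds, loss=loss, cfg=fit_cfg)
    report = evaluate(model, val_ds, scenario=scen.name, loss_kind=loss.kind)
    return report, history


def _record(scen: Scenario, seed: int, label: str,
            report: EvaluationReport) -> dict:
    minor = minority_classes(scen)
    rec = {
        "scenario": scen.name,
        "seed": seed,
        "loss": label,
        "accuracy": report.accuracy,
        "precision": report.macro_precision,
        "recall": report.macro_recall,
        "f1": report.macro_f1,
    }
    rec["minority_recall"] = (
        float(report.recall[minor].mean()) if minor else np.nan
    )
    rec["minority_f1"] = float(report.f1[minor].mean()) if minor else np.nan
    return rec


def compare_losses(
    scenarios: list[Scenario],
    seeds: list[int],
    cfg: ExperimentConfig = ExperimentConfig(),
    focal: LossConfig = LossConfig(),
    ce: LossConfig = LossConfig.cross_entropy(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Focal-loss vs cross-entropy under identical conditions.

    For every (scenario, seed) the two losses train on the same data,
    split and initial weights. Returns per-run records and a summary
    table (rows = scenarios, columns = loss x metric, seed means).
    """
    if not scenarios or not seeds:
        raise ValueError("need at least one scenario and one seed")
    records = []
    for scen in scenarios:
        for seed in seeds:
            prepared = prepare_split(scen, seed, cfg)
            for label, loss in (("FL", focal), ("CE", ce)):
                report, _ = run_single(scen, seed, loss, cfg, prepared=prepared)
                records.append(_record(scen, seed, label, report))
                logger.info(
                    "%s seed=%d %s: f1=%.4f minority_recall=%.4f",
                    scen.name, seed, label, records[-1]["f1"],
                    records[-1]["minority_recall"],
                )
    runs = pd.DataFrame(records)
    summary = (
        runs.pivot_table(
            index="scenario", columns="loss",
            values=["precision", "recall", "f1"], aggfunc="mean",
        )
        .swaplevel(axis=1)
        .sort_index(axis=1)
    )
    return runs, summary


def gamma_sweep(
    scen: Scenario,
    gammas: list[float],
    seeds: list[int],
    cfg: ExperimentConfig = ExperimentConfig(),
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Macro metrics per focusing parameter, alpha fixed at 0.25.

    Trains one model per (gamma, seed); returns per-gamma mean and std of
    macro precision/recall/F1 over seeds.
    """
    if any(g < 0 for g in gammas):
        raise ValueError("gamma values must be >= 0")
    records = []
    for seed in seeds:
        prepared = prepare_split(scen, seed, cfg)
        for g in gammas:
            loss = LossConfig(kind="focal", alpha=alpha, gamma=float(g))
            report, _ = run_single(scen, seed, loss, cfg, prepared=prepared)
            rec = _record(scen, seed, f"gamma={g}", report)
            rec["gamma"] = float(g)
            records.append(rec)
    runs = pd.DataFrame(records)
    out = runs.groupby("gamma")[["precision", "recall", "f1"]].agg(
        ["mean", "std"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out.reset_index()
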