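"""Training loop, stratified hold-out split, and per-class evaluation.

Training minimizes the configured loss with Adam (learning rate 2e-4,
batch size 128 by default), records per-epoch train/validation loss and
accuracy, and stops early when the validation loss has not improved for
``patience`` epochs — the operational reading of "train until the loss
converges". The weights of the best validation epoch are restored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import WindowedDataset
from .losses import LossConfig, loss_and_grad_logits, loss_value, one_hot
from .nn import Adam, HierarchicalNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization and split settings."""

    learning_rate: float = 2e-4
    batch_size: int = 128
    max_epochs: int = 200
    patience: int = 10
    split_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split fraction must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


def split_holdout(
    ds: WindowedDataset, cfg: TrainConfig
) -> tuple[WindowedDataset, WindowedDataset]:
    """Stratified hold-out split, deterministic given the seed.

    Each class contributes ``floor(split_fraction * n_c)`` windows to the
    training side and the rest to validation; every class needs at least
    two windows so both sides are non-empty.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = ds.class_counts()
    present = np.flatnonzero(counts)
    low = present[counts[present] < 2]
    if low.size:
        raise ValueError(
            f"classes {[ds.class_names[i] for i in low]} have fewer than 2 windows"
        )
    train_idx, val_idx = [], []
    for c in present:
        idx = np.flatnonzero(ds.y == c)
        idx = idx[rng.permutation(len(idx))]
        n_train = int(np.floor(cfg.split_fraction * len(idx)))
        train_idx.append(idx[:n_train])
        val_idx.append(idx[n_train:])
    train_idx = np.sort(np.concatenate(train_idx))
    val_idx = np.sort(np.concatenate(val_idx))
    return ds.subset(train_idx), ds.subset(val_idx)


def _snapshot(model: HierarchicalNetwork) -> list[np.ndarray]:
    arrays = []
    for _, layer in model.named_layers():
        for store in (layer.params, layer.buffers):
            arrays.extend(v.copy() for v in store.values())
    return arrays


def _restore(model: HierarchicalNetwork, arrays: list[np.ndarray]) -> None:
    it = iter(arrays)
    for _, layer in model.named_layers():
        for store in (layer.params, layer.buffers):
            for k in store:
                store[k][...] = next(it)


def predict_proba(
    model: HierarchicalNetwork, X: np.ndarray, batch_size: int = 512
) -> np.ndarray:
    """Class probabilities in inference mode (dropout off, running BN stats)."""
    out = [
        model.forward(X[i : i + batch_size], training=False)
        for i in range(0, len(X), batch_size)
    ]
    return np.concatenate(out) if out else np.empty((0, model.spec.n_classes))


def train(
    model: HierarchicalNetwork,
    train_ds: WindowedDataset,
    val_ds: WindowedDataset,
    loss: LossConfig = LossConfig(),
    cfg: TrainConfig = TrainConfig(),
) -> pd.DataFrame:
    """Fit the model; returns the per-epoch history.

    History columns: epoch, train_loss, train_accuracy, val_loss,
    val_accuracy. Train-side numbers are running averages over the
    epoch's minibatches (batch-stat mode); validation numbers use
    inference mode.
    """
    M = model.spec.n_classes
    Xtr, ytr = train_ds.X, train_ds.y
    Ytr = one_hot(ytr, M)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(lr=cfg.learning_rate)
    n = len(ytr)
    best_val = np.inf
    best_state = None
    bad_epochs = 0
    hist: dict[str, list] = {
        "epoch": [], "train_loss": [], "train_accuracy": [],
        "val_loss": [], "val_accuracy": [],
    }
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(n)
        tot_loss = 0.0
        tot_correct = 0
        for lo in range(0, n, cfg.batch_size):
            sel = perm[lo : lo + cfg.batch_size]
            Xb, Yb = Xtr[sel], Ytr[sel]
            model.zero_grad()
            logits = model.forward_logits(Xb, training=True)
            batch_loss, dlogits = loss_and_grad_logits(logits, Yb, loss)
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite loss ({batch_loss}) at epoch {epoch}, "
                    f"batch starting at {lo}; try a lower learning rate"
                )
            model.backward(dlogits.astype(model.dtype))
            opt.step(model.parameters())
            tot_loss += batch_loss * len(sel)
            tot_correct += int((logits.argmax(axis=1) == Yb.argmax(axis=1)).sum())
        val_p = predict_proba(model, val_ds.X)
        val_loss = loss_value(val_p, one_hot(val_ds.y, M), loss)
        val_acc = float((val_p.argmax(axis=1) == val_ds.y).mean())
        hist["epoch"].append(epoch)
        hist["train_loss"].append(tot_loss / n)
        hist["train_accuracy"].append(tot_correct / n)
        hist["val_loss"].append(val_loss)
        hist["val_accuracy"].append(val_acc)
        logger.info(
            "epoch %3d  loss %.4f acc %.4f | val_loss %.4f val_acc %.4f",
            epoch, tot_loss / n, tot_correct / n, val_loss, val_acc,
        )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = _snapshot(model)
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    if best_state is not None:
        _restore(model, best_state)
    return pd.DataFrame(hist)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Per-class and macro-averaged classification metrics.

    Confusion-matrix rows index the true class, columns the predicted
    class; row sums equal per-class support. Averages are unweighted
    (macro) means over classes. Classes absent from the evaluation set get
    recall 0 and a warning flag.
    """

    class_names: list[str]
    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    scenario: str = ""
    loss_kind: str = ""
    warnings: list[str] = field(default_factory=list)

    def per_class_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.class_names,
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "support": self.support,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.per_class_frame()
        macro = pd.DataFrame(
            {
                "class": ["macro_average"],
                "precision": [self.macro_precision],
                "recall": [self.macro_recall],
                "f1": [self.macro_f1],
                "support": [int(self.support.sum())],
            }
        )
        pd.concat([df, macro], ignore_index=True).to_csv(path, index=False)

    def __str__(self) -> str:
        lines = [
            f"scenario={self.scenario or '-'} loss={self.loss_kind or '-'} "
            f"accuracy={self.accuracy:.4f}",
            self.per_class_frame().to_string(index=False,
                                             float_format=lambda v: f"{v:.4f}"),
            f"macro: precision={self.macro_precision:.4f} "
            f"recall={self.macro_recall:.4f} f1={self.macro_f1:.4f}",
        ]
        if self.warnings:
            lines.append("warnings: " + "; ".join(self.warnings))
        return "\n".join(lines)


def metrics_from_confusion(confusion: np.ndarray):
    """precision, recall, F1 per class from a confusion matrix (rows = true).

    Degenerate cases (no predictions, or no support) yield 0 for the
    affected metric.
    """
    confusion = np.asarray(confusion, dtype=float)
    tp = np.diag(confusion)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return precision, recall, f1


def report_from_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    class_names: list[str],
    scenario: str = "",
    loss_kind: str = "",
) -> EvaluationReport:
    M = len(class_names)
    confusion = np.zeros((M, M), dtype=int)
    np.add.at(confusion, (np.asarray(y_true), np.asarray(y_pred)), 1)
    precision, recall, f1 = metrics_from_confusion(confusion)
    support = confusion.sum(axis=1)
    warnings = [
        f"class {class_names[c]!r} absent from the evaluation set; recall set to 0"
        for c in np.flatnonzero(support == 0)
    ]
    total = confusion.sum()
    return EvaluationReport(
        class_names=list(class_names),
        confusion=confusion,
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        accuracy=float(np.trace(confusion) / total) if total else 0.0,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        scenario=scenario,
        loss_kind=loss_kind,
        warnings=warnings,
    )


def evaluate(
    model: HierarchicalNetwork,
    ds: WindowedDataset,
    scenario: str = "",
    loss_kind: str = "",
) -> EvaluationReport:
    """Run the model on a dataset and tabulate per-class metrics."""
    if len(ds) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    y_pred = predict_proba(model, ds.X).argmax(axis=1)
    return report_from_predictions(
        ds.y, y_pred, ds.class_names, scenario=scenario, loss_kind=loss_kind
    )
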