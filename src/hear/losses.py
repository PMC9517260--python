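"""Cross-entropy and focal loss over softmax class probabilities.

For a sample with true-class probability ``p_t``, cross-entropy is
``-log p_t`` and focal loss is ``-alpha_t (1 - p_t)^gamma_t log p_t``.
The factor ``(1 - p_t)^gamma`` shrinks the contribution of well-classified
(easy) samples, so training gradient concentrates on hard and
minority-class samples; ``alpha`` is a class-balance weight. With
``gamma = 0`` and ``alpha = 1`` focal loss reduces exactly to
cross-entropy. ``alpha`` and ``gamma`` may be scalars (applied to the true
class uniformly) or per-class vectors.

Probabilities are clipped to ``[1e-7, 1]`` before the logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    """Choice of loss with its focal hyper-parameters.

    ``kind`` is ``"cross_entropy"`` or ``"focal"``; ``alpha`` > 0 is the
    balance factor (default 0.25) and ``gamma`` >= 0 the focusing
    parameter (default 2), each a scalar or a length-M vector.
    """

    kind: str = "focal"
    alpha: float | tuple[float, ...] = 0.25
    gamma: float | tuple[float, ...] = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("cross_entropy", "focal"):
            raise ValueError("kind must be 'cross_entropy' or 'focal'")
        if np.any(np.asarray(self.alpha) <= 0):
            raise ValueError("alpha must be positive")
        if np.any(np.asarray(self.gamma) < 0):
            raise ValueError("gamma must be non-negative")

    @classmethod
    def cross_entropy(cls) -> "LossConfig":
        return cls(kind="cross_entropy", alpha=1.0, gamma=0.0)


def _validate(p: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.atleast_2d(np.asarray(p, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    if not np.allclose(y.sum(axis=1), 1.0) or not np.all((y == 0) | (y == 1)):
        raise ValueError("y must be one-hot")
    return p, y


def _per_class(value, M: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(M, float(arr))
    if arr.shape != (M,):
        raise ValueError(f"per-class parameter must have length {M}")
    return arr


def cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    """Mean ``-log p_true`` over the batch (a single pair is a batch of 1)."""
    p, y = _validate(p, y)
    p_true = np.clip((p * y).sum(axis=1), EPS, 1.0)
    return float(np.mean(-np.log(p_true)))


def focal_loss(p: np.ndarray, y: np.ndarray,
               cfg: LossConfig = LossConfig()) -> float:
    """Mean ``-alpha_t (1 - p_t)^gamma_t log p_t`` over the batch."""
    p, y = _validate(p, y)
    M = p.shape[1]
    alpha = _per_class(cfg.alpha, M)
    gamma = _per_class(cfg.gamma, M)
    idx = y.argmax(axis=1)
    p_true = np.clip((p * y).sum(axis=1), EPS, 1.0)
    w = alpha[idx] * (1.0 - p_true) ** gamma[idx]
    return float(np.mean(-w * np.log(p_true)))


def loss_value(p: np.ndarray, y: np.ndarray, cfg: LossConfig) -> float:
    if cfg.kind == "cross_entropy":
        return cross_entropy(p, y)
    return focal_loss(p, y, cfg)


def loss_and_grad_logits(
    logits: np.ndarray, y: np.ndarray, cfg: LossConfig
) -> tuple[float, np.ndarray]:
    """Batch-mean loss and its gradient with respect to the logits.

    The softmax is folded in analytically. For cross-entropy the gradient
    is the familiar ``(p - y) / B``; for focal loss the chain rule through
    ``w(p_t) log p_t`` gives

    ``dL/dz_j = (dL/dp_t) * p_t * (delta_tj - p_j)``

    with ``dL/dp_t = alpha [ gamma (1-p_t)^(gamma-1) log p_t
    - (1-p_t)^gamma / p_t ]``.
    """
    logits = np.atleast_2d(np.asarray(logits, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if logits.shape != y.shape:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs y {y.shape}")
    B, M = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    idx = y.argmax(axis=1)
    p_true = np.clip(p[np.arange(B), idx], EPS, 1.0)
    if cfg.kind == "cross_entropy":
        loss = float(np.mean(-np.log(p_true)))
        grad = (p - y) / B
        return loss, grad
    alpha = _per_class(cfg.alpha, M)[idx]
    gamma = _per_class(cfg.gamma, M)[idx]
    one_m = 1.0 - p_true
    w = one_m ** gamma
    loss = float(np.mean(-alpha * w * np.log(p_true)))
    # d(loss_i)/d(p_t); the (1-p_t)^(gamma-1) factor is 0^negative-safe
    # because gamma = 0 gives dw = 0 exactly.
    with np.errstate(divide="ignore", invalid="ignore"):
        dw = np.where(gamma > 0, gamma * one_m ** np.where(gamma > 0, gamma - 1, 0), 0.0)
    dldp = alpha * (dw * np.log(p_true) - w / p_true)
    # dL/dz_j = dldp * p_t * (delta - p_j), averaged over the batch
    grad = -dldp[:, None] * p_true[:, None] * p
    grad[np.arange(B), idx] += dldp * p_true
    return loss, grad / B


def one_hot(y: np.ndarray, M: int) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    out = np.zeros((len(y), M))
    out[np.arange(len(y)), y] = 1.0
    return out
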