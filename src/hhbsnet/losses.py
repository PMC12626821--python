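"""Segmentation objectives: cross-entropy, focal loss, and their hybrid.

The hybrid objective is

    L = lambda * L_CE + (1 - lambda) * L_FL,
    L_CE = -log p_true,    L_FL = -alpha * (1 - p_true)^gamma * log p_true,

averaged over pixels, where ``p_true`` is the predicted probability of
the reference class.  With gamma = 0 and alpha = 1 the focal term
reduces exactly to cross-entropy; gamma > 0 down-weights well-classified
pixels so training concentrates on hard ones (small, low-contrast
lesions), and alpha re-balances the lesion/background pixel budget.

Two equivalent surfaces are provided: numpy functions over probability
maps (evaluation), and differentiable versions over logits (training).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor, as_tensor, log_softmax

__all__ = [
    "LossConfig",
    "cross_entropy_loss",
    "focal_loss",
    "hybrid_loss",
    "hybrid_loss_from_logits",
]

_EPS = 1e-7  # probability floor before logs


@dataclasses.dataclass
class LossConfig:
    """Mixing weight and focal parameters.

    Defaults are the conventional focal-loss settings (alpha 0.25,
    gamma 2) with an even cross-entropy/focal split.
    """

    lam: float = 0.5
    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be nonnegative, got {self.gamma}")


def _true_class_probs(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.shape[1:] != labels.shape:
        raise ValueError(
            f"probability map {probs.shape} does not align with labels {labels.shape}")
    k = probs.shape[0]
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(
            f"labels must lie in 0..{k - 1}, found range "
            f"[{labels.min()}, {labels.max()}]")
    flat = probs.reshape(k, -1)
    p_true = flat[labels.reshape(-1), np.arange(labels.size)]
    return np.clip(p_true, _EPS, 1.0)


def cross_entropy_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean over pixels of -log p(true class)."""
    return float(-np.log(_true_class_probs(probs, labels)).mean())


def focal_loss(probs: np.ndarray, labels: np.ndarray,
               config: LossConfig | None = None) -> float:
    """Mean over pixels of alpha * (1 - p_true)^gamma * (-log p_true)."""
    cfg = config or LossConfig()
    p = _true_class_probs(probs, labels)
    return float((cfg.alpha * (1.0 - p) ** cfg.gamma * (-np.log(p))).mean())


def hybrid_loss(probs: np.ndarray, labels: np.ndarray,
                config: LossConfig | None = None) -> float:
    """Convex combination lambda*CE + (1-lambda)*focal."""
    cfg = config or LossConfig()
    return (cfg.lam * cross_entropy_loss(probs, labels)
            + (1.0 - cfg.lam) * focal_loss(probs, labels, cfg))


def hybrid_loss_from_logits(logits: Tensor, labels: np.ndarray,
                            config: LossConfig | None = None) -> Tensor:
    """Differentiable hybrid loss on [N, K, H, W] (or [K, H, W]) logits."""
    cfg = config or LossConfig()
    t = as_tensor(logits)
    labels = np.asarray(labels)
    if t.ndim == 3:
        t = t.reshape(1, *t.shape)
        labels = labels[None]
    n, k, h, w = t.shape
    if labels.shape != (n, h, w):
        raise ValueError(f"labels {labels.shape} do not align with logits {t.shape}")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in 0..{k - 1}")
    logp = log_softmax(t, axis=1)
    onehot = np.zeros((n, k, h, w))
    np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
    logp_true = (logp * Tensor(onehot)).sum(axis=1)     # [N, H, W]
    p_true = logp_true.exp()
    ce = -logp_true
    fl = cfg.alpha * (1.0 - p_true) ** cfg.gamma * ce
    return (cfg.lam * ce + (1.0 - cfg.lam) * fl).mean()
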