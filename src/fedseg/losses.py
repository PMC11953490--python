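"""Training losses: Dice, binary cross-entropy, and the weighted
model-contrastive regularizer.

The public functions operate on plain numpy arrays in float64 and define the
reference semantics. Training uses the ``*_graph`` variants, which build the
same quantities on autodiff tensors; the BCE graph works in logit space for
numerical stability and agrees with the probability-space definition to well
under 1e-5 on clamped inputs.

The contrastive loss is a two-way temperature-scaled softmax over cosine
similarities: with s_g = sim(xi, xi_g) and s_b = sim(xi, xi_b),

    L_con = -beta * log( e^{s_g/tau} / (e^{s_g/tau} + e^{s_b/tau}) )
          =  beta * softplus((s_b - s_g) / tau)

where beta = exp(-n_k / N) strengthens the pull toward the global model for
data-poor clients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "LossConfig",
    "dice_loss",
    "bce_loss",
    "supervised_loss",
    "cosine_similarity",
    "beta_weight",
    "weighted_contrastive_loss",
    "total_loss",
    "supervised_loss_graph",
    "contrastive_loss_graph",
]


@dataclass(frozen=True)
class LossConfig:
    """Loss weights: mu scales BCE inside the supervised loss, alpha scales the
    contrastive term, tau is the softmax temperature."""

    mu: float = 1.0
    alpha: float = 1.0
    tau: float = 0.5
    epsilon: float = 1e-6

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.mu < 0 or self.alpha < 0:
            raise ValueError("mu and alpha must be nonnegative")


def _check_pair(pred: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    if pred.min() < 0 or pred.max() > 1:
        raise ValueError("predictions must lie in [0, 1]")
    return pred, target


def dice_loss(pred_prob: np.ndarray, target: np.ndarray,
              epsilon: float = 1e-6) -> float:
    """Soft Dice loss, averaged over samples (axis 0).

    Per sample: 1 - 2*|y * y_hat| / (|y| + |y_hat| + epsilon), with |.| the sum
    over pixels. The epsilon sits in the denominator only, so an empty mask
    against an empty prediction evaluates to 1.
    """
    pred, target = _check_pair(pred_prob, target)
    axes = tuple(range(1, pred.ndim))
    inter = (pred * target).sum(axis=axes)
    denom = pred.sum(axis=axes) + target.sum(axis=axes) + epsilon
    return float(np.mean(1.0 - 2.0 * inter / denom))


def bce_loss(pred_prob: np.ndarray, target: np.ndarray,
             epsilon: float = 1e-6) -> float:
    """Pixel-mean binary cross-entropy, averaged over samples.

    Probabilities are clamped to [epsilon, 1 - epsilon] before the logs.
    """
    pred, target = _check_pair(pred_prob, target)
    p = np.clip(pred, epsilon, 1.0 - epsilon)
    per_pixel = -(target * np.log(p) + (1.0 - target) * np.log1p(-p))
    axes = tuple(range(1, pred.ndim))
    return float(np.mean(per_pixel.mean(axis=axes)))


def supervised_loss(pred_prob: np.ndarray, target: np.ndarray,
                    cfg: LossConfig = LossConfig()) -> float:
    """Dice + mu * BCE."""
    return dice_loss(pred_prob, target, cfg.epsilon) + cfg.mu * bce_loss(
        pred_prob, target, cfg.epsilon
    )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> np.ndarray | float:
    """sim(a, b) = a.b / (|a||b|); accepts vectors or (n, d) batches.

    Zero-norm inputs raise: a silently-zero similarity would mask dead
    features upstream.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero-norm vector in cosine similarity")
    sim = (a * b).sum(axis=-1) / (na * nb)
    return float(sim) if sim.ndim == 0 else sim


def beta_weight(n_k: int, N: int) -> float:
    """Adaptive contrastive weight exp(-n_k / N); larger for data-poor clients."""
    if N <= 0:
        raise ValueError("N must be positive")
    if not 0 <= n_k <= N:
        raise ValueError("require 0 <= n_k <= N")
    return float(np.exp(-n_k / N))


def weighted_contrastive_loss(xi: np.ndarray, xi_g: np.ndarray, xi_b: np.ndarray,
                              tau: float = 0.5, beta: float = 1.0) -> float:
    """Weighted two-way contrastive loss; batched inputs are averaged.

    Computed as beta * softplus((sim(xi, xi_b) - sim(xi, xi_g)) / tau), the
    log-sum-exp-stable form of -beta * log softmax.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if beta <= 0:
        raise ValueError("beta must be positive")
    s_g = cosine_similarity(xi, xi_g)
    s_b = cosine_similarity(xi, xi_b)
    z = (np.asarray(s_b) - np.asarray(s_g)) / tau
    softplus = np.maximum(z, 0) + np.log1p(np.exp(-np.abs(z)))
    return float(beta * np.mean(softplus))


def total_loss(sup: float, con: float, alpha: float = 1.0) -> float:
    """Overall per-client objective: supervised + alpha * contrastive."""
    return float(sup + alpha * con)


# -- autodiff-graph variants used by the training loop ---------------------------


def supervised_loss_graph(logits: Tensor, target: np.ndarray,
                          cfg: LossConfig) -> tuple[Tensor, Tensor, Tensor]:
    """Supervised loss on logits; returns (sup, dice, bce) tensors.

    BCE is evaluated in logit space as mean(softplus(z) - z*y), which equals
    the clamped probability-space definition up to the clamp.
    """
    y = np.asarray(target, dtype=np.float32)
    if y.shape != logits.shape:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs target {y.shape}")
    axes = tuple(range(1, logits.ndim))
    probs = logits.sigmoid()
    inter = (probs * y).sum(axis=axes)
    denom = probs.sum(axis=axes) + Tensor(y.sum(axis=axes)) + cfg.epsilon
    dice = (1.0 - (2.0 * inter) / denom).mean()
    bce = (logits.softplus() - logits * y).mean()
    sup = dice + cfg.mu * bce
    return sup, dice, bce


def _cosine_rows_graph(xi: Tensor, ref: np.ndarray) -> Tensor:
    """Per-row cosine similarity between tensor rows and a constant matrix."""
    ref = np.asarray(ref, dtype=np.float32)
    ref_norm = np.linalg.norm(ref, axis=1)
    if np.any(ref_norm == 0):
        raise ValueError("zero-norm snapshot embedding")
    dot = (xi * Tensor(ref)).sum(axis=1)
    nx = ((xi * xi).sum(axis=1) + 1e-12).sqrt()
    return dot / (nx * Tensor(ref_norm))


def contrastive_loss_graph(xi: Tensor, xi_g: np.ndarray, xi_b: np.ndarray,
                           tau: float, beta: float) -> Tensor:
    """Differentiable weighted contrastive loss against frozen snapshots."""
    s_g = _cosine_rows_graph(xi, xi_g)
    s_b = _cosine_rows_graph(xi, xi_b)
    return ((s_b - s_g) * (1.0 / tau)).softplus().mean() * beta
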