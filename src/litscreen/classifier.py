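"""Feature fusion, the softmax head, and the focal loss.

The combined article representation X_i concatenates the inter-sample
title feature R_i, inter-sample abstract feature N_i, and the ReLU
feed-forward journal feature J_i.  A dense layer maps X_i to two logits
and a softmax yields the positive-class probability p_i.

Class imbalance is handled with the focal loss

    FL(i) = -alpha_t * (1 - p_t)^gamma * log(p_t)

where p_t is the predicted probability of the *true* class and alpha_t is
``alpha`` for positives and ``1 - alpha`` for negatives.  gamma down-weights
easy samples; defaults gamma=2, alpha=0.8.  With gamma=0, alpha=0.5 the
loss is exactly half the binary cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FocalLossParams",
    "PROB_EPS",
    "encode_journal",
    "combine",
    "predict",
    "focal_loss",
    "focal_loss_from_logits",
]

#: Probability clamp keeping log(p) finite.
PROB_EPS = 1e-7


@dataclass(frozen=True)
class FocalLossParams:
    """Focal-loss hyperparameters: modulating exponent gamma >= 0 and
    positive-class weight alpha in [0, 1]."""

    gamma: float = 2.0
    alpha: float = 0.8

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


def encode_journal(j: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Feed-forward + ReLU journal encoding: relu(j @ W + b).

    ``j`` may be a single vector or an (s, k) batch.
    """
    if j.shape[-1] != weight.shape[0]:
        raise ValueError(
            f"journal feature width {j.shape[-1]} does not match encoder input {weight.shape[0]}"
        )
    return np.maximum(j @ weight + bias, 0.0)


def combine(r: np.ndarray, n: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Concatenate title, abstract and journal features (in that order)."""
    return np.concatenate([r, n, j], axis=-1)


def predict(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Two-class softmax probabilities for a batch of combined features.

    Returns an (s, 2) array; column 1 is the positive-class probability.
    """
    logits = np.atleast_2d(x) @ weight + bias
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite logits in the classification head")
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    return y.astype(int)


def focal_loss(p: np.ndarray, y: np.ndarray, params: FocalLossParams = FocalLossParams()) -> float:
    """Mean focal loss of positive-class probabilities ``p`` against labels.

    Probabilities are clamped to [PROB_EPS, 1 - PROB_EPS] before the log.
    """
    y = _check_labels(y)
    p = np.clip(np.asarray(p, dtype=float), PROB_EPS, 1.0 - PROB_EPS)
    p_t = np.where(y == 1, p, 1.0 - p)
    alpha_t = np.where(y == 1, params.alpha, 1.0 - params.alpha)
    per_sample = -alpha_t * (1.0 - p_t) ** params.gamma * np.log(p_t)
    return float(per_sample.mean())


def focal_loss_from_logits(
    logits: np.ndarray, y: np.ndarray, params: FocalLossParams = FocalLossParams()
) -> tuple[float, np.ndarray]:
    """Mean focal loss of two-class logits, with its gradient.

    Returns ``(loss, d_logits)`` where ``d_logits`` has the same (s, 2)
    shape as ``logits``; used by the training loop.
    """
    y = _check_labels(y)
    s = logits.shape[0]
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    probs = e / e.sum(axis=1, keepdims=True)
    p_t = np.clip(probs[np.arange(s), y], PROB_EPS, 1.0 - PROB_EPS)
    alpha_t = np.where(y == 1, params.alpha, 1.0 - params.alpha)
    one_minus = 1.0 - p_t
    loss = float((-alpha_t * one_minus**params.gamma * np.log(p_t)).mean())

    # dL/dp_t; the gamma term vanishes identically when gamma == 0
    d_pt = -alpha_t * one_minus**params.gamma / p_t
    if params.gamma > 0:
        d_pt = d_pt + alpha_t * params.gamma * one_minus ** (params.gamma - 1.0) * np.log(p_t)
    # dp_t/dlogits through the softmax: p_t * (onehot(y) - probs)
    onehot = np.zeros_like(probs)
    onehot[np.arange(s), y] = 1.0
    d_logits = (d_pt * p_t)[:, None] * (onehot - probs) / s
    return loss, d_logits
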