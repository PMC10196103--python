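"""Losses: softmax cross-entropy and multi-class soft Dice.

Both return ``(loss, grad_wrt_logits)`` so networks backpropagate from the
logits directly.  The segmentation objective combines the two with equal
weight: cross-entropy drives per-pixel accuracy while the soft-Dice term
counteracts the extreme class imbalance between large (brain) and small
(pituitary, cistern) structures.
"""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "softmax_cross_entropy", "soft_dice_loss"]


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    # labels (N,H,W) or (N,) -> one-hot with class axis 1
    eye = np.eye(n_classes)
    oh = eye[labels]                       # (..., C)
    return np.moveaxis(oh, -1, 1)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over all items/pixels; labels are integer classes."""
    n_classes = logits.shape[1]
    p = softmax(logits)
    y = _one_hot(labels, n_classes)
    n_items = labels.size
    eps = 1e-12
    loss = -np.sum(y * np.log(p + eps)) / n_items
    grad = (p - y) / n_items
    return loss, grad


def soft_dice_loss(logits: np.ndarray, labels: np.ndarray, eps: float = 1e-6):
    """1 - mean soft Dice over classes, on softmax probabilities.

    Per class c: dice_c = (2 Σ p_c y_c + eps) / (Σ p_c + Σ y_c + eps),
    summed over the whole batch.
    """
    n_classes = logits.shape[1]
    p = softmax(logits)
    y = _one_hot(labels, n_classes)
    axes = (0,) + tuple(range(2, logits.ndim))
    inter = (p * y).sum(axis=axes)
    union = p.sum(axis=axes) + y.sum(axis=axes)
    dice = (2.0 * inter + eps) / (union + eps)
    loss = 1.0 - dice.mean()

    # d loss / d p_c at each location, then through the softmax Jacobian
    shape = [1, n_classes] + [1] * (logits.ndim - 2)
    dice_r = dice.reshape(shape)
    union_r = union.reshape(shape)
    dldp = -(2.0 * y - dice_r) / (union_r + eps) / n_classes
    inner = (dldp * p).sum(axis=1, keepdims=True)
    grad = p * (dldp - inner)
    return loss, grad
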