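"""Training losses: focal (classification), smooth-L1 (box), dice (mask).

The total is the weighted sum  L = l_cls * L_focal + l_box * L_sl1 +
l_mask * L_dice.  Focal loss is normalized by the positive-cell count,
the standard convention under extreme foreground/background imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, where_const


@dataclass
class LossReport:
    cls_loss: float
    box_loss: float
    mask_loss: float
    total: float


def focal_loss(logits: Tensor, targets: np.ndarray, *, alpha: float = 0.25,
               gamma: float = 2.0, normalizer: float | None = None) -> Tensor:
    """Sigmoid focal loss, summed and divided by ``normalizer``.

    ``targets`` is a {0,1} array of the same shape as ``logits``.  The
    balance weight is alpha on positives and 1-alpha on negatives; alpha=1
    disables the weighting, so gamma = 0, alpha = 1 reduces to plain binary
    cross-entropy (mean when ``normalizer`` equals the element count).
    """
    t = np.asarray(targets, dtype=logits.data.dtype)
    if t.shape != logits.shape:
        raise ValueError("logit/target shape mismatch")
    p = logits.sigmoid()
    # p_t = p on positives, 1-p on negatives
    p_t = p * t + (1.0 - p) * (1.0 - t)
    alpha_t = alpha * t + (1.0 - alpha) * (1.0 - t) if 0 <= alpha < 1 else 1.0
    loss = -(alpha_t * (1.0 - p_t) ** gamma) * p_t.clip_min(1e-9).log()
    total = loss.sum()
    if normalizer is None:
        normalizer = float(t.size)
    return total * (1.0 / max(normalizer, 1.0))


def smooth_l1(pred: Tensor, target: np.ndarray, *, beta: float = 1.0) -> Tensor:
    """Huber-style box loss, mean over all offset components.

    Quadratic (0.5 d^2 / beta) inside |d| < beta, linear (|d| - beta/2)
    outside; the two branches meet at |d| = beta with value beta/2.
    """
    t = np.asarray(target, dtype=np.float32)
    d = pred - t
    absd = d * np.sign(d.data)
    quad = (d * d) * (0.5 / beta)
    lin = absd - 0.5 * beta
    inside = np.abs(d.data) < beta
    loss = where_const(inside, quad, 0.0) + where_const(~inside, lin, 0.0)
    return loss.mean()


def dice_loss(pred: Tensor, target: np.ndarray, *, eps: float = 1e-6) -> Tensor:
    """Dice loss 1 - 2<p,t> / (|p|^2 + |t|^2 + eps), mean over instances.

    ``pred`` holds soft masks in [0, 1] of shape (n, H, W); ``target`` is
    binary of the same shape.  Perfect binary overlap gives ~0; disjoint
    supports give ~1.
    """
    t = np.asarray(target, dtype=np.float32)
    if t.shape != pred.shape:
        raise ValueError("mask shape mismatch")
    axes = tuple(range(1, pred.ndim))
    inter = (pred * t).sum(axis=axes)
    denom = (pred * pred).sum(axis=axes) + (t * t).sum(axis=axes)
    dice = (2.0 * inter) / (denom + eps)
    return (1.0 - dice).mean()
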