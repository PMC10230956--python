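"""Instance-mask generation: dynamic convolution, Matrix NMS, postprocess.

Dynamic convolution realises Z = F * K: each grid cell's predicted
D-vector (D = gamma^2 * C_mask) is reshaped into a (C_mask, gamma, gamma)
kernel and convolved (same padding) with the unified mask feature F,
producing one mask-score channel per cell.  With gamma = 1 this reduces to
a per-pixel dot product between F and the cell's kernel.

Matrix NMS resolves duplicate masks without sequential suppression: every
mask's score is decayed by the most suppressive higher-scored same-category
mask,

    score_j <- score_j * min_i  decay(iou_ij) / decay(iou_max,i),

with gaussian decay exp(-iou^2 / sigma) or linear decay (1 - iou), where
iou_max,i is mask i's largest IoU with any higher-scored mask of the same
category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn.functional import conv2d, bilinear_resize_array


@dataclass
class Detection:
    """One predicted instance at image resolution."""

    mask: np.ndarray
    score: float
    category: int
    box: tuple[float, float, float, float]

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")
        if not self.mask.any():
            raise ValueError("detection mask must be nonempty")


@dataclass
class PostprocessConfig:
    score_thr: float = 0.1       # pre-NMS class-score gate
    mask_thr: float = 0.5        # sigmoid binarisation threshold
    keep_thr: float = 0.5        # post-NMS keep threshold on decayed scores
    nms_sigma: float = 2.0
    nms_mode: str = "gaussian"   # or "linear"
    pre_nms: int = 500
    max_detections: int = 100


def dynamic_conv(feature: Tensor, kernels: Tensor, gamma: int = 1) -> Tensor:
    """Convolve the unified mask feature with per-cell predicted kernels.

    ``feature``: (B, C_mask, H', W'); ``kernels``: (B, Q, D) with
    D = gamma^2 * C_mask.  Returns mask logits (B, Q, H', W').
    """
    B, C, H, W = feature.shape
    Bk, Q, D = kernels.shape
    if Bk != B:
        raise ValueError("batch mismatch between feature and kernels")
    if D != gamma * gamma * C:
        raise ValueError(f"kernel dim {D} != gamma^2*C = {gamma * gamma * C}")
    if gamma == 1:
        flat = feature.reshape(B, C, H * W)
        return (kernels @ flat).reshape(B, Q, H, W)
    outs = []
    for b in range(B):
        w = kernels[b].reshape(Q, C, gamma, gamma)
        outs.append(conv2d(feature[b:b + 1], w, padding=gamma // 2))
    return nn.concat(outs, axis=0)


def mask_iou_matrix(masks: np.ndarray) -> np.ndarray:
    """Pairwise IoU of a stack of binary masks, shape (n, n)."""
    flat = masks.reshape(len(masks), -1).astype(np.float64)
    inter = flat @ flat.T
    areas = flat.sum(axis=1)
    union = areas[:, None] + areas[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def matrix_nms(masks: np.ndarray, scores: np.ndarray, categories: np.ndarray,
               *, mode: str = "gaussian", sigma: float = 2.0) -> np.ndarray:
    """Decay scores of overlapping same-category masks in matrix form.

    ``masks`` is an (n, H, W) boolean stack; returns the decayed scores in
    the input order (no sorting or suppression is applied here).
    """
    n = len(masks)
    if not (len(scores) == len(categories) == n):
        raise ValueError("masks, scores and categories must have equal length")
    if n == 0:
        return np.zeros(0, dtype=np.float32)
    order = np.argsort(-scores, kind="stable")
    m = np.asarray(masks, dtype=bool)[order]
    s = np.asarray(scores, dtype=np.float64)[order]
    c = np.asarray(categories)[order]

    iou = mask_iou_matrix(m)
    same = c[:, None] == c[None, :]
    # suppressor[i, j]: i is higher-scored, same category as j
    suppressor = np.triu(same, k=1)
    # compensation per suppressor i: its own max IoU with ITS suppressors
    comp = np.where(suppressor, iou, 0.0).max(axis=0)

    if mode == "gaussian":
        ratio = np.exp(-(iou ** 2) / sigma) / np.exp(-(comp[:, None] ** 2) / sigma)
    elif mode == "linear":
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (1.0 - iou) / (1.0 - comp[:, None])
        ratio = np.nan_to_num(ratio, nan=1.0, posinf=np.inf)
    else:
        raise ValueError(f"unknown NMS mode {mode!r}")

    ratio = np.where(suppressor, ratio, np.inf)
    factors = np.minimum(ratio.min(axis=0, initial=np.inf), 1.0)
    decayed = np.empty(n, dtype=np.float64)
    decayed[order] = s * factors
    return decayed


def postprocess(mask_logits: dict[str, np.ndarray],
                class_logits: dict[str, np.ndarray],
                image_size: tuple[int, int],
                config: PostprocessConfig) -> list[Detection]:
    """Decode one image's per-level grids into final detections.

    Cells whose class probability clears ``score_thr`` contribute a
    candidate; soft masks are binarised at ``mask_thr`` and empty ones
    dropped; scores are rescaled by the mean in-mask confidence; Matrix NMS
    decays duplicates; survivors above ``keep_thr`` are sorted and
    truncated to ``max_detections``; masks are bilinearly upsampled to
    image size before the final binarisation.
    """
    cand_soft, cand_scores, cand_cats = [], [], []
    for lvl, logits in mask_logits.items():
        cls = class_logits[lvl]                      # (Q, M)
        prob = 1.0 / (1.0 + np.exp(-cls))
        q_idx, m_idx = np.nonzero(prob > config.score_thr)
        for q, m in zip(q_idx, m_idx):
            soft = 1.0 / (1.0 + np.exp(-logits[q]))  # (H', W')
            hard = soft > config.mask_thr
            if not hard.any():
                continue
            maskness = float(soft[hard].mean())
            cand_soft.append(soft)
            cand_scores.append(float(prob[q, m]) * maskness)
            cand_cats.append(int(m) + 1)
    if not cand_soft:
        return []

    scores = np.asarray(cand_scores)
    order = np.argsort(-scores, kind="stable")[:config.pre_nms]
    soft = np.stack([cand_soft[i] for i in order])
    scores = scores[order]
    cats = np.asarray(cand_cats)[order]
    hard = soft > config.mask_thr

    decayed = matrix_nms(hard, scores, cats, mode=config.nms_mode,
                         sigma=config.nms_sigma)
    keep = decayed >= config.keep_thr
    if not keep.any():
        return []
    soft, cats, decayed = soft[keep], cats[keep], decayed[keep]
    final_order = np.argsort(-decayed, kind="stable")[:config.max_detections]

    detections = []
    for i in final_order:
        up = bilinear_resize_array(soft[i], image_size)
        mask = up > config.mask_thr
        if not mask.any():
            continue
        ys, xs = np.nonzero(mask)
        box = (float(xs.min()), float(ys.min()),
               float(xs.max()) + 1.0, float(ys.max()) + 1.0)
        detections.append(Detection(mask=mask, score=float(min(decayed[i], 1.0)),
                                    category=int(cats[i]), box=box))
    return detections
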