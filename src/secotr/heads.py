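"""Function heads (kernel / class / box) and ground-truth grid assignment.

Each pyramid level used for prediction is pooled to its own N x N patch
grid; a single linear layer per head is applied with shared weights at
every level, emitting per-cell dynamic-convolution kernels (N x N x D with
D = gamma^2 * C_mask), class logits (N x N x M) and box-edge offsets
(N x N x 4).

Assignment follows the YOLO/SOLO center rule: an instance is routed to the
level(s) whose scale range contains sqrt(area); within a level, the cells
overlapping the instance's shrunken center region (box center +- eps * box
half-extent) whose own centers lie inside the ground-truth box are
positive.  If that set is empty (sub-cell instances) the single cell
containing the box center is used.  When two instances claim a cell, the
smaller instance wins (instances are processed in decreasing area order
and later assignments overwrite).  Box targets are the normalized offsets
from the cell's projected image coordinate to the four edges of the
ground-truth box G.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .coco_io import InstanceAnnotation
from .cotr import patchify
from .backbone import LEVEL_STRIDES


@dataclass
class HeadsConfig:
    levels: tuple[str, ...] = ("P2", "P3", "P4", "P5")
    grid_sizes: tuple[int, ...] = (36, 24, 16, 12)
    # sqrt-area routing ranges (pixels at image scale), one per level
    scale_ranges: tuple[tuple[float, float], ...] = (
        (0.0, 64.0), (32.0, 128.0), (64.0, 256.0), (128.0, 2048.0))
    gamma: int = 1
    eps_center: float = 0.2
    box_norm_base: float = 8.0
    num_classes: int = 1
    class_prior: float = 0.01  # focal-loss bias initialisation

    def __post_init__(self):
        if not (len(self.levels) == len(self.grid_sizes) == len(self.scale_ranges)):
            raise ValueError("levels, grid_sizes and scale_ranges must align")
        if self.gamma < 1 or self.gamma % 2 == 0 and self.gamma != 1:
            raise ValueError("gamma must be 1 or an odd kernel size")


def kernel_dim(gamma: int, c_mask: int) -> int:
    """D = gamma^2 * C_mask."""
    return gamma * gamma * c_mask


class FunctionHeads(nn.Module):
    """Shared linear heads over per-level patch grids."""

    def __init__(self, channels: int, c_mask: int, config: HeadsConfig):
        self.config = config
        self.c_mask = c_mask
        d = kernel_dim(config.gamma, c_mask)
        self.pos = [Tensor(np.zeros((1, channels, n, n), dtype=np.float32),
                           requires_grad=True) for n in config.grid_sizes]
        self.kernel_head = nn.Linear(channels, d, init="head")
        self.class_head = nn.Linear(channels, config.num_classes, init="head")
        pi = config.class_prior
        self.class_head.bias.data[...] = -np.log((1 - pi) / pi)
        self.box_head = nn.Linear(channels, 4, init="head")

    def run_heads(self, pyramid: dict[str, Tensor]
                  ) -> dict[str, tuple[Tensor, Tensor, Tensor]]:
        """Per-level (KernelSet, ClassGrid, BoxGrid), each (B, N*N, ...)."""
        out = {}
        for lvl, n, pos in zip(self.config.levels, self.config.grid_sizes, self.pos):
            grid = patchify(pyramid[lvl], n, pos)  # (B, C, N, N)
            B, C = grid.shape[:2]
            tokens = grid.transpose(0, 2, 3, 1).reshape(B * n * n, C)
            kernels = self.kernel_head(tokens).reshape(B, n * n, -1)
            scores = self.class_head(tokens).reshape(B, n * n, -1)
            boxes = self.box_head(tokens).reshape(B, n * n, 4)
            out[lvl] = (kernels, scores, boxes)
        return out

    forward = run_heads


# ---------------------------------------------------------------------------
# ground-truth assignment
# ---------------------------------------------------------------------------

@dataclass
class AssignmentResult:
    """Supervision targets for one image.

    ``positive_cells``: (level name, i, j, instance index) tuples;
    ``class_targets``: per level, an (N, N) integer grid (0 = background);
    ``mask_targets``: per positive cell, a boolean mask at unified-feature
    resolution; ``box_targets``: per positive cell, the (l, t, r, b)
    normalized edge offsets.
    """

    positive_cells: list[tuple[str, int, int, int]]
    class_targets: dict[str, np.ndarray]
    mask_targets: list[np.ndarray]
    box_targets: list[np.ndarray]


def _center_cells(box: tuple[float, float, float, float], n: int,
                  image_size: tuple[int, int], eps: float
                  ) -> list[tuple[int, int]]:
    """Cells positive for a box under the shrunken-center-region rule."""
    h, w = image_size
    x0, y0, x1, y1 = box
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    hw, hh = (x1 - x0) / 2.0, (y1 - y0) / 2.0
    rx0, rx1 = cx - eps * hw, cx + eps * hw
    ry0, ry1 = cy - eps * hh, cy + eps * hh
    # index range of cells overlapping the (closed) center region
    i0 = int(np.clip(np.floor(ry0 * n / h), 0, n - 1))
    i1 = int(np.clip(np.floor(min(ry1, h - 1e-6) * n / h), 0, n - 1))
    j0 = int(np.clip(np.floor(rx0 * n / w), 0, n - 1))
    j1 = int(np.clip(np.floor(min(rx1, w - 1e-6) * n / w), 0, n - 1))
    cells = []
    for i in range(i0, i1 + 1):
        for j in range(j0, j1 + 1):
            yc = (i + 0.5) * h / n
            xc = (j + 0.5) * w / n
            if x0 <= xc <= x1 and y0 <= yc <= y1:
                cells.append((i, j))
    if not cells:
        i = int(np.clip(np.floor(cy * n / h), 0, n - 1))
        j = int(np.clip(np.floor(cx * n / w), 0, n - 1))
        cells = [(i, j)]
    return cells


def _resample_mask(mask: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    soft = nn.bilinear_resize_array(mask.astype(np.float32), size)
    hard = soft >= 0.5
    if not hard.any():  # sub-pixel instance: keep its strongest pixel
        hard = np.zeros_like(hard)
        hard[np.unravel_index(np.argmax(soft), soft.shape)] = True
    return hard


def assign_targets(annotations: list[InstanceAnnotation],
                   image_size: tuple[int, int],
                   config: HeadsConfig,
                   feature_size: tuple[int, int]) -> AssignmentResult:
    """Route instances to grid cells and build supervision targets."""
    h, w = image_size
    class_targets = {lvl: np.zeros((n, n), dtype=np.int64)
                     for lvl, n in zip(config.levels, config.grid_sizes)}
    owner: dict[tuple[str, int, int], int] = {}

    order = sorted(range(len(annotations)), key=lambda k: -annotations[k].area)
    for idx in order:
        ann = annotations[idx]
        sq = float(np.sqrt(ann.area))
        for lvl, n, (lo, hi) in zip(config.levels, config.grid_sizes,
                                    config.scale_ranges):
            if not (lo <= sq <= hi):
                continue
            for i, j in _center_cells(ann.box, n, image_size, config.eps_center):
                owner[(lvl, i, j)] = idx
                class_targets[lvl][i, j] = ann.category_id

    positive_cells = []
    mask_targets = []
    box_targets = []
    stride = {lvl: LEVEL_STRIDES[lvl] for lvl in config.levels}
    for (lvl, i, j), idx in sorted(owner.items()):
        ann = annotations[idx]
        n = config.grid_sizes[config.levels.index(lvl)]
        yc = (i + 0.5) * h / n
        xc = (j + 0.5) * w / n
        x0, y0, x1, y1 = ann.box
        norm = stride[lvl] * config.box_norm_base
        tgt = np.array([(xc - x0), (yc - y0), (x1 - xc), (y1 - yc)],
                       dtype=np.float32) / norm
        box_targets.append(np.maximum(tgt, 0.0))
        mask_targets.append(_resample_mask(ann.mask, feature_size))
        positive_cells.append((lvl, i, j, idx))
    return AssignmentResult(positive_cells, class_targets, mask_targets, box_targets)


def decode_box(cell: tuple[str, int, int], target: np.ndarray,
               image_size: tuple[int, int], config: HeadsConfig
               ) -> tuple[float, float, float, float]:
    """Invert a box target at its cell's projected coordinate."""
    lvl, i, j = cell
    n = config.grid_sizes[config.levels.index(lvl)]
    h, w = image_size
    yc = (i + 0.5) * h / n
    xc = (j + 0.5) * w / n
    norm = LEVEL_STRIDES[lvl] * config.box_norm_base
    l, t, r, b = (float(v) * norm for v in target)
    return (xc - l, yc - t, xc + r, yc + b)
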