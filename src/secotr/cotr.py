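"""Coordinate-transformer (COTR) stack.

The stride-32 pyramid level is partitioned into an N x N grid of patch
embeddings (adaptive average pooling preserves channels), a learned
positional embedding is added once, and k transformer-style layers are
applied.  Each layer is the standard pre-norm block with the token
self-attention replaced by coordinate attention acting on the grid as a
(C, N, N) spatial map:

    u   = x + CoordAttention(LN(x))
    out = u + MLP(LN(u))

The final grid is emitted twice: flattened to (N*N, C) sequence features
for the function heads, and resized bilinearly back to the input's spatial
size as the refined P5 map consumed by joint pyramid upsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .coord_attention import CoordAttention


@dataclass
class CotrConfig:
    k: int = 3                       # number of stacked layers
    n_patch: int = 12                # COTR grid size N on P5
    mlp_ratio: float = 2.0
    reduction: int = 32              # coordinate-attention reduction ratio
    grid_sizes: tuple[int, ...] = (36, 24, 16, 12)  # head grids per level

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if any(n < 1 for n in self.grid_sizes):
            raise ValueError("grid sizes must be positive")
        if any(a < b for a, b in zip(self.grid_sizes, self.grid_sizes[1:])):
            raise ValueError("grid sizes must be non-increasing with level depth")


class PositionalPatchify(nn.Module):
    """Adaptive-pool a feature map to an N x N grid and add a learned
    positional embedding (one vector per grid cell, added exactly once)."""

    def __init__(self, channels: int, n: int, *, learned_pos: bool = True):
        self.n = n
        if learned_pos:
            self.pos = Tensor(np.zeros((1, channels, n, n), dtype=np.float32),
                              requires_grad=True)
        else:
            self.pos = None

    def forward(self, x: Tensor) -> Tensor:
        if min(x.shape[-2:]) < self.n:
            raise ValueError(f"feature {x.shape[-2:]} smaller than grid {self.n}")
        grid = nn.adaptive_avg_pool(x, (self.n, self.n))
        if self.pos is not None:
            grid = grid + self.pos
        return grid


def patchify(x: Tensor, n: int, pos: Tensor | None = None) -> Tensor:
    """Functional patchify: (B, C, H, W) -> (B, C, N, N) grid (+ pos)."""
    if min(x.shape[-2:]) < n:
        raise ValueError(f"feature {x.shape[-2:]} smaller than grid {n}")
    grid = nn.adaptive_avg_pool(x, (n, n))
    if pos is not None:
        grid = grid + pos
    return grid


class CotrLayer(nn.Module):
    """Pre-norm transformer block with coordinate attention as the mixer.

    Both residual branches carry a learned per-channel scale (init 1).
    Zeroing the scales — or all branch transforms plus the attention-path
    scale — turns the layer into an exact identity map, which is also the
    lever the composition tests use.
    """

    def __init__(self, channels: int, *, mlp_ratio: float = 2.0,
                 reduction: int = 32, norm_kind: str = "group"):
        hidden = max(int(channels * mlp_ratio), 1)
        self.ln1 = nn.LayerNorm(channels)
        self.attn = CoordAttention(channels, reduction, norm_kind=norm_kind)
        self.ln2 = nn.LayerNorm(channels)
        self.fc1 = nn.Linear(channels, hidden)
        self.fc2 = nn.Linear(hidden, channels)
        self.attn_scale = Tensor(np.ones((1, channels, 1, 1), dtype=np.float32),
                                 requires_grad=True)
        self.mlp_scale = Tensor(np.ones((1, channels, 1, 1), dtype=np.float32),
                                requires_grad=True)

    def _ln_spatial(self, x: Tensor, ln: nn.LayerNorm) -> Tensor:
        flat = x.transpose(0, 2, 3, 1)
        return ln(flat).transpose(0, 3, 1, 2)

    def forward(self, grid: Tensor) -> Tensor:
        u = grid + self.attn_scale * self.attn(self._ln_spatial(grid, self.ln1))
        B, C, N1, N2 = u.shape
        tokens = self._ln_spatial(u, self.ln2).transpose(0, 2, 3, 1).reshape(B * N1 * N2, C)
        h = self.fc2(self.fc1(tokens).hardswish())
        mlp_out = h.reshape(B, N1, N2, C).transpose(0, 3, 1, 2)
        return u + self.mlp_scale * mlp_out


class Cotr(nn.Module):
    """Patchify P5, run k COTR layers, emit sequence features + refined P5."""

    def __init__(self, channels: int, config: CotrConfig, *,
                 norm_kind: str = "group"):
        self.config = config
        self.patchify = PositionalPatchify(channels, config.n_patch)
        self.layers = [CotrLayer(channels, mlp_ratio=config.mlp_ratio,
                                 reduction=config.reduction, norm_kind=norm_kind)
                       for _ in range(config.k)]

    def forward(self, p5: Tensor) -> tuple[Tensor, Tensor]:
        grid = self.patchify(p5)
        for layer in self.layers:
            grid = layer(grid)
        B, C, N, _ = grid.shape
        seq = grid.transpose(0, 2, 3, 1).reshape(B, N * N, C)
        refined = nn.interpolate_bilinear(grid, p5.shape[-2:])
        return seq, refined
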