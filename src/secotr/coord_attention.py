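"""Coordinate attention: directional pooling, joint encoding, gating.

For input X of shape (C, H, W), each channel is pooled along rows and
columns separately,

    z_c(h) = (1/W) sum_i x_c(h, i),      z_c(w) = (1/H) sum_j x_c(j, w),

the two summaries are concatenated along the spatial axis and passed
through a shared 1x1 transform F1 with nonlinearity delta and reduction
ratio r, split back into per-direction halves, mapped by per-direction 1x1
transforms and squashed by a sigmoid to give gates g^h (C, H) and
g^w (C, W).  The output re-weights the input multiplicatively:

    y_c(i, j) = x_c(i, j) * g^h_c(i) * g^w_c(j).

(The width gate is indexed by the width coordinate j; both gates lie in
(0, 1), so |y| <= |x| elementwise.)  All operations run batched on
(B, C, H, W) tensors and are differentiable.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor


def pool_directional(x: Tensor) -> tuple[Tensor, Tensor]:
    """Row and column mean pooling of a (B, C, H, W) tensor.

    Returns ``z_h`` of shape (B, C, H) and ``z_w`` of shape (B, C, W).
    """
    z_h = x.mean(axis=3)
    z_w = x.mean(axis=2)
    return z_h, z_w


class CoordAttention(nn.Module):
    """The full gating block; also exposes the intermediate operations.

    Parameters
    ----------
    channels : feature channels C.
    reduction : reduction ratio r of the shared transform (C -> max(C//r, 1)).
    activation : ``"hswish"`` (default) or ``"relu"`` — the design only
        requires that delta is a nonlinearity.
    use_norm : include a normalisation step between F1 and delta.
    """

    def __init__(self, channels: int, reduction: int = 32, *,
                 activation: str = "hswish", use_norm: bool = True,
                 norm_kind: str = "group"):
        mid = max(channels // reduction, 1)
        self.channels = channels
        self.mid = mid
        self.f1 = nn.Conv2d(channels, mid, 1)
        self.norm = nn.make_norm(norm_kind if use_norm else "none", mid)
        self.act = nn.HardSwish() if activation == "hswish" else nn.ReLU()
        self.f_h = nn.Conv2d(mid, channels, 1)
        self.f_w = nn.Conv2d(mid, channels, 1)

    def attention_gates(self, z_h: Tensor, z_w: Tensor) -> tuple[Tensor, Tensor]:
        """Directional summaries -> sigmoid gates (g_h: (B,C,H), g_w: (B,C,W))."""
        B, C, H = z_h.shape
        W = z_w.shape[2]
        if C != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {C}")
        # concatenate along the spatial axis and run the shared 1x1 transform
        zcat = nn.concat([z_h, z_w], axis=2).reshape(B, C, H + W, 1)
        f = self.act(self.norm(self.f1(zcat)))
        f_h = f[:, :, :H, :]
        f_w = f[:, :, H:, :]
        g_h = self.f_h(f_h).sigmoid().reshape(B, C, H)
        g_w = self.f_w(f_w).sigmoid().reshape(B, C, W)
        return g_h, g_w

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        z_h, z_w = pool_directional(x)
        g_h, g_w = self.attention_gates(z_h, z_w)
        return x * g_h.reshape(B, C, H, 1) * g_w.reshape(B, C, 1, W)


def apply_attention(x: Tensor, g_h: Tensor, g_w: Tensor) -> Tensor:
    """Multiplicative re-weighting y[c,i,j] = x[c,i,j] * g_h[c,i] * g_w[c,j]."""
    B, C, H, W = x.shape
    return x * g_h.reshape(B, C, H, 1) * g_w.reshape(B, C, 1, W)
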