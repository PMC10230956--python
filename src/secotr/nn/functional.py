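"""Differentiable NN primitives: convolution and spatial resampling.

Convolution is implemented by the classic kernel-offset decomposition: for
each of the kh*kw kernel taps the padded input is sliced with the right
stride/dilation offset and contracted against that tap's weights.  The
backward pass mirrors the loop with strided scatter-adds.  Grouped
convolution supports ``groups == 1`` (dense) and ``groups == C_in``
(depthwise) — the only two cases a MobileNet-style network needs.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, pad2d, spatial_matmul


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, dilation: int = 1,
           groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) on a (B, C, H, W) tensor.

    ``weight`` has shape (C_out, C_in // groups, kh, kw).
    """
    B, C, H, W = x.shape
    Cout, Cin_g, kh, kw = weight.shape
    if groups not in (1, C):
        raise ValueError(f"groups must be 1 or C_in={C}, got {groups}")
    if groups == 1 and Cin_g != C:
        raise ValueError(f"weight expects {Cin_g} input channels, got {C}")
    if groups == C and (Cin_g != 1 or Cout % C != 0):
        raise ValueError("depthwise conv needs weight shape (C*m, 1, kh, kw)")

    xp = pad2d(x, padding)
    Hp, Wp = xp.shape[-2:]
    Ho = (Hp - dilation * (kh - 1) - 1) // stride + 1
    Wo = (Wp - dilation * (kw - 1) - 1) // stride + 1
    if Ho < 1 or Wo < 1:
        raise ValueError("convolution output would be empty")

    xd, wd = xp.data, weight.data
    out = np.zeros((B, Cout, Ho, Wo), dtype=np.float32)
    # slices per kernel tap, reused by the backward pass
    taps = []
    for u in range(kh):
        for v in range(kw):
            hs = slice(u * dilation, u * dilation + stride * (Ho - 1) + 1, stride)
            ws = slice(v * dilation, v * dilation + stride * (Wo - 1) + 1, stride)
            taps.append((u, v, hs, ws))
            patch = xd[:, :, hs, ws]
            if groups == 1:
                out += np.einsum("bchw,oc->bohw", patch, wd[:, :, u, v], optimize=True)
            else:  # depthwise: C_out == C (multiplier folded into caller)
                out += patch * wd[:, 0, u, v][None, :, None, None]

    parents = [xp, weight]

    def bw(g):
        if weight.requires_grad:
            gw = np.zeros_like(wd)
        if xp.requires_grad:
            gx = np.zeros_like(xd)
        for u, v, hs, ws in taps:
            patch = xd[:, :, hs, ws]
            if groups == 1:
                if weight.requires_grad:
                    gw[:, :, u, v] += np.einsum("bohw,bchw->oc", g, patch, optimize=True)
                if xp.requires_grad:
                    gx[:, :, hs, ws] += np.einsum("bohw,oc->bchw", g, wd[:, :, u, v],
                                                  optimize=True)
            else:
                if weight.requires_grad:
                    gw[:, 0, u, v] += (g * patch).sum(axis=(0, 2, 3))
                if xp.requires_grad:
                    gx[:, :, hs, ws] += g * wd[:, 0, u, v][None, :, None, None]
        if weight.requires_grad:
            weight._accumulate(gw)
        if xp.requires_grad:
            xp._accumulate(gx)

    out_t = Tensor._make(out, parents, bw)
    if bias is not None:
        out_t = out_t + bias.reshape(1, Cout, 1, 1)
    return out_t


# ---------------------------------------------------------------------------
# spatial resampling as fixed linear maps
# ---------------------------------------------------------------------------

def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-interpolation matrix for bilinear resize (align_corners=False)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        m[o, lo] += 1.0 - frac
        m[o, hi] += frac
    return m


def _avgpool_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Adaptive average-pool partition matrix (floor/ceil bin edges)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    for o in range(n_out):
        a = (o * n_in) // n_out
        b = -((-(o + 1) * n_in) // n_out)  # ceil
        m[o, a:b] = 1.0 / (b - a)
    return m


_MAT_CACHE: dict[tuple, np.ndarray] = {}


def _cached(kind: str, n_out: int, n_in: int) -> np.ndarray:
    key = (kind, n_out, n_in)
    if key not in _MAT_CACHE:
        fn = _bilinear_matrix if kind == "bilinear" else _avgpool_matrix
        _MAT_CACHE[key] = fn(n_out, n_in)
    return _MAT_CACHE[key]


def interpolate_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinearly resize a (B, C, H, W) tensor to ``size`` = (H', W')."""
    Ho, Wo = size
    H, W = x.shape[-2:]
    if (H, W) == (Ho, Wo):
        return x
    return spatial_matmul(x, _cached("bilinear", Ho, H), _cached("bilinear", Wo, W))


def adaptive_avg_pool(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Adaptive average pooling of a (B, C, H, W) tensor to ``size``."""
    Ho, Wo = size
    H, W = x.shape[-2:]
    if Ho > H or Wo > W:
        raise ValueError(f"pool output {size} exceeds input {(H, W)}")
    if (H, W) == (Ho, Wo):
        return x
    return spatial_matmul(x, _cached("avg", Ho, H), _cached("avg", Wo, W))


def bilinear_resize_array(a: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a plain (H, W) or (C, H, W) array (no autograd)."""
    squeeze = a.ndim == 2
    if squeeze:
        a = a[None]
    Ho, Wo = size
    H, W = a.shape[-2:]
    out = np.einsum("oh,chw,pw->cop", _cached("bilinear", Ho, H),
                    a.astype(np.float32), _cached("bilinear", Wo, W), optimize=True)
    return out[0] if squeeze else out
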