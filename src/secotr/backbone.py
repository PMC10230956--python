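"""Inverted-residual (MobileNetV2-style) backbone with a top-down FPN.

The backbone expands features to a wider space with a 1x1 convolution,
filters with a depthwise 3x3, and projects back down — the
"dimension enhancement then dimension reduction" pattern that keeps mobile
networks cheap.  The four stages with output strides 4/8/16/32 feed C2-C5;
the FPN projects each laterally to a uniform channel width, sums in
upsampled coarser levels top-down, and smooths each sum with a 3x3
convolution, yielding the pyramid P2-P5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

LEVEL_STRIDES = {"P2": 4, "P3": 8, "P4": 16, "P5": 32}


@dataclass
class BackboneConfig:
    width_multiplier: float = 1.0
    fpn_channels: int = 256
    tiny_mode: bool = False
    norm_kind: str = "group"

    def __post_init__(self):
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        if self.fpn_channels < 8:
            raise ValueError("fpn_channels must be >= 8")


def _round_ch(c: float) -> int:
    return max(8, int(c + 4) // 8 * 8)


class InvertedResidual(nn.Module):
    def __init__(self, c_in: int, c_out: int, *, stride: int, expand: int,
                 norm: str):
        mid = c_in * expand
        self.use_res = stride == 1 and c_in == c_out
        mods = []
        if expand != 1:
            mods.append(nn.ConvNormAct(c_in, mid, 1, norm=norm))
        mods.append(nn.ConvNormAct(mid, mid, 3, stride=stride, groups=mid, norm=norm))
        mods.append(nn.Sequential(nn.Conv2d(mid, c_out, 1, bias=False),
                                  nn.make_norm(norm, c_out)))
        self.block = nn.Sequential(*mods)

    def forward(self, x: Tensor) -> Tensor:
        out = self.block(x)
        return out + x if self.use_res else out


# (expand, channels, repeats, stride) per stage; stage boundaries at the
# stride-2 blocks put C2/C3/C4/C5 at strides 4/8/16/32
_FULL_STAGES = [
    (1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
    (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1),
]
_TINY_STAGES = [
    (1, 8, 1, 1), (2, 12, 1, 2), (2, 16, 1, 2), (2, 24, 2, 2), (2, 32, 1, 2),
]


class MobileNetV2Backbone(nn.Module):
    def __init__(self, config: BackboneConfig):
        wm = config.width_multiplier
        norm = config.norm_kind
        stages = _TINY_STAGES if config.tiny_mode else _FULL_STAGES
        stem_ch = _round_ch((8 if config.tiny_mode else 32) * wm)
        self.stem = nn.ConvNormAct(3, stem_ch, 3, stride=2, norm=norm)
        self.blocks: list[nn.Module] = []
        self._taps: list[int] = []  # indices of the last block at each stride
        c_prev = stem_ch
        stride_so_far = 2
        idx = -1
        tap_at_stride = {}
        for expand, ch, reps, stride in stages:
            ch = _round_ch(ch * wm)
            for r in range(reps):
                s = stride if r == 0 else 1
                self.blocks.append(InvertedResidual(c_prev, ch, stride=s,
                                                    expand=expand, norm=norm))
                idx += 1
                stride_so_far *= s
                c_prev = ch
                tap_at_stride[stride_so_far] = (idx, ch)
        self._taps = [tap_at_stride[s][0] for s in (4, 8, 16, 32)]
        self.stage_channels = [tap_at_stride[s][1] for s in (4, 8, 16, 32)]

    def forward(self, x: Tensor) -> list[Tensor]:
        """Return [C2, C3, C4, C5]."""
        x = self.stem(x)
        outs = []
        taps = set(self._taps)
        for i, block in enumerate(self.blocks):
            x = block(x)
            if i in taps:
                outs.append(x)
        return outs


class FPN(nn.Module):
    def __init__(self, in_channels: list[int], out_channels: int, norm: str):
        self.laterals = [nn.Conv2d(c, out_channels, 1) for c in in_channels]
        self.smooth = [nn.Conv2d(out_channels, out_channels, 3, padding=1)
                       for _ in in_channels]

    def forward(self, feats: list[Tensor]) -> list[Tensor]:
        lat = [l(f) for l, f in zip(self.laterals, feats)]
        merged = [lat[-1]]
        for f in reversed(lat[:-1]):
            up = nn.interpolate_bilinear(merged[0], f.shape[-2:])
            merged.insert(0, f + up)
        return [s(m) for s, m in zip(self.smooth, merged)]


class BackboneFPN(nn.Module):
    """image batch -> {P2..P5} feature pyramid with uniform channel width."""

    def __init__(self, config: BackboneConfig):
        self.config = config
        self.body = MobileNetV2Backbone(config)
        self.fpn = FPN(self.body.stage_channels, config.fpn_channels,
                       config.norm_kind)

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        return self.extract_features(x)

    def extract_features(self, x: Tensor) -> dict[str, Tensor]:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (B, 3, H, W) input, got {x.shape}")
        B, _, H, W = x.shape
        if H < 32 or W < 32:
            raise ValueError("input spatial dims must be >= 32")
        ph = (-H) % 32
        pw = (-W) % 32
        if ph or pw:
            widths = [(0, 0), (0, 0), (0, ph), (0, pw)]
            x = Tensor._make(np.pad(x.data, widths), (x,),
                             lambda g: x._accumulate(g[:, :, :H, :W]))
        feats = self.body(x)
        pyramid = self.fpn(feats)
        return dict(zip(("P2", "P3", "P4", "P5"), pyramid))
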