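"""Joint pyramid upsampling: fuse P2-P4 (FPN) and refined P5 (COTR) into a
single stride-4 unified mask feature.

Each level is first projected into a common channel space with a
conv+norm+activation block; P3/P4/P5 are bilinearly upsampled x2/x4/x8 to
stride 4 and concatenated with P2 into y; four parallel depthwise-separable
convolutions with dilation rates 1, 2, 4 and 8 read y at growing receptive
fields; their outputs are concatenated and reduced by a final convolution
block to the mask-feature width.  The result F has spatial size exactly
(H/4, W/4) for an input image (H, W); predicted masks are upsampled to
image resolution later, at decode time.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .nn import Tensor


@dataclass
class JpuConfig:
    c_mask: int = 256
    dilations: tuple[int, ...] = (1, 2, 4, 8)


class SeparableConv(nn.Sequential):
    """Depthwise 3x3 (dilated) + pointwise 1x1, each with norm+activation."""

    def __init__(self, c_in: int, c_out: int, dilation: int, norm: str):
        super().__init__(
            nn.ConvNormAct(c_in, c_in, 3, dilation=dilation, groups=c_in, norm=norm),
            nn.ConvNormAct(c_in, c_out, 1, norm=norm),
        )


class Jpu(nn.Module):
    def __init__(self, in_channels: int, config: JpuConfig, *,
                 norm_kind: str = "group"):
        cm = config.c_mask
        self.config = config
        self.project = [nn.ConvNormAct(in_channels, cm, 3, norm=norm_kind)
                        for _ in range(4)]
        y_ch = 4 * cm
        self.branches = [SeparableConv(y_ch, cm, d, norm_kind)
                         for d in config.dilations]
        self.reduce = nn.ConvNormAct(cm * len(config.dilations), cm, 1,
                                     norm=norm_kind)

    def project_levels(self, levels: list[Tensor]) -> list[Tensor]:
        """Map each pyramid level to c_mask channels, spatial sizes kept."""
        if len(levels) != 4:
            raise ValueError(f"expected 4 pyramid levels, got {len(levels)}")
        return [proj(lvl) for proj, lvl in zip(self.project, levels)]

    def fuse(self, projected: list[Tensor]) -> Tensor:
        """Upsample-concat the projected levels and apply the dilated bank."""
        target = projected[0].shape[-2:]
        ups = [projected[0]]
        for lvl in projected[1:]:
            up = nn.interpolate_bilinear(lvl, target)
            if up.shape[-2:] != target:
                raise ValueError("spatial mismatch after upsampling")
            ups.append(up)
        y = nn.concat(ups, axis=1)
        feats = [branch(y) for branch in self.branches]
        return self.reduce(nn.concat(feats, axis=1))

    def forward(self, levels: list[Tensor]) -> Tensor:
        return self.fuse(self.project_levels(levels))
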