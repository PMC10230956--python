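"""Layer/module system: parameter containers with torch-like ergonomics.

Initialisation draws from a package-level generator reset by
:func:`manual_seed`, so a fixed seed plus a fixed construction order gives a
bit-identical model.  Normalisation layers are batch-independent (group /
layer norm) — there is no train/eval statistics split, which keeps tiny-batch
CPU training deterministic.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor, concat
from .functional import conv2d

_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Reset the parameter-initialisation RNG."""
    global _RNG
    _RNG = np.random.default_rng(seed)


def _kaiming(shape: tuple[int, ...], fan_out: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_out)
    return _RNG.normal(0.0, std, size=shape).astype(np.float32)


class Module:
    """Base class; parameters and submodules are discovered via attributes."""

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = state[k].astype(np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel_size: int, *, stride: int = 1,
                 padding: int = 0, dilation: int = 1, groups: int = 1,
                 bias: bool = True, init: str = "kaiming"):
        k = kernel_size
        shape = (c_out, c_in // groups, k, k)
        fan_out = c_out * k * k // (groups if groups > 1 else 1)
        if init == "kaiming":
            w = _kaiming(shape, max(fan_out, 1))
        elif init == "zero":
            w = np.zeros(shape, dtype=np.float32)
        elif init == "identity":
            if c_in != c_out or k != 1 or groups != 1:
                raise ValueError("identity init requires 1x1 square dense conv")
            w = np.eye(c_out, dtype=np.float32).reshape(shape)
        else:
            raise ValueError(init)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True) if bias else None
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation, groups=self.groups)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, *, bias: bool = True, init: str = "kaiming"):
        if init == "kaiming":
            w = _kaiming((n_in, n_out), n_out)
        elif init == "zero":
            w = np.zeros((n_in, n_out), dtype=np.float32)
        elif init == "head":  # small-std init for prediction heads
            w = _RNG.normal(0.0, 0.01, size=(n_in, n_out)).astype(np.float32)
        else:
            raise ValueError(init)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class GroupNorm(Module):
    """Group normalisation over (B, C, H, W); batch-size independent."""

    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        if num_channels % num_groups != 0:
            raise ValueError("channels must divide into groups")
        self.num_groups = num_groups
        self.eps = eps
        self.gamma = Tensor(np.ones(num_channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        G = self.num_groups
        xg = x.reshape(B, G, C // G * H * W)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
        xn = (xg - mu) / ((var + self.eps) ** 0.5)
        xn = xn.reshape(B, C, H, W)
        return xn * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)


class LayerNorm(Module):
    """Normalisation over the trailing feature axis of (..., C)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class HardSwish(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.hardswish()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


def make_norm(kind: str, channels: int) -> Module:
    """Factory for the network's normalisation layers.

    ``group`` (default): GroupNorm with up-to-8 groups; ``none``: identity.
    """
    if kind == "group":
        g = 1
        for cand in (8, 4, 2, 1):
            if channels % cand == 0:
                g = cand
                break
        return GroupNorm(g, channels)
    if kind == "none":
        return Identity()
    raise ValueError(f"unknown norm kind {kind!r}")


class ConvNormAct(Sequential):
    """conv → norm → activation block used throughout the network."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, *, stride: int = 1,
                 dilation: int = 1, groups: int = 1, norm: str = "group",
                 act: str = "hswish"):
        pad = dilation * (k // 2)
        act_mod = {"hswish": HardSwish(), "relu": ReLU(), "none": Identity()}[act]
        super().__init__(
            Conv2d(c_in, c_out, k, stride=stride, padding=pad, dilation=dilation,
                   groups=groups, bias=False),
            make_norm(norm, c_out),
            act_mod,
        )
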