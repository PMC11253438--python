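"""Partial convolution (PConv) and its analytic FLOPs / memory-access model.

A partial convolution applies a k x k convolution to a contiguous slab of
``cp = r * c`` channels (the first or last ones, chosen for regular memory
access) and passes the remaining ``c - cp`` channels through unchanged.  With
the typical partial ratio r = 1/4 the convolution FLOPs drop to r^2 = 1/16 of
a dense convolution over all ``c`` channels, and the dominant memory traffic
to r = 1/4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, concat
from .nn.modules import Conv2d, Module


@dataclass(frozen=True)
class PConvSpec:
    """Static description of a partial convolution layer.

    c: in/out channel count; r: partial ratio in (0, 1]; k: odd kernel size;
    position: which contiguous slab is convolved ('first' or 'last').
    Stride 1, same-padding.
    """

    c: int
    r: float = 0.25
    k: int = 3
    position: str = "first"
    cp: int = field(init=False)

    def __post_init__(self):
        if self.c < 1:
            raise ValueError("c must be positive")
        if not 0 < self.r <= 1:
            raise ValueError("partial ratio r must lie in (0, 1]")
        if self.k % 2 == 0 or self.k < 1:
            raise ValueError("kernel size k must be odd and positive")
        if self.position not in ("first", "last"):
            raise ValueError("position must be 'first' or 'last'")
        cp = self.r * self.c
        if abs(cp - round(cp)) > 1e-9 or round(cp) < 1:
            raise ValueError(f"r*c must be a positive integer, got {cp}")
        object.__setattr__(self, "cp", int(round(cp)))


def _check_ratio(c: int, r: float) -> int:
    cp = r * c
    if abs(cp - round(cp)) > 1e-9 or round(cp) < 1:
        raise ValueError(f"r*c must be a positive integer, got r={r}, c={c}")
    return int(round(cp))


def pconv_flops(h: int, w: int, k: int, c: int, r: float) -> float:
    """FLOPs of a partial convolution: h * w * k^2 * cp^2.

    The ratio to a dense convolution (h * w * k^2 * c^2) is exactly r^2.
    """
    if min(h, w, k, c) < 1 or r <= 0:
        raise ValueError("all arguments must be positive")
    cp = _check_ratio(c, r)
    return float(h * w * k * k * cp * cp)


def pconv_memory_access(h: int, w: int, k: int, c: int, r: float) -> float:
    """Memory access of a partial convolution: h * w * 2*cp + k^2 * cp^2.

    For h*w >> k^2*cp the first term dominates, so the access volume is about
    r times a dense convolution's h * w * 2*c.
    """
    if min(h, w, k, c) < 1 or r <= 0:
        raise ValueError("all arguments must be positive")
    cp = _check_ratio(c, r)
    return float(h * w * 2 * cp + k * k * cp * cp)


class PConv2d(Module):
    """Partial convolution layer: dense k x k conv on a cp-channel slab,
    bit-exact identity on the remaining channels."""

    def __init__(self, spec: PConvSpec, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.spec = spec
        self.conv = Conv2d(
            spec.cp, spec.cp, spec.k, rng, stride=1, padding=spec.k // 2, bias=bias
        )
        self.last_input_hw: tuple | None = None

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if c != self.spec.c:
            raise ValueError(f"PConv2d expects {self.spec.c} channels, got {c}")
        self.last_input_hw = x.shape[2:]
        cp = self.spec.cp
        if cp == c:
            return self.conv(x)
        if self.spec.position == "first":
            active, rest = x[:, :cp], x[:, cp:]
            return concat([self.conv(active), rest], axis=1)
        rest, active = x[:, : c - cp], x[:, c - cp :]
        return concat([rest, self.conv(active)], axis=1)


def conv3x3(
    cin: int,
    cout: int,
    rng: np.random.Generator,
    use_pconv: bool = False,
    r: float = 0.25,
    stride: int = 1,
    bias: bool = True,
) -> Module:
    """3x3 convolution factory: swaps in a PConv2d wherever the flag allows it.

    Partial convolution keeps the channel count, so only stride-1 convolutions
    with cin == cout are replaceable; others stay dense.
    """
    if use_pconv and cin == cout and stride == 1:
        try:
            return PConv2d(PConvSpec(c=cin, r=r), rng, bias=bias)
        except ValueError:
            pass  # r*c not integral for this width: keep the dense conv
    return Conv2d(cin, cout, 3, rng, stride=stride, padding=1, bias=bias)
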