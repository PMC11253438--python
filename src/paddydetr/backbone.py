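"""Multi-scale CNN backbone.

A compact residual network of four stages (stem stride 4, then three stride-2
stages) whose taps produce the feature pyramid the encoder consumes:

    s3: stride 8,  128 channels      (80 x 80 for a 640 input)
    s4: stride 16, 256 channels      (40 x 40)
    s5: stride 32, 512 channels      (20 x 20)

Each stage's tap passes through a 1x1 projection to the fixed channel count.
Every stride-1 3x3 convolution is replaceable by a partial convolution via
the ``use_pconv`` flag; that swap never changes any output shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor
from .nn.modules import BatchNorm2d, Conv2d, Module, ReLU, Sequential
from .pconv import conv3x3


@dataclass
class MultiScaleFeatures:
    """Backbone pyramid: s3/s4/s5 at strides 8/16/32."""

    s3: Tensor
    s4: Tensor
    s5: Tensor


class ResidualBlock(Module):
    def __init__(self, channels: int, rng, use_pconv: bool = False, r: float = 0.25):
        super().__init__()
        self.conv1 = conv3x3(channels, channels, rng, use_pconv, r)
        self.bn1 = BatchNorm2d(channels)
        self.conv2 = conv3x3(channels, channels, rng, use_pconv, r)
        self.bn2 = BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        return (y + x).relu()


def _downsample(cin: int, cout: int, rng) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, 3, rng, stride=2, padding=1, bias=False),
        BatchNorm2d(cout),
        ReLU(),
    )


class Backbone(Module):
    """Four-stage residual CNN with pyramid taps.

    widths: channel counts of the s3/s4/s5 taps (default 128/256/512).
    depth: residual blocks per stage.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        widths: tuple[int, int, int] = (128, 256, 512),
        depth: int = 2,
        use_pconv: bool = False,
        r: float = 0.25,
    ):
        super().__init__()
        w3, w4, w5 = widths
        self.widths = (w3, w4, w5)
        c0, c1 = max(w3 // 4, 8), max(w3 // 2, 16)
        self.stem = Sequential(
            Conv2d(3, c0, 3, rng, stride=2, padding=1, bias=False),
            BatchNorm2d(c0),
            ReLU(),
            Conv2d(c0, c1, 3, rng, stride=2, padding=1, bias=False),
            BatchNorm2d(c1),
            ReLU(),
        )
        self.stage3 = Sequential(
            _downsample(c1, w3, rng),
            *[ResidualBlock(w3, rng, use_pconv, r) for _ in range(depth)],
        )
        self.stage4 = Sequential(
            _downsample(w3, w4, rng),
            *[ResidualBlock(w4, rng, use_pconv, r) for _ in range(depth)],
        )
        self.stage5 = Sequential(
            _downsample(w4, w5, rng),
            *[ResidualBlock(w5, rng, use_pconv, r) for _ in range(depth)],
        )
        self.proj3 = Conv2d(w3, w3, 1, rng)
        self.proj4 = Conv2d(w4, w4, 1, rng)
        self.proj5 = Conv2d(w5, w5, 1, rng)

    def forward(self, x: Tensor) -> MultiScaleFeatures:
        """x: N x 3 x H x W with H, W divisible by 32."""
        _, c, H, W = x.shape
        if c != 3:
            raise ValueError(f"expected 3 input channels, got {c}")
        if H % 32 != 0 or W % 32 != 0:
            raise ValueError(
                f"input spatial size {H}x{W} must be divisible by 32 "
                "(the backbone downsamples by strides 8/16/32)"
            )
        x = self.stem(x)
        t3 = self.stage3(x)
        t4 = self.stage4(t3)
        t5 = self.stage5(t4)
        return MultiScaleFeatures(s3=self.proj3(t3), s4=self.proj4(t4), s5=self.proj5(t5))
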