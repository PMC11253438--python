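"""Hybrid encoder.

Three cooperating parts process the backbone pyramid:

* a Transformer branch with cascaded group attention runs on the high-level
  map s5, where context between weeds and crop rows lives, producing y1;
* a multi-branch dilated-convolution CNN runs on the low-level map s3, where
  fine local detail of small plants lives, producing y2;
* a top-down cross-scale fusion combines y1, the middle map s4 and y2 into
  the single feature map y3 handed to the decoder.

For a 640 input with default widths: y1 = 20x20x512, y2 = 80x80x256 and
y3 = 80x80x512.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import MultiScaleFeatures
from .cga import CascadedGroupAttention
from .nn import DTYPE, Tensor, concat, upsample_nearest
from .nn.modules import BatchNorm2d, Conv2d, LayerNorm, Linear, Module, ReLU, Sequential
from .pconv import conv3x3


@dataclass
class EncodedFeatures:
    y1: Tensor  # transformer branch output, s5 grid
    y2: Tensor  # dilated-CNN branch output, s3 grid
    y3: Tensor  # fused map, s3 grid


def sinusoidal_position_encoding_2d(h: int, w: int, dim: int) -> np.ndarray:
    """Fixed 2D sine/cosine positional encoding, (h*w) x dim, row-major tokens.

    Half the channels encode the row coordinate, half the column coordinate.
    """
    if dim % 4 != 0:
        raise ValueError("positional encoding dim must be divisible by 4")
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(0, half, 2) / half)

    def encode(coords):
        ang = coords[:, None] * freqs[None, :]
        return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)

    rows = encode(np.arange(h, dtype=np.float64))  # h x half
    cols = encode(np.arange(w, dtype=np.float64))  # w x half
    pe = np.zeros((h, w, dim), dtype=DTYPE)
    pe[:, :, :half] = rows[:, None, :]
    pe[:, :, half:] = cols[None, :, :]
    return pe.reshape(h * w, dim)


def flatten_map(x: Tensor) -> Tensor:
    """NCHW feature map -> N x (H*W) x C token stack, row-major."""
    n, c, h, w = x.shape
    return x.reshape(n, c, h * w).transpose(0, 2, 1)


def unflatten_map(x: Tensor, h: int, w: int) -> Tensor:
    n, l, c = x.shape
    return x.transpose(0, 2, 1).reshape(n, c, h, w)


class EncoderBlock(Module):
    """Pre-norm residual block: x + CGA(norm(x)), then x + FFN(norm(x)).

    Pre-normalisation keeps the residual identity path unnormalised, which
    trains stably under plain SGD without warmup."""

    def __init__(self, dim: int, heads: int, rng, ffn_ratio: int = 4, key_dim: int | None = None):
        super().__init__()
        self.attn = CascadedGroupAttention(dim, heads, rng, key_dim=key_dim)
        self.norm1 = LayerNorm(dim)
        self.fc1 = Linear(dim, dim * ffn_ratio, rng)
        self.fc2 = Linear(dim * ffn_ratio, dim, rng)
        self.norm2 = LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        x = x + self.fc2(self.fc1(self.norm2(x)).relu())
        return x


class TransformerBranch(Module):
    """Encode s5 with `layers` CGA blocks; zero layers is the identity."""

    def __init__(self, dim: int, heads: int, rng, layers: int = 1, ffn_ratio: int = 4):
        super().__init__()
        self.dim = dim
        self.blocks = [EncoderBlock(dim, heads, rng, ffn_ratio) for _ in range(layers)]

    def forward(self, s5: Tensor) -> Tensor:
        if not self.blocks:
            return s5
        n, c, h, w = s5.shape
        tokens = flatten_map(s5)
        pe = sinusoidal_position_encoding_2d(h, w, c)
        tokens = tokens + Tensor(pe[None])
        for block in self.blocks:
            tokens = block(tokens)
        return unflatten_map(tokens, h, w)


@dataclass(frozen=True)
class DilatedBranchSpec:
    """Layout of the dilated-convolution branch run on s3.

    Three parallel 3x3 branches with dilations (6, 12, 18), each BN + ReLU
    with a 1x1 residual projection; branch outputs are concatenated
    (3 x branch_channels), fused by a 1x1 conv down to fused_channels, then
    expanded by a final 1x1 conv to out_channels = y2's width.
    """

    dilations: tuple[int, ...] = (6, 12, 18)
    branch_channels: int = 80
    fused_channels: int = 80
    out_channels: int = 256
    expand_output: bool = True  # disable to emit the fused width directly

    @property
    def concat_channels(self) -> int:
        return len(self.dilations) * self.branch_channels


class DilatedCNNBranch(Module):
    def __init__(self, in_channels: int, spec: DilatedBranchSpec, rng):
        super().__init__()
        self.spec = spec
        self.branch_convs = [
            Conv2d(in_channels, spec.branch_channels, 3, rng, padding=d, dilation=d, bias=False)
            for d in spec.dilations
        ]
        self.branch_bns = [BatchNorm2d(spec.branch_channels) for _ in spec.dilations]
        self.residuals = [
            Conv2d(in_channels, spec.branch_channels, 1, rng) for _ in spec.dilations
        ]
        self.fuse = Conv2d(spec.concat_channels, spec.fused_channels, 1, rng)
        self.expand = (
            Conv2d(spec.fused_channels, spec.out_channels, 1, rng) if spec.expand_output else None
        )

    def forward(self, s3: Tensor) -> Tensor:
        outs = []
        for conv, bn, res in zip(self.branch_convs, self.branch_bns, self.residuals):
            outs.append(bn(conv(s3)).relu() + res(s3))
        fused = self.fuse(concat(outs, axis=1))
        return self.expand(fused) if self.expand is not None else fused

    @property
    def out_channels(self) -> int:
        return self.spec.out_channels if self.spec.expand_output else self.spec.fused_channels


class CrossScaleFusion(Module):
    """Top-down FPN-style fusion of (y1, s4, y2) into y3 on the s3 grid.

    lateral 1x1 on y1 -> 2x upsample -> add 1x1(s4) -> 3x3 conv ->
    2x upsample -> concat with y2 -> 3x3 conv at the output width.
    """

    def __init__(
        self,
        c_y1: int,
        c_s4: int,
        c_y2: int,
        rng,
        out_channels: int | None = None,
        use_pconv: bool = False,
        r: float = 0.25,
    ):
        super().__init__()
        self.out_channels = out_channels if out_channels is not None else c_y1
        self.lateral_y1 = Conv2d(c_y1, c_s4, 1, rng)
        self.lateral_s4 = Conv2d(c_s4, c_s4, 1, rng)
        self.mid_conv = Sequential(
            conv3x3(c_s4, c_s4, rng, use_pconv, r), BatchNorm2d(c_s4), ReLU()
        )
        cat = c_s4 + c_y2
        self.out_conv = Sequential(
            Conv2d(cat, self.out_channels, 3, rng, padding=1, bias=False),
            BatchNorm2d(self.out_channels),
            ReLU(),
        )

    def forward(self, y1: Tensor, s4: Tensor, y2: Tensor) -> Tensor:
        h1, w1 = y1.shape[2:]
        h4, w4 = s4.shape[2:]
        h2, w2 = y2.shape[2:]
        if not (h4 == 2 * h1 and w4 == 2 * w1 and h2 == 2 * h4 and w2 == 2 * w4):
            raise ValueError(
                f"fusion expects spatial ratios 1:2:4, got y1 {h1}x{w1}, s4 {h4}x{w4}, y2 {h2}x{w2}"
            )
        top = upsample_nearest(self.lateral_y1(y1), 2) + self.lateral_s4(s4)
        mid = upsample_nearest(self.mid_conv(top), 2)
        return self.out_conv(concat([mid, y2], axis=1))


class HybridEncoder(Module):
    def __init__(
        self,
        widths: tuple[int, int, int],
        rng,
        layers: int = 1,
        heads: int = 8,
        ffn_ratio: int = 4,
        branch_spec: DilatedBranchSpec | None = None,
        use_pconv: bool = False,
        r: float = 0.25,
    ):
        super().__init__()
        w3, w4, w5 = widths
        self.transformer = TransformerBranch(w5, heads, rng, layers=layers, ffn_ratio=ffn_ratio)
        spec = branch_spec if branch_spec is not None else DilatedBranchSpec(out_channels=w4)
        self.cnn_branch = DilatedCNNBranch(w3, spec, rng)
        self.fusion = CrossScaleFusion(
            w5, w4, self.cnn_branch.out_channels, rng, out_channels=w5, use_pconv=use_pconv, r=r
        )

    def forward(self, feats: MultiScaleFeatures) -> EncodedFeatures:
        y1 = self.transformer(feats.s5)
        y2 = self.cnn_branch(feats.s3)
        y3 = self.fusion(y1, feats.s4, y2)
        return EncodedFeatures(y1=y1, y2=y2, y3=y3)
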