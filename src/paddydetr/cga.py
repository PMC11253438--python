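"""Cascaded Group Attention (CGA).

Standard multi-head attention feeds every head the full feature vector, which
encourages redundant, highly correlated heads.  CGA instead splits the input
channels into h contiguous groups and gives each head its own group:

    head j   :  Xt_j = Attn(X'_j Wq_j, X'_j Wk_j, X'_j Wv_j)
    cascade  :  X'_j = X_j + Xt_{j-1}   for j > 1   (X'_1 = X_1)
    output   :  Concat(Xt_1 .. Xt_h) Wp

Because each head's Q/K/V projections read only C/h channels instead of C,
the QKV layers cost exactly 1/h of their standard-MHA counterparts, while the
cascade re-injects each head's output into the next head's input, deepening
the effective network at no parameter cost.
"""

from __future__ import annotations

import math

import numpy as np

from .nn import Tensor, concat, softmax
from .nn.modules import Linear, Module


def split_heads(x, h: int):
    """Split the channel axis of N x C tokens into h contiguous C/h groups.

    Order-preserving: concatenating the splits along the channel axis
    reconstructs the input exactly.  Works on Tensors and numpy arrays.
    """
    C = x.shape[-1]
    if C % h != 0:
        raise ValueError(f"channel count {C} not divisible by head count {h}")
    step = C // h
    return [x[..., j * step : (j + 1) * step] for j in range(h)]


def cga_qkv_cost(C: int, h: int, key_dim: int | None = None, n_tokens: int = 1):
    """Parameter and FLOP counts of the QKV projections, CGA vs standard MHA.

    Standard MHA projects the full C channels for each of the h heads; CGA
    projects only the head's C/h-channel split.  Returns a dict with both
    counts and their ratio, which is exactly 1/h.
    """
    if C % h != 0:
        raise ValueError(f"channel count {C} not divisible by head count {h}")
    if key_dim is None:
        key_dim = C // h
    split = C // h
    cga_params = h * 3 * split * key_dim
    std_params = h * 3 * C * key_dim
    cga_flops = n_tokens * cga_params
    std_flops = n_tokens * std_params
    return {
        "cga_params": cga_params,
        "std_params": std_params,
        "cga_flops": cga_flops,
        "std_flops": std_flops,
        "ratio": cga_params / std_params,
    }


class CascadedGroupAttention(Module):
    """Self-attention over B x N x C token stacks with channel-split heads
    and head-to-head cascading."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator, key_dim: int | None = None):
        super().__init__()
        if dim % heads != 0:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim = dim
        self.heads = heads
        self.split = dim // heads
        self.key_dim = key_dim if key_dim is not None else self.split
        # value dim equals the split width so the concatenation returns C dims
        self.wq = [Linear(self.split, self.key_dim, rng, bias=False) for _ in range(heads)]
        self.wk = [Linear(self.split, self.key_dim, rng, bias=False) for _ in range(heads)]
        self.wv = [Linear(self.split, self.split, rng, bias=False) for _ in range(heads)]
        self.proj = Linear(dim, dim, rng)
        self.last_attn: list[np.ndarray] | None = None  # row-stochastic maps, for inspection
        self.last_head_outputs: list[np.ndarray] | None = None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.dim:
            raise ValueError(f"expected {self.dim} channels, got {x.shape[-1]}")
        splits = split_heads(x, self.heads)
        scale = 1.0 / math.sqrt(self.key_dim)
        outs = []
        attns = []
        prev = None
        for j in range(self.heads):
            xj = splits[j] if prev is None else splits[j] + prev
            q = self.wq[j](xj)
            k = self.wk[j](xj)
            v = self.wv[j](xj)
            attn = softmax((q @ k.transpose(*range(q.ndim - 2), q.ndim - 1, q.ndim - 2)) * scale, axis=-1)
            out = attn @ v
            attns.append(attn.data)
            outs.append(out)
            prev = out
        self.last_attn = attns
        self.last_head_outputs = [o.data for o in outs]
        return self.proj(concat(outs, axis=-1))
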