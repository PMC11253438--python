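"""Set-prediction head: transformer decoder, bipartite matching, losses.

A fixed set of Q learnable queries cross-attends the fused encoder map y3 and
each query predicts a class distribution over {field_ridge,
single_barnyard_grass, patch_barnyard_grass, no_object} plus a normalized
(cx, cy, w, h) box.  Training assigns ground truths to queries by minimum-cost
bipartite (Hungarian) matching and applies cross-entropy, L1 and generalized
IoU losses to the matched pairs; unmatched queries are supervised toward
no_object with a down-weighted cross-entropy term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .nn import Tensor, maximum, minimum, softmax, stack
from .nn.modules import LayerNorm, Linear, Module, Parameter
from .encoder import flatten_map, sinusoidal_position_encoding_2d

NUM_CLASSES = 3
NO_OBJECT = NUM_CLASSES  # index of the "no object" class


# ---------------------------------------------------------------------------
# box geometry (numpy, xyxy)
# ---------------------------------------------------------------------------
def cxcywh_to_xyxy(b: np.ndarray) -> np.ndarray:
    b = np.asarray(b, dtype=np.float64)
    cx, cy, w, h = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=-1)


def xyxy_to_cxcywh(b: np.ndarray) -> np.ndarray:
    b = np.asarray(b, dtype=np.float64)
    x1, y1, x2, y2 = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack([(x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1], axis=-1)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of two xyxy box arrays, shape (len(a), len(b))."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    x1 = np.maximum(a[:, None, 0], b[None, :, 0])
    y1 = np.maximum(a[:, None, 1], b[None, :, 1])
    x2 = np.minimum(a[:, None, 2], b[None, :, 2])
    y2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x2 - x1, 0, None) * np.clip(y2 - y1, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(union > 0, inter / union, 0.0)


def giou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise generalized IoU (IoU minus enclosing-box penalty), in [-1, 1]."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    iou = iou_matrix(a, b)
    x1 = np.minimum(a[:, None, 0], b[None, :, 0])
    y1 = np.minimum(a[:, None, 1], b[None, :, 1])
    x2 = np.maximum(a[:, None, 2], b[None, :, 2])
    y2 = np.maximum(a[:, None, 3], b[None, :, 3])
    hull = (x2 - x1) * (y2 - y1)
    inter_x1 = np.maximum(a[:, None, 0], b[None, :, 0])
    inter_y1 = np.maximum(a[:, None, 1], b[None, :, 1])
    inter_x2 = np.minimum(a[:, None, 2], b[None, :, 2])
    inter_y2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(inter_x2 - inter_x1, 0, None) * np.clip(inter_y2 - inter_y1, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        return iou - np.where(hull > 0, (hull - union) / hull, 0.0)


# ---------------------------------------------------------------------------
# prediction containers
# ---------------------------------------------------------------------------
@dataclass
class DetectionSet:
    """Fixed-size set of query predictions for one image.

    class_probs: Q x (NUM_CLASSES + 1) rows on the probability simplex.
    boxes: Q x 4 normalized (cx, cy, w, h) in [0, 1].
    """

    class_probs: np.ndarray
    boxes: np.ndarray

    def __post_init__(self):
        self.class_probs = np.asarray(self.class_probs, dtype=np.float64)
        self.boxes = np.asarray(self.boxes, dtype=np.float64)
        if self.class_probs.ndim != 2 or self.boxes.shape != (len(self.class_probs), 4):
            raise ValueError("inconsistent DetectionSet shapes")

    @property
    def num_queries(self) -> int:
        return len(self.class_probs)


@dataclass
class MatchResult:
    """Injective assignment of ground-truth indices to query indices."""

    assignment: dict[int, int]
    cost: float


@dataclass
class LossBreakdown:
    total: float
    class_ce: float
    box_l1: float
    box_giou: float
    aux: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# matching and losses
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class MatchWeights:
    cls: float = 1.0
    l1: float = 5.0
    giou: float = 2.0


def match_cost_matrix(
    class_probs: np.ndarray,
    boxes_cxcywh: np.ndarray,
    gt_labels: np.ndarray,
    gt_boxes_cxcywh: np.ndarray,
    weights: MatchWeights,
) -> np.ndarray:
    """Q x G matching cost: -p(class) + L1 + (-GIoU), with the given weights."""
    cls_cost = -class_probs[:, gt_labels]
    l1_cost = np.abs(boxes_cxcywh[:, None, :] - gt_boxes_cxcywh[None, :, :]).sum(axis=-1)
    giou_cost = -giou_matrix(cxcywh_to_xyxy(boxes_cxcywh), cxcywh_to_xyxy(gt_boxes_cxcywh))
    return weights.cls * cls_cost + weights.l1 * l1_cost + weights.giou * giou_cost


def hungarian_match(
    preds: DetectionSet,
    gts: list[tuple[int, np.ndarray]],
    weights: MatchWeights = MatchWeights(),
) -> MatchResult:
    """Minimum-cost injective assignment of ground truths to queries.

    gts: list of (class_index, normalized cxcywh box).
    """
    if len(gts) > preds.num_queries:
        raise ValueError(f"{len(gts)} ground truths exceed {preds.num_queries} queries")
    if not gts:
        return MatchResult(assignment={}, cost=0.0)
    gt_labels = np.array([g[0] for g in gts])
    gt_boxes = np.stack([np.asarray(g[1], dtype=np.float64) for g in gts])
    cost = match_cost_matrix(preds.class_probs, preds.boxes, gt_labels, gt_boxes, weights)
    rows, cols = linear_sum_assignment(cost.T)  # rows: gt indices, cols: queries
    assignment = {int(r): int(c) for r, c in zip(rows, cols)}
    return MatchResult(assignment=assignment, cost=float(cost.T[rows, cols].sum()))


def classification_loss(
    class_probs,
    target_labels: np.ndarray,
    no_object_weight: float = 0.1,
    eps: float = 1e-8,
):
    """Weighted mean cross-entropy -log p(true class) over a query set.

    Accepts a Tensor (differentiable) or numpy array of probability rows.
    Queries whose target is no_object are down-weighted so the abundant
    background class does not swamp the loss.  Probabilities are clamped at
    `eps` before the log.
    """
    target_labels = np.asarray(target_labels, dtype=np.int64)
    n = len(target_labels)
    w = np.where(target_labels == NO_OBJECT, no_object_weight, 1.0)
    if isinstance(class_probs, Tensor):
        picked = class_probs[np.arange(n), target_labels]
        nll = -(picked.clamp_min(eps).log())
        return (nll * Tensor(w.astype(np.float32))).sum() / float(w.sum())
    probs = np.asarray(class_probs, dtype=np.float64)
    nll = -np.log(np.maximum(probs[np.arange(n), target_labels], eps))
    return float((w * nll).sum() / w.sum())


def classification_loss_from_logits(
    logits: Tensor, target_labels: np.ndarray, no_object_weight: float = 0.1
) -> Tensor:
    """Weighted-mean cross-entropy straight from logits (log-softmax form).

    Numerically safe in both directions: unlike the probability-space form it
    keeps a nonzero gradient even when a target class's probability has
    underflowed to zero."""
    from .nn import log_softmax

    target_labels = np.asarray(target_labels, dtype=np.int64)
    n = len(target_labels)
    w = np.where(target_labels == NO_OBJECT, no_object_weight, 1.0)
    lsm = log_softmax(logits, axis=-1)
    picked = lsm[np.arange(n), target_labels]
    return -(picked * Tensor(w.astype(np.float32))).sum() / float(w.sum())


def _giou_aligned(pred_xyxy: Tensor, gt_xyxy: np.ndarray) -> Tensor:
    """Differentiable elementwise GIoU of matched box pairs, shape (M,)."""
    g = Tensor(gt_xyxy.astype(np.float32))
    ix1 = maximum(pred_xyxy[:, 0], g[:, 0])
    iy1 = maximum(pred_xyxy[:, 1], g[:, 1])
    ix2 = minimum(pred_xyxy[:, 2], g[:, 2])
    iy2 = minimum(pred_xyxy[:, 3], g[:, 3])
    inter = (ix2 - ix1).clamp_min(0.0) * (iy2 - iy1).clamp_min(0.0)
    area_p = (pred_xyxy[:, 2] - pred_xyxy[:, 0]).clamp_min(0.0) * (
        pred_xyxy[:, 3] - pred_xyxy[:, 1]
    ).clamp_min(0.0)
    area_g = (g[:, 2] - g[:, 0]) * (g[:, 3] - g[:, 1])
    union = area_p + area_g - inter
    iou = inter / union.clamp_min(1e-9)
    hx1 = minimum(pred_xyxy[:, 0], g[:, 0])
    hy1 = minimum(pred_xyxy[:, 1], g[:, 1])
    hx2 = maximum(pred_xyxy[:, 2], g[:, 2])
    hy2 = maximum(pred_xyxy[:, 3], g[:, 3])
    hull = ((hx2 - hx1) * (hy2 - hy1)).clamp_min(1e-9)
    return iou - (hull - union) / hull


def _cxcywh_to_xyxy_t(b: Tensor) -> Tensor:
    cx, cy, w, h = b[:, 0], b[:, 1], b[:, 2], b[:, 3]
    half = Tensor(np.float32(0.5))
    return stack([cx - w * half, cy - h * half, cx + w * half, cy + h * half], axis=1)


def box_losses(matched_pred_boxes, gt_boxes: np.ndarray):
    """(mean L1, mean 1-GIoU) over matched pairs of normalized cxcywh boxes.

    Accepts a Tensor (differentiable) or a numpy array of predictions.
    The GIoU loss of each pair lies in [0, 2].
    """
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    if isinstance(matched_pred_boxes, Tensor):
        gt32 = Tensor(gt_boxes.astype(np.float32))
        diff = matched_pred_boxes - gt32
        l1 = maximum(diff, -diff).sum(axis=1).mean()
        giou = _giou_aligned(_cxcywh_to_xyxy_t(matched_pred_boxes), cxcywh_to_xyxy(gt_boxes))
        return l1, (1.0 - giou).mean()
    pred = np.asarray(matched_pred_boxes, dtype=np.float64).reshape(-1, 4)
    l1 = float(np.abs(pred - gt_boxes).sum(axis=1).mean()) if len(pred) else 0.0
    if len(pred):
        g = giou_matrix(cxcywh_to_xyxy(pred), cxcywh_to_xyxy(gt_boxes))
        giou_loss = float((1.0 - np.diagonal(g)).mean())
    else:
        giou_loss = 0.0
    return l1, giou_loss


# ---------------------------------------------------------------------------
# decoder modules
# ---------------------------------------------------------------------------
class MultiHeadAttention(Module):
    """Standard softmax attention with h heads over B x N x C stacks."""

    def __init__(self, dim: int, heads: int, rng):
        super().__init__()
        if dim % heads != 0:
            raise ValueError("dim must be divisible by heads")
        self.dim, self.heads, self.hd = dim, heads, dim // heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        b, nq, _ = q.shape
        nk = k.shape[1]
        scale = 1.0 / math.sqrt(self.hd)

        def split(x, n):
            return x.reshape(b, n, self.heads, self.hd).transpose(0, 2, 1, 3)

        qh, kh, vh = split(self.wq(q), nq), split(self.wk(k), nk), split(self.wv(v), nk)
        attn = softmax((qh @ kh.transpose(0, 1, 3, 2)) * scale, axis=-1)
        out = (attn @ vh).transpose(0, 2, 1, 3).reshape(b, nq, self.dim)
        return self.proj(out)


class DecoderLayer(Module):
    def __init__(self, dim: int, heads: int, rng, ffn_ratio: int = 4):
        super().__init__()
        self.self_attn = MultiHeadAttention(dim, heads, rng)
        self.norm1 = LayerNorm(dim)
        self.cross_attn = MultiHeadAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, dim * ffn_ratio, rng)
        self.fc2 = Linear(dim * ffn_ratio, dim, rng)
        self.norm3 = LayerNorm(dim)

    def forward(self, tgt: Tensor, query_pos: Tensor, memory: Tensor) -> Tensor:
        # pre-norm residual wiring: the unnormalised residual stream preserves
        # each query's identity, which plain SGD needs to avoid query collapse
        t = self.norm1(tgt)
        q = t + query_pos
        tgt = tgt + self.self_attn(q, q, t)
        t = self.norm2(tgt)
        tgt = tgt + self.cross_attn(t + query_pos, memory, memory)
        tgt = tgt + self.fc2(self.fc1(self.norm3(tgt)).relu())
        return tgt


class DETRDecoder(Module):
    """Query-based decoder over the fused map y3.

    num_queries learnable queries; shared class and box heads applied after
    every layer (auxiliary supervision).  `memory_stride` subsamples the y3
    token grid for cross-attention, a desk-scale cost knob.
    """

    def __init__(
        self,
        dim: int,
        rng,
        num_queries: int = 100,
        layers: int = 6,
        heads: int = 8,
        ffn_ratio: int = 4,
        memory_stride: int = 1,
    ):
        super().__init__()
        self.dim = dim
        self.num_queries = num_queries
        self.memory_stride = memory_stride
        bound = 1.0 / math.sqrt(dim)
        self.query_pos = Parameter(rng.uniform(-bound, bound, size=(num_queries, dim)))
        self.layers = [DecoderLayer(dim, heads, rng, ffn_ratio) for _ in range(layers)]
        self.final_norm = LayerNorm(dim)  # closes the pre-norm residual stack
        self.class_head = Linear(dim, NUM_CLASSES + 1, rng)
        self.box_fc1 = Linear(dim, dim, rng)
        self.box_fc2 = Linear(dim, dim, rng)
        self.box_head = Linear(dim, 4, rng)

    def _heads(self, tgt: Tensor):
        tgt = self.final_norm(tgt)
        logits = self.class_head(tgt)
        boxes = self.box_head(self.box_fc2(self.box_fc1(tgt).relu()).relu()).sigmoid()
        return logits, boxes

    def forward(self, y3: Tensor):
        """Returns a list of (class_logits, boxes) per decoder layer (last = final).

        class_logits: B x Q x (NUM_CLASSES + 1); boxes: B x Q x 4 (cxcywh in [0,1]).
        """
        b, c, h, w = y3.shape
        if c != self.dim:
            raise ValueError(f"decoder dim {self.dim} != y3 channels {c}")
        s = self.memory_stride
        mem_map = y3 if s == 1 else y3[:, :, ::s, ::s]
        hm, wm = mem_map.shape[2:]
        pe = sinusoidal_position_encoding_2d(hm, wm, c)
        memory = flatten_map(mem_map) + Tensor(pe[None])
        qpos = self.query_pos.reshape(1, self.num_queries, self.dim)
        ones = Tensor(np.ones((b, 1, 1), dtype=np.float32))
        query_pos = ones * qpos
        # seed the decoder state with the query embedding itself: each query
        # then carries its identity through the residual stream, not only
        # through its attention weights (robust against uniform-attention
        # collapse under plain SGD)
        tgt = query_pos
        outputs = []
        for layer in self.layers:
            tgt = layer(tgt, query_pos, memory)
            outputs.append(self._heads(tgt))
        return outputs


def decode(y3: Tensor, decoder: DETRDecoder) -> list[DetectionSet]:
    """Run the decoder in inference mode and package per-image DetectionSets."""
    outputs = decoder(y3)
    logits, boxes = outputs[-1]
    probs_np = softmax(logits, axis=-1).data
    return [
        DetectionSet(class_probs=probs_np[i], boxes=boxes.data[i])
        for i in range(probs_np.shape[0])
    ]
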