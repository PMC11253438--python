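"""Full detector: backbone -> hybrid encoder -> set-prediction decoder."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .backbone import Backbone, MultiScaleFeatures
from .encoder import DilatedBranchSpec, EncodedFeatures, HybridEncoder
from .head import (
    DETRDecoder,
    DetectionSet,
    LossBreakdown,
    MatchWeights,
    NO_OBJECT,
    box_losses,
    classification_loss,
    classification_loss_from_logits,
    decode,
    hungarian_match,
)
from .nn import Tensor, softmax
from .nn.modules import Module
from .pconv import PConv2d, pconv_flops, pconv_memory_access


@dataclass
class DetectorConfig:
    """Architecture hyperparameters.

    Defaults reproduce the published layout for a 640 x 640 x 3 input:
    pyramid channels 128/256/512 at strides 8/16/32, a single-layer CGA
    transformer on s5, dilated branches (6, 12, 18) at 80 channels on s3,
    and a 6-layer decoder with 100 queries.
    """

    widths: tuple = (128, 256, 512)
    backbone_depth: int = 2
    use_pconv: bool = False
    partial_ratio: float = 0.25
    encoder_layers: int = 1
    encoder_heads: int = 8
    ffn_ratio: int = 4
    dilations: tuple = (6, 12, 18)
    branch_channels: int = 80
    fused_channels: int = 80
    decoder_layers: int = 6
    decoder_heads: int = 8
    num_queries: int = 100
    memory_stride: int = 1
    seed: int = 0

    def branch_spec(self) -> DilatedBranchSpec:
        return DilatedBranchSpec(
            dilations=tuple(self.dilations),
            branch_channels=self.branch_channels,
            fused_channels=self.fused_channels,
            out_channels=self.widths[1],
        )


def tiny_config(seed: int = 0) -> DetectorConfig:
    """Desk-scale preset: narrow widths and a short decoder so full training
    runs on one CPU in minutes.  Shapes and dataflow are unchanged."""
    return DetectorConfig(
        widths=(32, 64, 128),
        backbone_depth=1,
        encoder_layers=1,
        encoder_heads=4,
        ffn_ratio=2,
        branch_channels=24,
        fused_channels=24,
        decoder_layers=2,
        decoder_heads=4,
        num_queries=12,
        seed=seed,
    )


class WeedDetector(Module):
    def __init__(self, config: DetectorConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.backbone = Backbone(
            rng,
            widths=tuple(config.widths),
            depth=config.backbone_depth,
            use_pconv=config.use_pconv,
            r=config.partial_ratio,
        )
        self.encoder = HybridEncoder(
            tuple(config.widths),
            rng,
            layers=config.encoder_layers,
            heads=config.encoder_heads,
            ffn_ratio=config.ffn_ratio,
            branch_spec=config.branch_spec(),
            use_pconv=config.use_pconv,
            r=config.partial_ratio,
        )
        self.decoder = DETRDecoder(
            config.widths[2],
            rng,
            num_queries=config.num_queries,
            layers=config.decoder_layers,
            heads=config.decoder_heads,
            ffn_ratio=config.ffn_ratio,
            memory_stride=config.memory_stride,
        )

    # -- forward paths --------------------------------------------------------
    def features(self, images: Tensor) -> tuple[MultiScaleFeatures, EncodedFeatures]:
        feats = self.backbone(images)
        return feats, self.encoder(feats)

    def forward(self, images: Tensor):
        """images: B x 3 x H x W in [0, 1].  Returns per-layer (logits, boxes)."""
        _, encoded = self.features(images)
        return self.decoder(encoded.y3)

    def predict(self, images: Tensor) -> list[DetectionSet]:
        self.eval()
        _, encoded = self.features(images)
        return decode(encoded.y3, self.decoder)

    # -- training loss --------------------------------------------------------
    def compute_loss(
        self,
        outputs,
        targets: list[list[tuple[int, np.ndarray]]],
        weights: MatchWeights = MatchWeights(),
        no_object_weight: float = 0.1,
        aux_loss: bool = True,
    ):
        """Hungarian-matched DETR loss over a batch.

        outputs: the per-layer (logits, boxes) list from forward().
        targets: per image, a list of (class_index, normalized cxcywh box).
        Returns (total_loss Tensor, LossBreakdown).
        """
        layer_range = range(len(outputs)) if aux_loss else [len(outputs) - 1]
        total = None
        breakdown = None
        aux_records = []
        final = len(outputs) - 1
        for li in layer_range:
            logits, boxes = outputs[li]
            probs = softmax(logits, axis=-1)
            b = logits.shape[0]
            layer_loss = None
            ce_v = l1_v = giou_v = 0.0
            for i in range(b):
                det = DetectionSet(class_probs=probs.data[i], boxes=boxes.data[i])
                match = hungarian_match(det, targets[i], weights)
                target_labels = np.full(det.num_queries, NO_OBJECT, dtype=np.int64)
                for g_idx, q_idx in match.assignment.items():
                    target_labels[q_idx] = targets[i][g_idx][0]
                ce = classification_loss_from_logits(logits[i], target_labels, no_object_weight)
                loss_i = weights.cls * ce
                if match.assignment:
                    order = sorted(match.assignment.items())
                    q_idx = np.array([q for _, q in order])
                    gt_boxes = np.stack([np.asarray(targets[i][g][1]) for g, _ in order])
                    l1, giou_l = box_losses(boxes[i][q_idx], gt_boxes)
                    loss_i = loss_i + weights.l1 * l1 + weights.giou * giou_l
                    l1_v += float(l1.data)
                    giou_v += float(giou_l.data)
                ce_v += float(ce.data)
                layer_loss = loss_i if layer_loss is None else layer_loss + loss_i
            layer_loss = layer_loss * (1.0 / b)
            record = {
                "total": float(layer_loss.data),
                "class_ce": ce_v / b,
                "box_l1": l1_v / b,
                "box_giou": giou_v / b,
            }
            if li == final:
                breakdown = record
            else:
                aux_records.append(record)
            total = layer_loss if total is None else total + layer_loss
        bd = LossBreakdown(
            total=float(total.data),
            class_ce=breakdown["class_ce"],
            box_l1=breakdown["box_l1"],
            box_giou=breakdown["box_giou"],
            aux=aux_records,
        )
        return total, bd

    # -- analytics ------------------------------------------------------------
    def conv_cost_table(self, input_hw: tuple[int, int] | None = (640, 640)) -> list[dict]:
        """Per-convolution FLOPs/memory rows, with the dense-equivalent ratio.

        Runs a dummy forward (if input_hw given) so every layer has recorded
        its input spatial size, then tabulates analytic costs.
        """
        from .nn.modules import Conv2d

        if input_hw is not None:
            self.eval()
            dummy = Tensor(np.zeros((1, 3, input_hw[0], input_hw[1]), dtype=np.float32))
            self.forward(dummy)
        rows = []
        for name, mod in self.named_modules():
            if isinstance(mod, PConv2d) and mod.last_input_hw is not None:
                h, w = mod.last_input_hw
                s = mod.spec
                dense = float(h * w * s.k * s.k * s.c * s.c)
                rows.append(
                    {
                        "layer": name,
                        "kind": "pconv",
                        "h": h,
                        "w": w,
                        "k": s.k,
                        "c_in": s.c,
                        "c_out": s.c,
                        "flops": pconv_flops(h, w, s.k, s.c, s.r),
                        "dense_flops": dense,
                        "flops_ratio": pconv_flops(h, w, s.k, s.c, s.r) / dense,
                        "memory_access": pconv_memory_access(h, w, s.k, s.c, s.r),
                        "dense_memory_access": float(h * w * 2 * s.c + s.k * s.k * s.c * s.c),
                    }
                )
            elif isinstance(mod, Conv2d) and mod.last_input_hw is not None:
                h, w = mod.last_input_hw
                k, ci, co, st = mod.kernel_size, mod.in_channels, mod.out_channels, mod.stride
                ho, wo = h // st, w // st
                flops = float(ho * wo * k * k * ci * co)
                rows.append(
                    {
                        "layer": name,
                        "kind": "conv",
                        "h": h,
                        "w": w,
                        "k": k,
                        "c_in": ci,
                        "c_out": co,
                        "flops": flops,
                        "dense_flops": flops,
                        "flops_ratio": 1.0,
                        "memory_access": float(ho * wo * 2 * co + k * k * ci * co),
                        "dense_memory_access": float(ho * wo * 2 * co + k * k * ci * co),
                    }
                )
        return rows

    def config_dict(self) -> dict:
        return asdict(self.config)
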