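"""Training loop: SGD with momentum and polynomial learning-rate decay.

The published schedule is SGD with base learning rate 0.001, momentum 0.9,
weight decay 1e-4, batch size 4 and 500 iterations, with the learning rate
decayed polynomially to a floor of 0:

    lr(t) = base_lr * (1 - t / max_iterations)^p
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .data import AnnotatedImage
from .head import DetectionSet, MatchWeights
from .model import WeedDetector
from .nn import Tensor
from .nn.optim import SGD


@dataclass
class TrainConfig:
    base_lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 4
    max_iterations: int = 500
    p: float = 0.9  # polynomial decay exponent
    min_lr: float = 0.0
    grad_clip: float = 0.1  # global-norm cap; 0 disables
    no_object_weight: float = 0.1
    aux_loss: bool = True
    optimizer: str = "sgd"  # "sgd" (published settings) or "adam" (desk-scale)
    seed: int = 0


def poly_lr(iter_num: int, cfg: TrainConfig) -> float:
    """Polynomially decayed learning rate at an iteration index.

    base_lr at iteration 0, the floor (0 by default) at max_iterations;
    monotone non-increasing in between.
    """
    if not 0 <= iter_num <= cfg.max_iterations:
        raise ValueError(
            f"iter_num {iter_num} outside [0, {cfg.max_iterations}]"
        )
    lr = cfg.base_lr * (1.0 - iter_num / cfg.max_iterations) ** cfg.p
    return max(lr, cfg.min_lr)


def image_to_input(img: AnnotatedImage) -> np.ndarray:
    """H x W x 3 uint8 -> 3 x H x W float32 in [0, 1]."""
    return (img.pixels.astype(np.float32) / 255.0).transpose(2, 0, 1)


def image_targets(img: AnnotatedImage) -> list[tuple[int, np.ndarray]]:
    """Annotations -> (class_index, normalized cxcywh) training targets."""
    h, w = img.height, img.width
    out = []
    for a in img.annotations:
        x1, y1, x2, y2 = a.box
        out.append(
            (
                a.label_index,
                np.array(
                    [(x1 + x2) / (2 * w), (y1 + y2) / (2 * h), (x2 - x1) / w, (y2 - y1) / h]
                ),
            )
        )
    return out


def detections_from(dets: DetectionSet, width: float, height: float) -> list[tuple]:
    """DetectionSet -> (class_index, score, pixel xyxy) rows, one per query.

    The score of a query is its highest non-background class probability.
    """
    out = []
    for probs, box in zip(dets.class_probs, dets.boxes):
        cls = int(np.argmax(probs[:-1]))
        score = float(probs[cls])
        cx, cy, w, h = box
        out.append(
            (
                cls,
                score,
                (
                    (cx - w / 2) * width,
                    (cy - h / 2) * height,
                    (cx + w / 2) * width,
                    (cy + h / 2) * height,
                ),
            )
        )
    return out


class NonFiniteLossError(RuntimeError):
    def __init__(self, iteration: int, breakdown):
        super().__init__(
            f"non-finite loss at iteration {iteration}: {breakdown}"
        )
        self.iteration = iteration
        self.breakdown = breakdown


def train_loop(
    model: WeedDetector,
    dataset: list[AnnotatedImage],
    cfg: TrainConfig,
    val_dataset: list[AnnotatedImage] | None = None,
    match_weights: MatchWeights = MatchWeights(),
    log_path: str | Path | None = None,
    checkpoint_dir: str | Path | None = None,
    log_every: int = 10,
) -> dict:
    """Optimize the detector on a dataset of annotated images.

    Per iteration: set the decayed learning rate, draw a seeded batch,
    forward, Hungarian matching, loss, backward, clip, step.  Returns the
    loss/lr history; optionally writes a JSONL log, a final checkpoint and a
    best-validation-mAP50 checkpoint (evaluated every 50 iterations).
    """
    from .evaluation import annotations_to_gts, map50  # local import, avoids cycle

    if not dataset:
        raise ValueError("dataset must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    if cfg.optimizer == "sgd":
        opt = SGD(
            model.parameters(),
            lr=cfg.base_lr,
            momentum=cfg.momentum,
            weight_decay=cfg.weight_decay,
        )
    elif cfg.optimizer == "adam":
        from .nn.optim import Adam

        opt = Adam(model.parameters(), lr=cfg.base_lr, weight_decay=cfg.weight_decay)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")
    inputs = [image_to_input(img) for img in dataset]
    targets = [image_targets(img) for img in dataset]
    history = {"loss": [], "lr": [], "class_ce": [], "box_l1": [], "box_giou": []}
    log_file = open(log_path, "w") if log_path else None
    best_map = -1.0
    checkpoint_dir = Path(checkpoint_dir) if checkpoint_dir else None

    def _eval_map(images):
        model.eval()
        gts = annotations_to_gts(images)
        preds = []
        for img in images:
            x = Tensor(image_to_input(img)[None])
            det = model.predict(x)[0]
            preds.append(detections_from(det, img.width, img.height))
        model.train()
        return map50(preds, gts)

    model.train()
    for it in range(cfg.max_iterations):
        opt.lr = poly_lr(it, cfg)
        idx = rng.choice(len(dataset), size=min(cfg.batch_size, len(dataset)), replace=False)
        batch = Tensor(np.stack([inputs[i] for i in idx]))
        batch_targets = [targets[i] for i in idx]
        outputs = model(batch)
        loss, bd = model.compute_loss(
            outputs,
            batch_targets,
            weights=match_weights,
            no_object_weight=cfg.no_object_weight,
            aux_loss=cfg.aux_loss,
        )
        if not np.isfinite(bd.total):
            if checkpoint_dir:
                checkpoint_dir.mkdir(parents=True, exist_ok=True)
                np.savez(checkpoint_dir / "diagnostic_state.npz", **model.state_dict())
            raise NonFiniteLossError(it, bd)
        opt.zero_grad()
        loss.backward()
        if cfg.grad_clip > 0:
            opt.clip_grad_norm(cfg.grad_clip)
        opt.step()
        history["loss"].append(bd.total)
        history["lr"].append(opt.lr)
        history["class_ce"].append(bd.class_ce)
        history["box_l1"].append(bd.box_l1)
        history["box_giou"].append(bd.box_giou)
        if log_file and (it % log_every == 0 or it == cfg.max_iterations - 1):
            log_file.write(
                json.dumps({"iter": it, "lr": opt.lr, **{k: history[k][-1] for k in
                            ("loss", "class_ce", "box_l1", "box_giou")}})
                + "\n"
            )
        if val_dataset and checkpoint_dir and (it + 1) % 50 == 0:
            vmap = _eval_map(val_dataset)
            if vmap > best_map:
                best_map = vmap
                checkpoint_dir.mkdir(parents=True, exist_ok=True)
                np.savez(checkpoint_dir / "best.npz", **model.state_dict())
    if log_file:
        log_file.close()
    if checkpoint_dir:
        checkpoint_dir.mkdir(parents=True, exist_ok=True)
        np.savez(checkpoint_dir / "last.npz", **model.state_dict())
        (checkpoint_dir / "train_config.json").write_text(json.dumps(asdict(cfg)))
    history["best_val_map50"] = best_map
    return history


def load_checkpoint(model: WeedDetector, path: str | Path):
    state = dict(np.load(Path(path)))
    model.load_state_dict(state)
    return model
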