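"""Experiment configuration: one YAML document wiring data, model, training
and evaluation settings, with strict (unknown-key-rejecting) parsing."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .model import DetectorConfig
from .synthetic import SyntheticSceneConfig
from .train import TrainConfig


@dataclass
class DataConfig:
    # synthetic-scene generation
    n_scenes: int = 32
    scene: SyntheticSceneConfig = field(default_factory=SyntheticSceneConfig)
    # preprocessing
    model_input_side: int = 640
    tile_size: int = 600
    augment: bool = False
    split_ratios: tuple = (7, 2, 1)


@dataclass
class EvalConfig:
    score_threshold: float = 0.5
    iou_threshold: float = 0.5


@dataclass
class ExperimentConfig:
    data: DataConfig = field(default_factory=DataConfig)
    model: DetectorConfig = field(default_factory=DetectorConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "ExperimentConfig":
        doc = dict(doc or {})
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        out = cls()
        for section, target in (
            ("data", DataConfig),
            ("model", DetectorConfig),
            ("train", TrainConfig),
            ("eval", EvalConfig),
        ):
            if section in doc:
                setattr(out, section, _build(target, doc[section], section))
        if "seed" in doc:
            out.seed = int(doc["seed"])
        return out

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(_listify(self.to_dict()), sort_keys=False))


def _build(target, doc: dict, section: str):
    doc = dict(doc or {})
    known = {f.name for f in fields(target)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
    kwargs = {}
    for f in fields(target):
        if f.name not in doc:
            continue
        v = doc[f.name]
        if f.name == "scene":
            v = _build(SyntheticSceneConfig, v, "data.scene")
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    if target is SyntheticSceneConfig:
        return target(**kwargs)
    obj = target()
    for k, v in kwargs.items():
        setattr(obj, k, v)
    return obj


def _listify(x):
    """YAML-friendly copy: tuples become lists (round-trips back via _build)."""
    if isinstance(x, dict):
        return {k: _listify(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_listify(v) for v in x]
    return x
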