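"""Run configuration: typed sections, YAML loading with strict validation.

Unknown keys are rejected and every numeric field is range-checked at load
time, so a typo in a config file fails immediately rather than silently
training the wrong model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields

import yaml

__all__ = ["ModelConfig", "TrainConfig", "DataConfig", "EvalConfig", "RunConfig",
           "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class ModelConfig:
    img_size: int = 160            # network input side, px (must be /32)
    K: int = 36                    # angle-class bins over [0, 180)
    beta: int = 2                  # CSL window radius, bins
    sigma: float = 0.7             # CSL Gaussian width, bins
    base_width: int = 16           # backbone base channel count
    neck_width: int = 32           # FPN lateral width
    micro_layer: bool = True       # stride-4 detection head on/off
    use_ciou: bool = True          # CIoU vs plain 1-IoU localization loss
    transform_net: bool = True     # color-transform front end on/off
    transform_channels: int = 16
    transform_blocks: int = 3
    n_codewords: int = 32
    transform_rescale: float = 3.0
    anchor_ratio_gate: float = 4.0
    w_localization: float = 0.05   # loss component weights
    w_objectness: float = 1.0
    w_classification: float = 0.5
    w_angle: float = 0.5

    def validate(self):
        for name in ("w_localization", "w_objectness", "w_classification", "w_angle"):
            _check(getattr(self, name) > 0, f"{name} must be positive")
        _check(self.img_size % 32 == 0 and self.img_size > 0,
               f"img_size must be a positive multiple of 32, got {self.img_size}")
        _check(self.K >= 2, "K must be >= 2")
        _check(0 < self.beta < self.K / 2, "beta must be in (0, K/2)")
        _check(self.sigma > 0, "sigma must be positive")
        _check(self.base_width >= 4 and self.neck_width >= 4, "widths must be >= 4")
        _check(self.transform_rescale > 0, "transform_rescale must be positive")
        _check(self.anchor_ratio_gate > 1, "anchor_ratio_gate must exceed 1")


@dataclass
class TrainConfig:
    optimizer: str = "sgd"
    batch_size: int = 16
    lr: float = 0.005
    transform_lr: float = None     # color-transform net lr; defaults to lr
    weight_decay: float = 1e-3
    momentum: float = 0.9
    epochs: int = 100
    cosine_decay: bool = True
    warmup_steps: int = 20
    seed: int = 0

    def validate(self):
        _check(self.optimizer == "sgd", f"unsupported optimizer {self.optimizer!r}")
        _check(self.batch_size >= 1, "batch_size must be >= 1")
        _check(self.lr > 0, "lr must be positive")
        _check(self.transform_lr is None or self.transform_lr > 0,
               "transform_lr must be positive when set")
        _check(self.weight_decay >= 0 and self.momentum >= 0, "negative decay/momentum")
        _check(self.epochs >= 1, "epochs must be >= 1")
        _check(self.warmup_steps >= 0, "warmup_steps must be >= 0")


@dataclass
class DataConfig:
    data_dir: str = "."
    manifest: str = "manifest.tsv"
    split_seed: int = 0

    def validate(self):
        pass


@dataclass
class EvalConfig:
    conf_threshold: float = 0.25
    nms_iou: float = 0.45
    tp_iou: float = 0.5

    def validate(self):
        for name in ("conf_threshold", "nms_iou", "tp_iou"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must be in [0, 1], got {v}")


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    data: DataConfig = field(default_factory=DataConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    def validate(self):
        for sec in (self.model, self.train, self.data, self.eval):
            sec.validate()

    # -- (de)serialization -------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        section_types = {f.name: f.default_factory for f in fields(cls)}
        unknown = set(d) - set(section_types)
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        sections = {}
        for name, factory in section_types.items():
            sec_cls = factory
            sub = d.get(name, {}) or {}
            valid = {f.name for f in fields(sec_cls)}
            bad = set(sub) - valid
            if bad:
                raise ConfigError(f"unknown keys in [{name}]: {sorted(bad)}")
            sections[name] = sec_cls(**sub)
        cfg = cls(**sections)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh) or {}
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return RunConfig.from_dict(d)
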