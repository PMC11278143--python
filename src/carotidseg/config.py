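"""Pipeline configuration: nested dataclasses with lossless YAML round-trip.

Every default is the reference protocol value: Adam lr 1e-4 with exponential
decay (253 steps, rate 0.96), Dice loss, 100-epoch cap with patience 10 on
validation mean IoU, 5 folds, probability threshold 0.5, dropout 0.6,
1000-filter bottleneck, 7×/1.3× area-stratified augmentation with the stated
transform probabilities, 7 self-training rounds with erosion in the first 4
and a 50% per-carotid IoU gate.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .augmentation import AugmentationPolicy
from .model import ResUnetConfig
from .self_training import SelfTrainConfig
from .synthetic import PhantomSpec
from .training import TrainConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


def _coerce(cls, data: dict):
    """Rebuild a dataclass from a YAML dict, restoring tuple-typed fields."""
    kwargs = {}
    defaults = {f.name: f.default for f in fields(cls)}
    for key, val in data.items():
        if key not in defaults:
            raise ValueError(f"unknown {cls.__name__} field {key!r}")
        if isinstance(val, list) and isinstance(defaults[key], tuple):
            val = tuple(val)
        kwargs[key] = val
    return cls(**kwargs)


@dataclass
class PipelineConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    model: ResUnetConfig = field(default_factory=ResUnetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    selftrain: SelfTrainConfig = field(default_factory=SelfTrainConfig)
    multiplier_small: float = 1.3
    multiplier_big: float = 7.0
    n_phantoms: int = 6
    contrast_range: tuple = (0.05, 0.30)
    run_dir: str = "runs/default"
    master_seed: int = 0
    log_level: str = "INFO"

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Propagate one master seed into every seeded sub-config."""
        from dataclasses import replace
        return replace(
            self,
            master_seed=seed,
            phantom=replace(self.phantom, seed=seed),
            augmentation=replace(self.augmentation, seed=seed),
            train=replace(self.train, seed=seed),
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _tuples_to_lists(obj):
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def save_config(cfg: PipelineConfig, path) -> None:
    data = _tuples_to_lists(cfg.to_dict())
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False, default_flow_style=None)


def load_config(path) -> PipelineConfig:
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh) or {}
    sections = {
        "phantom": PhantomSpec,
        "augmentation": AugmentationPolicy,
        "model": ResUnetConfig,
        "train": TrainConfig,
        "selftrain": SelfTrainConfig,
    }
    kwargs = {}
    for key, val in data.items():
        if key in sections:
            kwargs[key] = _coerce(sections[key], val or {})
        elif key == "contrast_range" and isinstance(val, list):
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return PipelineConfig(**kwargs)
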