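"""Run configuration: YAML loading for all pipeline components."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .convnext import ConvNeXtConfig
from .phantom import PhantomConfig
from .quality import QualityThresholds
from .training import AugmentConfig, TrainConfig


def _build(cls, data: dict):
    """Instantiate a (frozen) dataclass from a dict, tuple-izing sequence fields."""
    kwargs = {}
    valid = {f.name: f for f in fields(cls)}
    for key, value in (data or {}).items():
        if key not in valid:
            raise ValueError(f"unknown {cls.__name__} field {key!r}")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


@dataclass
class RunConfig:
    """Composite configuration for the whole pipeline.

    Defaults mirror the study settings: quality bands 10-30 (brightness)
    and [200, 300) (blurriness), Gaussian sigma 1 for the blur metric,
    decision threshold 0.5, Adam(0.5, 0.99) at lr 1e-4.
    """

    thresholds: QualityThresholds = field(default_factory=QualityThresholds)
    model: ConvNeXtConfig = field(default_factory=ConvNeXtConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    pooling_threshold: float = 0.5
    sigma: float = 1.0
    quality_on_resized: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pooling_threshold <= 1.0:
            raise ValueError("pooling_threshold must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        aug = data.get("train", {}).pop("augment", None) if isinstance(data.get("train"), dict) else None
        kwargs = {
            "thresholds": _build(QualityThresholds, data.pop("thresholds", {})),
            "model": _build(ConvNeXtConfig, data.pop("model", {})),
            "train": _build(TrainConfig, data.pop("train", {})),
            "phantom": _build(PhantomConfig, data.pop("phantom", {})),
        }
        if aug is not None:
            kwargs["train"].augment = _build(AugmentConfig, aug)
        for key in ("pooling_threshold", "sigma", "quality_on_resized"):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise ValueError(f"unknown RunConfig sections: {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(Path(path)) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "thresholds": asdict(self.thresholds),
            "model": asdict(self.model),
            "train": asdict(self.train),
            "phantom": asdict(self.phantom),
            "pooling_threshold": self.pooling_threshold,
            "sigma": self.sigma,
            "quality_on_resized": self.quality_on_resized,
        }
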