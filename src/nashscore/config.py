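"""Pipeline configuration: a single validated YAML document.

Unknown keys are rejected so typos fail loudly instead of silently using
defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class TileGeometry(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tile_px: int = 299
    mpp_high: float = 0.44
    mpp_low: float = 1.32
    min_tissue: float = 0.05


class ClassifierConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    backbone: str = "small_cnn"
    input_px: int = 96
    channels: tuple[int, ...] = (16, 32, 48, 64)
    n_per_class: int = 32
    epochs: int = 12
    batch_size: int = 32
    lr: float = 2e-3
    train_frac: float = 0.95


class AnnConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hidden: tuple[int, int] = (16, 8)
    epochs: int = 600
    lr: float = 0.01
    folds: int = 4


class StainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    vectors: list[list[float]] | None = None  # 2-3 OD triplets; default = package palette
    od_threshold: float = 0.15


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    geometry: TileGeometry = Field(default_factory=TileGeometry)
    classifiers: dict[str, ClassifierConfig] = Field(default_factory=dict)
    ann: AnnConfig = Field(default_factory=AnnConfig)
    stain: StainConfig = Field(default_factory=StainConfig)
    seed: int = 0

    @field_validator("classifiers")
    @classmethod
    def _known_features(cls, v):
        from .features import FEATURES

        unknown = set(v) - set(FEATURES)
        if unknown:
            raise ValueError(f"unknown features in classifier config: {sorted(unknown)}")
        return v

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def training_settings(self):
        from .pipeline import DEFAULT_TRAINING, TrainingSettings

        out = dict(DEFAULT_TRAINING)
        for feature, cc in self.classifiers.items():
            out[feature] = TrainingSettings(
                n_per_class=cc.n_per_class,
                epochs=cc.epochs,
                batch_size=cc.batch_size,
                lr=cc.lr,
                input_px=cc.input_px,
                channels=tuple(cc.channels),
                train_frac=cc.train_frac,
            )
        return out
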