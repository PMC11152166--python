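"""Structured pipeline configuration (YAML) with strict validation.

One global seed fans out to per-stage seeds via a stable hash of the stage
name, so each stage is independently reproducible.  Every run writes a
resolved-config snapshot beside its outputs.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InputConfig(_Strict):
    stride: int = 10
    n_source_frames: int = 120
    size: int = 128
    start_frame: int = 0


class SynthConfig(_Strict):
    n_embryos: int = 5
    frame_size: int = 64
    frame_rate: float = 30.0
    clip_seconds: float = 20.0
    mean_gap_hours: float = 3.0
    gap_jitter_hours: float = 1.0
    format: str = "gif"  # or "tiff"


class AugmentConfig(_Strict):
    p_enable: float = 0.5
    salt_pepper_fraction: float = 0.02
    blur_sigma_min: float = 0.5
    blur_sigma_max: float = 1.5
    selective: bool = True


class ModelConfig(_Strict):
    preset: str = "default"  # "default" or "tiny"
    overrides: dict = Field(default_factory=dict)  # ModelSpec fields

    def to_spec(self, input_shape=None, n_classes=None):
        from .model import DEFAULT_SPEC, ModelSpec, tiny_spec

        if self.preset == "default":
            base = DEFAULT_SPEC.to_dict()
        elif self.preset == "tiny":
            base = tiny_spec().to_dict()
        else:
            raise ValueError(f"unknown model preset: {self.preset!r}")
        base.update(self.overrides)
        if input_shape is not None:
            base["input_shape"] = list(input_shape)
        if n_classes is not None:
            base["n_classes"] = n_classes
        return ModelSpec.from_dict(base)


class TrainSection(_Strict):
    loss: str = "sparse_categorical_cross_entropy"
    learning_rate: float = 1e-6
    epochs: int = 50
    batch_size: int = 32
    n_repeats: int = 3
    triplet_margin: float = 1.0

    def to_train_config(self, seed: int):
        from .train import TrainConfig

        return TrainConfig(
            loss=self.loss,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=seed,
            n_repeats=self.n_repeats,
            triplet_margin=self.triplet_margin,
        )


class EventsConfig(_Strict):
    radula_threshold: float = 0.6
    hatch_threshold: float = 0.4
    dead_threshold: float = 0.3
    smoothing_window: int = 0

    def to_timing_config(self):
        from .events import EventTimingConfig
        from .taxonomy import EventLabel

        cfg = EventTimingConfig(smoothing_window=self.smoothing_window)
        cfg = cfg.with_threshold(EventLabel.RADULA, self.radula_threshold)
        cfg = cfg.with_threshold(EventLabel.HATCH, self.hatch_threshold)
        return cfg.with_threshold(EventLabel.DEAD, self.dead_threshold)


class AnalysisConfig(_Strict):
    projection: str = "linear_pca"
    n_neighbors: int = 15
    min_dist: float = 0.1


class PipelineConfig(_Strict):
    input: InputConfig = Field(default_factory=InputConfig)
    synth: SynthConfig = Field(default_factory=SynthConfig)
    augment: AugmentConfig = Field(default_factory=AugmentConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    train: TrainSection = Field(default_factory=TrainSection)
    events: EventsConfig = Field(default_factory=EventsConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    seed: int = 0
    out_dir: str = "outputs"
    log_level: str = "INFO"


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def save_snapshot(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Write the fully resolved config beside the run's outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "resolved_config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)
    return path


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from the global seed."""
    return int(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31)
    )
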