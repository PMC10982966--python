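"""Validated run configuration (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    # unknown keys are configuration typos (e.g. a misspelled threshold) and
    # must fail loudly
    model_config = ConfigDict(extra="forbid")


class SynthSection(_Strict):
    n_slides: int = 29
    block_grid: tuple[int, int] = (8, 6)
    tile_size: int = 512
    difficulty: float = 0.0
    annotated_fraction: float = 1.0
    test_fraction: float = 0.25


class TilingSection(_Strict):
    overlap: float = 0.5
    min_foreground_fraction: float = 0.0
    augment: bool = True


class TrainingSection(_Strict):
    backbone: str = "pooled-mlp"
    epochs: int = 10
    batch_size: int = 64
    learning_rate: float = 0.01
    validation_fraction: float = 0.2
    class_weight: str | None = "inverse_frequency"
    selection_metric: str = "balanced_accuracy"


class PseudoSection(_Strict):
    enabled: bool = True
    confidence_threshold: float = 0.90
    enforce_diagnosis: bool = True
    augment_pseudo: bool = False


class HeatmapSection(_Strict):
    enabled: bool = True
    alpha: float = 0.4


class RunConfig(_Strict):
    """Full pipeline configuration; the seed reaches every stochastic stage."""

    seed: int = 0
    synth: SynthSection = Field(default_factory=SynthSection)
    tiling: TilingSection = Field(default_factory=TilingSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    pseudo: PseudoSection = Field(default_factory=PseudoSection)
    heatmap: HeatmapSection = Field(default_factory=HeatmapSection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.model_validate(doc)

    def to_dict(self) -> dict:
        return json.loads(self.model_dump_json())

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
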