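"""Declarative experiment configuration with schema validation.

One YAML file drives a run: model geometry, training schedule,
confidence threshold, attention settings and the seed. Unknown keys are
rejected, and every run artifact embeds the resolved configuration and
its content hash so results are attributable to an exact setup.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .confidence import DEFAULT_THRESHOLD
from .encoder import ModelConfig
from .interpretation import DEFAULT_MIN_SAMPLES
from .objectives import LossWeights
from .trainer import TrainConfig


@dataclass
class ExperimentConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    confidence_threshold: float = DEFAULT_THRESHOLD
    min_attention_samples: int = DEFAULT_MIN_SAMPLES
    attention_rollout: bool = False
    seed: int = 0

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        _reject_unknown(data, {f.name for f in dataclasses.fields(cls)},
                        context="experiment config")
        if "model" in data:
            model = dict(data["model"])
            _reject_unknown(model,
                            {f.name for f in dataclasses.fields(ModelConfig)},
                            context="model config")
            if "tasks" in model:
                model["tasks"] = tuple(model["tasks"])
            data["model"] = ModelConfig(**model)
        if "training" in data:
            training = dict(data["training"])
            _reject_unknown(training,
                            {f.name for f in dataclasses.fields(TrainConfig)},
                            context="training config")
            if "loss_weights" in training:
                lw = dict(training["loss_weights"])
                _reject_unknown(lw,
                                {f.name for f in dataclasses.fields(LossWeights)},
                                context="loss weights")
                training["loss_weights"] = LossWeights(**lw)
            if training.get("tasks") is not None:
                training["tasks"] = tuple(training["tasks"])
            data["training"] = TrainConfig(**training)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


def _reject_unknown(data: dict, allowed: set, context: str):
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
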