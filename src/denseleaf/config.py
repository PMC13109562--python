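"""YAML run configuration mapping onto the dataclass configs."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .assign import CostWeights, MatchConfig
from .model import ModelConfig
from .scenes import SceneSpec
from .train import TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]


class RunConfig:
    """Bundle of model / training / scene configuration for one run."""

    def __init__(self, model: ModelConfig | None = None,
                 train: TrainConfig | None = None,
                 scene: SceneSpec | None = None):
        self.model = model or ModelConfig()
        self.train = train or TrainConfig()
        self.scene = scene or SceneSpec()

    def to_dict(self) -> dict:
        d = {"model": asdict(self.model), "train": asdict(self.train),
             "scene": asdict(self.scene)}
        # tuples serialize as lists; that is fine for YAML round-trip
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        model_d = dict(d.get("model", {}))
        match_d = model_d.pop("match", None)
        if match_d is not None:
            weights_d = match_d.pop("weights", None)
            weights = CostWeights(**weights_d) if weights_d else CostWeights()
            model_d["match"] = MatchConfig(weights=weights, **match_d)
        scene_d = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in dict(d.get("scene", {})).items()}
        return cls(
            model=ModelConfig(**model_d),
            train=TrainConfig(**dict(d.get("train", {}))),
            scene=SceneSpec(**scene_d),
        )


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
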