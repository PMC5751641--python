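"""Run configuration: model hyperparameters, feature switches, seeds.

Defaults reproduce the reference settings for both stages: the trigger
network (word dim 100, 3 hidden layers of 1000 units, batch 512, dropout
0.2) and the argument CNN (word dim 50, filter widths 3/5/7, 1000 dense
units, batch 128, dropout 0.2).  Every source of randomness in a run is
fanned out from the single ``seed`` via :func:`stage_seed`.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class TriggerModelConfig:
    word_dim: int = 100
    hidden_layers: int = 3
    hidden_units: int = 1000
    batch_size: int = 512
    dropout: float = 0.2


@dataclass
class ArgumentModelConfig:
    word_dim: int = 50
    filter_widths: tuple[int, ...] = (3, 5, 7)
    n_filters: int = 100
    hidden_units: int = 1000
    batch_size: int = 128
    dropout: float = 0.2


@dataclass
class RunConfig:
    seed: int = 0
    # feature geometry
    d_win: int = 2
    d_top: int = 50
    d_pos: int = 20
    d_dis: int = 20
    max_distance_bucket: int = 10
    max_path_len: int = 20
    # training schedule
    epochs: int = 80
    patience: int | None = 15
    validation_fraction: float = 0.1
    # trigger-stage feature ablation switches
    use_topic: bool = True
    use_pos: bool = True
    use_distance: bool = True
    # trigger-stage candidate handling
    trigger_pos_filter: bool = False   # restrict candidates to content words
    negative_downsample: float | None = None  # keep this fraction of negatives
    anchor_strategy: str = "last"      # "last" or "head" token of a span
    # argument-stage feature ablation switches
    arg_use_pos: bool = True
    arg_use_distance: bool = True
    arg_use_type: bool = True
    # evaluation
    recursive_core_only: bool = True
    # optional pretrained embeddings (word2vec text format)
    embeddings_path: str | None = None
    arg_embeddings_path: str | None = None
    trigger: TriggerModelConfig = field(default_factory=TriggerModelConfig)
    argument: ArgumentModelConfig = field(default_factory=ArgumentModelConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        trigger = TriggerModelConfig(**data.pop("trigger", {}))
        arg_raw = dict(data.pop("argument", {}))
        if "filter_widths" in arg_raw:
            arg_raw["filter_widths"] = tuple(arg_raw["filter_widths"])
        argument = ArgumentModelConfig(**arg_raw)
        return cls(trigger=trigger, argument=argument, **data)

    def to_yaml(self, path: str | Path) -> None:
        payload = self.to_dict()
        payload["argument"]["filter_widths"] = list(
            payload["argument"]["filter_widths"]
        )
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def fingerprint(self) -> str:
        return f"{zlib.crc32(repr(sorted(self.to_dict().items())).encode()):08x}"


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed (< 2**31)."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, stage))
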