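"""Run configuration: YAML serialization of every tunable block.

A run's effective configuration can be echoed next to its artifacts so any
result can be reproduced from the config file plus the seed alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .gait import GaitConfig
from .preprocessing import PreprocessConfig
from .upper_limb import UpperLimbConfig


@dataclass
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    kinematics: UpperLimbConfig = field(default_factory=UpperLimbConfig)
    gait: GaitConfig = field(default_factory=GaitConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "preprocess": dataclasses.asdict(self.preprocess),
            "kinematics": dataclasses.asdict(self.kinematics),
            "gait": dataclasses.asdict(self.gait),
            "seed": self.seed,
        }


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from YAML; missing blocks/keys keep their defaults."""
    cfg = RunConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for block, target in (
        ("preprocess", cfg.preprocess),
        ("kinematics", cfg.kinematics),
        ("gait", cfg.gait),
    ):
        for key, value in (data.get(block) or {}).items():
            if not hasattr(target, key):
                raise ValueError(f"unknown config key {block}.{key}")
            setattr(target, key, value)
    if "seed" in data:
        cfg.seed = int(data["seed"])
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
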