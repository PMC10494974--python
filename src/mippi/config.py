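"""Run configuration and seed management.

A run is described by one YAML/JSON document with nested ``model``,
``train``, ``loss``, ``pssm`` and ``paths`` sections plus a single
master ``seed``.  Unknown keys are rejected so typos cannot silently
fall back to defaults.  Every pipeline stage derives its own seed from
the master seed and a stage label through a fixed mixing function, so
each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path

import numpy as np
import yaml

from .network import ModelConfig
from .training import LossConfig, TrainConfig


def derive_seed(master: int, label: str) -> int:
    """Stable per-stage seed below 2**31 from the master seed and a label."""
    ss = np.random.SeedSequence([master & 0x7FFFFFFF, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclasses.dataclass
class RunConfig:
    model: ModelConfig
    train: TrainConfig
    loss: LossConfig
    pssm: dict
    paths: dict
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0) -> "RunConfig":
        return cls(
            model=ModelConfig(seed=derive_seed(seed, "model")),
            train=TrainConfig(seed=derive_seed(seed, "train")),
            loss=LossConfig(),
            pssm={"source": "pseudo", "database": None,
                  "iterations": 3, "evalue": 1e-3},
            paths={},
            seed=seed,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        base = cls.default(seed=int(data.pop("seed", 0)))
        for section, target in (("model", base.model), ("train", base.train),
                                ("loss", base.loss)):
            overrides = data.pop(section, {}) or {}
            known = {f.name for f in dataclasses.fields(target)}
            unknown = set(overrides) - known
            if unknown:
                raise ValueError(f"unknown {section} config keys: {sorted(unknown)}")
            for key, value in overrides.items():
                if key == "alpha" and isinstance(value, list):
                    value = tuple(value)
                setattr(target, key, value)
        base.pssm.update(data.pop("pssm", {}) or {})
        base.paths.update(data.pop("paths", {}) or {})
        if data:
            raise ValueError(f"unknown config sections: {sorted(data)}")
        return base

    def to_dict(self) -> dict:
        return {
            "model": dataclasses.asdict(self.model),
            "train": dataclasses.asdict(self.train),
            "loss": dataclasses.asdict(self.loss),
            "pssm": self.pssm,
            "paths": self.paths,
            "seed": self.seed,
        }

    def dump(self, path: str | Path) -> None:
        """Write the resolved configuration next to a run's outputs."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=str))
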