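"""Experiment configuration: one YAML schema driving every pipeline stage.

A single global seed fans out to per-stage seeds so stages can be re-run
independently and still reproduce bit-for-bit.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, replace

import yaml

from .networks import ArchitectureConfig
from .synthetic import SyntheticSpec
from .training import TrainConfig

__all__ = ["ExperimentConfig", "stage_seed"]

_STAGE_OFFSETS = {"synth": 1, "basis": 2, "train": 3, "evaluate": 4, "edit": 5}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global one (< 2**31)."""
    return (global_seed * 1000 + _STAGE_OFFSETS[stage]) % (2 ** 31 - 1)


@dataclass
class ExperimentConfig:
    """All knobs of a pipeline run."""

    output_dir: str = "ledshape_run"
    population_dir: str | None = None       # None -> generate synthetic data
    n_shapes: int = 889
    seed: int = 0
    kappa: int = 3
    n_candidate_modes: int | None = None
    flavour: str = "vae"
    led: bool = True
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    architecture: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    eval_n_generate: int = 100
    eval_vp_pairs: int = 6000

    def resolved(self) -> "ExperimentConfig":
        """Fan the global seed out into the stage configs."""
        synth = replace(self.synthetic, seed=stage_seed(self.seed, "synth"))
        train = replace(self.train, flavour=self.flavour,
                        seed=stage_seed(self.seed, "train"))
        if not self.led:
            train = replace(train, eta1=0.0, eta2=0.0, eta=0.0)
        return replace(self, synthetic=synth, train=train)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"]["factor_scale"] = list(d["synthetic"]["factor_scale"])
        d["architecture"]["channels"] = list(d["architecture"]["channels"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "synthetic" in d:
            syn = dict(d["synthetic"])
            if "factor_scale" in syn:
                syn["factor_scale"] = tuple(syn["factor_scale"])
            d["synthetic"] = SyntheticSpec(**syn)
        if "train" in d:
            d["train"] = TrainConfig(**d["train"])
        if "architecture" in d:
            arch = dict(d["architecture"])
            if "channels" in arch:
                arch["channels"] = tuple(arch["channels"])
            d["architecture"] = ArchitectureConfig(**arch)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
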