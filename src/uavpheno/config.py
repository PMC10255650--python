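"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .sensors import SENSORS
from .simulate import TRAITS


@dataclass
class MissionConfig:
    id: str
    sensor: str
    stage: str = "milk"          # phenological label: milk / dough
    noise_sd: float = 0.01      # additive reflectance noise SD
    fcover_scale: float = 1.0   # <1 emulates late-season senescence

    def __post_init__(self) -> None:
        if self.sensor not in SENSORS:
            raise ValueError(f"unknown sensor {self.sensor!r}")


@dataclass
class TrialConfig:
    trial_id: str
    n_genotypes: int
    n_replicates: int = 4


@dataclass
class RunConfig:
    seed: int
    outdir: str = "runs/demo"
    trials: list[TrialConfig] = field(default_factory=lambda: [
        TrialConfig("CVT1", 25), TrialConfig("CVT2", 30)])
    missions: list[MissionConfig] = field(default_factory=lambda: [
        MissionConfig("M1", "PS", "milk", 0.010, 1.0),
        MissionConfig("M2", "P4M", "milk", 0.008, 1.0),
        MissionConfig("M3", "PS", "dough", 0.020, 0.45),
        MissionConfig("M4", "P4M", "dough", 0.018, 0.45),
    ])
    n_soil: int = 60
    split_fraction: float = 2.0 / 3.0
    cv_folds: int = 10
    heritability_basis: str = "entry_mean"
    biophysical_replicates: list[int] = field(default_factory=lambda: [1, 2])
    biophysical_traits: list[str] = field(
        default_factory=lambda: ["LAI", "fAPAR", "fCover", "LCC"])
    ml_methods: list[str] = field(
        default_factory=lambda: ["plsr", "rfr", "krr", "gpr"])
    parametric_families: list[str] | None = None   # None = all 14
    soil_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.trials = [t if isinstance(t, TrialConfig) else TrialConfig(**t)
                       for t in self.trials]
        self.missions = [m if isinstance(m, MissionConfig)
                         else MissionConfig(**m) for m in self.missions]
        for t in self.biophysical_traits:
            if t not in TRAITS:
                raise ValueError(f"unknown trait {t!r}")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed."""
        return (int(self.seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
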