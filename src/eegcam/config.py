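"""YAML experiment configuration with fail-fast validation.

The on-disk format is a nested YAML document; pydantic models validate it
and report offending field paths.  Every section is optional — omitted
fields fall back to the library defaults, so ``{}`` is a valid config.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError

from .cv import CVConfig
from .model import ModelConfig
from .synth import BandSignature, CohortSpec, EpochSpec
from .training import TrainConfig


class SignatureCfg(BaseModel):
    band: str
    region: List[str]
    amplitude: float = Field(ge=0)
    amplitude_sd: float = Field(default=0.0, ge=0)
    per_trial_jitter: float = Field(default=0.0, ge=0)

    def build(self) -> BandSignature:
        return BandSignature(self.band, tuple(self.region), self.amplitude,
                             self.amplitude_sd, self.per_trial_jitter)


class CohortCfg(BaseModel):
    group_sizes: Optional[Dict[str, int]] = None
    trial_totals: Optional[Dict[str, Dict[str, int]]] = None
    signatures: Optional[Dict[str, List[SignatureCfg]]] = None
    noise_exponent: float = 1.0
    noise_scale: float = Field(default=10.0, ge=0)
    artifact_rates: Optional[Dict[str, float]] = None
    artifact_amplitudes: Optional[Dict[str, float]] = None
    scale: float = Field(default=1.0, ge=0)
    master_seed: int = 0

    def build(self) -> CohortSpec:
        kw = dict(noise_exponent=self.noise_exponent,
                  noise_scale=self.noise_scale, scale=self.scale,
                  master_seed=self.master_seed)
        if self.group_sizes is not None:
            kw["group_sizes"] = dict(self.group_sizes)
        if self.trial_totals is not None:
            kw["trial_totals"] = {g: dict(t) for g, t in self.trial_totals.items()}
        if self.signatures is not None:
            kw["signatures"] = {g: [s.build() for s in sigs]
                                for g, sigs in self.signatures.items()}
        if self.artifact_rates is not None:
            kw["artifact_rates"] = dict(self.artifact_rates)
        if self.artifact_amplitudes is not None:
            kw["artifact_amplitudes"] = dict(self.artifact_amplitudes)
        return CohortSpec(**kw)


class EpochCfg(BaseModel):
    fs: float = 250.0
    t_start: float = -80.0
    t_end: float = 1200.0
    n_channels: int = 60
    n_samples: int = 320

    def build(self) -> EpochSpec:
        return EpochSpec(self.fs, self.t_start, self.t_end,
                         self.n_channels, self.n_samples)


class ModelCfg(BaseModel):
    n_channels: int = 60
    n_samples: int = 320
    spatial_filters: int = 16
    temporal_kernel_len: int = 64
    depth_multiplier: int = 2
    n_classes: int = 2
    groups: Optional[int] = None
    init_seed: int = 0

    def build(self) -> ModelConfig:
        return ModelConfig(**self.model_dump())


class TrainCfg(BaseModel):
    learning_rate: float = Field(default=1e-3, gt=0)
    batch_size: int = Field(default=64, ge=1)
    max_epochs: int = Field(default=200, ge=1)
    patience: int = Field(default=20, ge=0)
    shuffle_seed: int = 0

    def build(self) -> TrainConfig:
        return TrainConfig(**self.model_dump())


class CVCfg(BaseModel):
    n_iterations: int = 100
    seed_start: int = 42
    seed_end: int = 141
    heldout_fraction: float = Field(default=0.20, gt=0, lt=1)
    task_filter: str = "ALL"

    def build(self) -> CVConfig:
        return CVConfig(**self.model_dump())


class RunConfig(BaseModel):
    cohort: CohortCfg = Field(default_factory=CohortCfg)
    epoch: EpochCfg = Field(default_factory=EpochCfg)
    model: ModelCfg = Field(default_factory=ModelCfg)
    train: TrainCfg = Field(default_factory=TrainCfg)
    cv: CVCfg = Field(default_factory=CVCfg)
    log_level: str = "INFO"


class ConfigError(ValueError):
    pass


def load_run_config(path: Optional[str | Path]) -> RunConfig:
    """Load and validate a YAML config; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as e:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in e.errors())
        raise ConfigError(f"invalid config {path}: {locs}") from None
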