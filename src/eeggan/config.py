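"""YAML run configuration and the run manifest.

The configuration is strict: unknown keys are errors, because a silently
ignored typo in a hyperparameter is the main reproducibility hazard in this
kind of experiment.  Every stage draws its randomness from seeds recorded in
the manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .models import CriticSpec, GeneratorSpec
from .cs import CSResNetSpec
from .synthetic import SyntheticConfig
from .training import TrainConfig


class ConfigError(ValueError):
    """Configuration failed schema validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticSection(_Strict):
    n_frames: int = 100
    frame_len: int = 500
    sampling_rate: float = 250.0
    bands: list[tuple[float, float, float]] | None = None
    noise_exponent: float = 1.0
    noise_power: float = 0.5
    amplitude_jitter: float = 0.1
    seed: int = 0

    def build(self) -> SyntheticConfig:
        kw = self.model_dump()
        if kw["bands"] is None:
            kw.pop("bands")
        else:
            kw["bands"] = tuple(tuple(b) for b in kw["bands"])
        return SyntheticConfig(**kw)


class PreprocessSection(_Strict):
    frame_len: int = 500
    sampling_rate: float = 250.0
    train_fraction: float = Field(0.7, gt=0.0, lt=1.0)
    seed: int = 0


class GeneratorSection(_Strict):
    noise_dim: int = 1000
    lstm_layers: int = 2
    lstm_units: int = 128
    timesteps: int | None = None
    output_len: int = 500
    fc_hidden: Optional[int] = None
    leaky_slope: float = 1e-4
    dropout: float = 0.5
    batchnorm_before_activation: bool = True
    output_activation: Literal["tanh", "linear"] = "tanh"

    def build(self) -> GeneratorSpec:
        kw = self.model_dump()
        if kw["timesteps"] is None:
            kw["timesteps"] = kw["noise_dim"]
        return GeneratorSpec(**kw).validate()


class CriticSection(_Strict):
    input_len: int = 500
    fc_pre: int = 256
    conv_filters: list[int] = [8, 16, 32, 64]
    kernel: int = 3
    stride: int = 2
    leaky_slope: float = 1e-4
    dropout: float = 0.5
    batchnorm: bool = True
    final_activation: Literal["sigmoid", "linear"] = "sigmoid"

    def build(self) -> CriticSpec:
        kw = self.model_dump()
        kw["conv_filters"] = tuple(kw["conv_filters"])
        return CriticSpec(**kw).validate()


class TrainSection(_Strict):
    loss_variant: Literal["bce", "wgan", "wgan_gp"] = "wgan_gp"
    gp_lambda: float = 10.0
    gp_mode: Literal["interpolate", "fake"] = "interpolate"
    critic_updates_per_gen: int = 5
    epochs: int = 1000
    batch_size: int = 64
    lr: float = 1e-3
    adam_betas: tuple[float, float] = (0.5, 0.9)
    lr_step: int = 50
    lr_gamma: float = 0.5
    noise_distribution: Literal["uniform01", "gaussian"] = "uniform01"
    seed: int = 0

    def build(self) -> TrainConfig:
        kw = self.model_dump()
        kw["adam_betas"] = tuple(kw["adam_betas"])
        return TrainConfig(**kw)


class MetricsSection(_Strict):
    aggregation: Literal["paired_mean", "nearest_real_mean"] = "paired_mean"
    n_generated: int = 64
    seed: int = 0


class CSSection(_Strict):
    cr_grid: list[int] = [10, 20, 30, 40, 50, 60, 70, 80, 90]
    fractions: list[int] = [0, 25, 50, 75, 100]
    ones_per_column: int = 4
    architecture: Literal["resnet", "plain_cnn"] = "resnet"
    epochs: int = 30
    batch_size: int = 64
    lr: float = 1e-3
    signal_len: int | None = None
    stem_filters: int = 16
    block_filters: list[int] = [32, 64, 128, 64, 32, 16]
    block_kernels: list[int] = [7, 7, 5, 5, 3, 3]
    blocks: int = 2
    dilation: int = 2
    seed: int = 0

    def build_spec(self, signal_len: int) -> CSResNetSpec:
        return CSResNetSpec(signal_len=self.signal_len or signal_len,
                            stem_filters=self.stem_filters,
                            blocks=self.blocks,
                            block_filters=tuple(self.block_filters),
                            block_kernels=tuple(self.block_kernels),
                            dilation=self.dilation).validate()


class RunConfig(_Strict):
    synthetic: SyntheticSection | None = None
    preprocess: PreprocessSection | None = None
    generator: GeneratorSection | None = None
    critic: CriticSection | None = None
    train: TrainSection | None = None
    metrics: MetricsSection | None = None
    cs: CSSection | None = None


def load_config(path) -> RunConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as e:
        raise ConfigError(f"invalid YAML: {e}") from e
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as e:
        locs = "; ".join(".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
                         for err in e.errors())
        raise ConfigError(f"config schema violation: {locs}") from e


def dump_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(cfg.model_dump(exclude_none=True), sort_keys=False)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Record of one CLI run: config snapshot, seeds, timings, artifacts."""

    def __init__(self, config: RunConfig, run_dir: Path):
        from . import __version__
        self.data = {
            "package_version": __version__,
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "config": config.model_dump(exclude_none=True),
            "seeds": {},
            "stages": {},
            "inputs": {},
            "outputs": {},
        }
        self.run_dir = Path(run_dir)

    def record_seed(self, stage: str, seed: int):
        self.data["seeds"][stage] = int(seed)

    def record_input(self, name: str, path):
        self.data["inputs"][name] = {"path": str(path), "sha256": sha256_file(path)}

    def record_stage(self, stage: str, seconds: float, **outputs):
        self.data["stages"][stage] = {"seconds": round(seconds, 3)}
        for k, v in outputs.items():
            self.data["outputs"][f"{stage}.{k}"] = str(v)

    def write(self) -> Path:
        self.run_dir.mkdir(parents=True, exist_ok=True)
        path = self.run_dir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2))
        return path
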