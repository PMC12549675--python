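"""Flat run configuration: every network, optimiser, scheduler, loss and
augmentation knob in one key:value file (YAML subset), round-tripping
without loss; unknown keys are rejected by name."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .network import NetworkConfig, TrainConfig

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # network
    embed_dim: int = 96
    encoder_depths: tuple = (2, 2, 2, 2)
    decoder_depths: tuple = (2, 2, 2, 1)
    mvsa_stages: tuple = (1,)
    mvsa_enabled: bool = True
    kass_enabled: bool = True
    csif_enabled: bool = True
    num_classes: int = 1
    state_dim: int = 16
    expand: int = 2
    grid_count: int = 8
    grid_min: float = -2.0
    grid_max: float = 2.0
    denominator: float = 0.33
    branch1_tail: str = "cam_ln"
    sigma_min: float = 0.5
    sigma_max: float = 5.0
    n_scales: int = 5
    frangi_beta: float = 0.5
    frangi_c: float = 15.0
    # optimisation
    epochs: int = 1000
    batch_size: int = 4
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    weight_decay: float = 1e-2
    t_max: int = 50
    lr_min: float = 1e-5
    w1: float = 1.0
    w2: float = 1.0
    augment: bool = True
    patience: int = 100
    # run
    seed: int = 0
    train_dir: str = ""
    val_dir: str = ""
    out_dir: str = "runs/train"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a key:value mapping")
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(raw) - set(known)
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        kwargs = {}
        for k, v in raw.items():
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        try:
            cfg = cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def network_config(self) -> NetworkConfig:
        names = {f.name for f in dataclasses.fields(NetworkConfig)}
        return NetworkConfig(**{k: v for k, v in dataclasses.asdict(self).items()
                                if k in names})

    def train_config(self) -> TrainConfig:
        names = {f.name for f in dataclasses.fields(TrainConfig)}
        d = dataclasses.asdict(self)
        return TrainConfig(**{k: v for k, v in d.items() if k in names})
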