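"""Pipeline configuration: defaults, YAML round-trip, strict validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classify import MLPConfig
from .ga import GAConfig

__all__ = ["SimulationConfig", "WindowConfig", "CVConfig", "PipelineConfig",
           "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised with an itemised list of offending keys."""


@dataclass
class SimulationConfig:
    n_subjects: int = 8
    analysis: str = "activity"          # activity | emotion | mental
    duration_per_class: float = 120.0
    inter_subject_jitter: float = 0.05
    noise_ecg: float = 0.02
    noise_teb: float = 0.01


@dataclass
class WindowConfig:
    window_s: float = 60.0
    stride_s: float = 10.0
    majority: float = 0.9
    baseline_alpha: float = 1.0 / 15000.0


@dataclass
class CVConfig:
    nmax: float = 80_000.0
    repetitions: int = 1


@dataclass
class PipelineConfig:
    ecg_fs: float = 250.0
    teb_fs: float = 100.0
    if_rate: float = 50.0
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    mlp: MLPConfig = field(default_factory=MLPConfig)
    cv: CVConfig = field(default_factory=CVConfig)


def _to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


def _from_dict(cls, data: dict, prefix: str, errors: list[str]):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            errors.append(f"{prefix}{key}")
            continue
        f = fields[key]
        sub = {"simulation": SimulationConfig, "window": WindowConfig,
               "ga": GAConfig, "mlp": MLPConfig, "cv": CVConfig}.get(key)
        if sub is not None and isinstance(value, dict):
            kwargs[key] = _from_dict(sub, value, f"{prefix}{key}.", errors)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        if not errors:
            raise ConfigError(str(exc)) from exc
        return None


def load_config(path) -> PipelineConfig:
    """Load YAML (or JSON) config; unknown keys raise an itemised error,
    missing keys take the defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    errors: list[str] = []
    cfg = _from_dict(PipelineConfig, data, "", errors)
    if errors:
        raise ConfigError("unknown config keys: " + ", ".join(sorted(errors)))
    return cfg


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))
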