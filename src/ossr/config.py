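"""Structured run configuration: typed sections, strict keys, YAML round-trip.

Every field has a default; unknown keys are rejected by name so a typo in a
config file fails loudly.  The effective configuration is dumped alongside
outputs for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .metrics import MetricConfig
from .phantom import DegradationSpec, PhantomSpec
from .registration import RegistrationConfig
from .simplenet import NetworkConfig
from .train import TrainingConfig
from .tvd import TVDConfig


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GradationConfig:
    window_center: float = -120.0  # HU, used when inputs carry no window metadata
    window_width: float = 1440.0


@dataclass
class RunConfig:
    gradation: GradationConfig = field(default_factory=GradationConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    metrics: MetricConfig = field(default_factory=MetricConfig)
    tvd: TVDConfig = field(default_factory=TVDConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    degradation: DegradationSpec = field(default_factory=DegradationSpec)
    seed: int = 0
    log_level: str = "INFO"


_SECTIONS = {
    "gradation": GradationConfig,
    "registration": RegistrationConfig,
    "network": NetworkConfig,
    "training": TrainingConfig,
    "metrics": MetricConfig,
    "tvd": TVDConfig,
    "phantom": PhantomSpec,
    "degradation": DegradationSpec,
}


def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")
    from .phantom import Structure

    fixed = {}
    for k, v in data.items():
        if cls is PhantomSpec and k == "structures":
            v = tuple(s if isinstance(s, Structure)
                      else _build(Structure, {kk: tuple(vv) if isinstance(vv, list)
                                              else vv for kk, vv in s.items()},
                                  f"{where}.structures")
                      for s in v)
        elif isinstance(v, list):
            v = tuple(v)
        fixed[k] = v
    return cls(**fixed)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file and/or a nested override dict."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    for section, values in (overrides or {}).items():
        if isinstance(values, dict):
            data.setdefault(section, {}).update(values)
        else:
            data[section] = values
    cfg = RunConfig()
    for key, values in data.items():
        if key in _SECTIONS:
            if not isinstance(values, dict):
                raise ConfigError(f"section {key} must be a mapping")
            setattr(cfg, key, _build(_SECTIONS[key], values, key))
        elif key == "seed":
            cfg.seed = int(values)
        elif key == "log_level":
            cfg.log_level = str(values)
        else:
            raise ConfigError(f"unknown config key: {key}")
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the effective configuration for provenance."""
    out = {name: dataclasses.asdict(getattr(cfg, name)) for name in _SECTIONS}
    out["seed"] = cfg.seed
    out["log_level"] = cfg.log_level
    # tuples and numpy scalars -> plain YAML types
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if hasattr(obj, "item"):
            return obj.item()
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(clean(out), fh, sort_keys=False)
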