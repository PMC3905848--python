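"""Pipeline configuration: one YAML file covering every free parameter.

Sections map onto the parameter dataclasses of the other modules
(``simulation`` → :class:`~irif3d.simulate.SimulationConfig`,
``detection`` → :class:`~irif3d.quantify.DetectionParams`,
``profiles`` → :class:`~irif3d.profiles.ProfileParams`).  Unknown keys are
rejected so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Union

import yaml

from .profiles import ProfileParams
from .quantify import DetectionParams
from .simulate import SimulationConfig


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    profiles: ProfileParams = field(default_factory=ProfileParams)
    quantile_convention: str = "linear"  # documentation tag; only linear implemented
    coloc_scope: str = "per-focus"

    def __post_init__(self):
        if self.quantile_convention != "linear":
            raise ConfigError(
                "only the linear-interpolation quantile convention is implemented"
            )
        if self.coloc_scope not in ("per-focus", "per-nucleus"):
            raise ConfigError(f"bad coloc_scope {self.coloc_scope!r}")


_SECTIONS = {
    "simulation": SimulationConfig,
    "detection": DetectionParams,
    "profiles": ProfileParams,
}


def _build_section(cls, values: dict) -> Any:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    coerced = {}
    for key, value in values.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    return cls(**coerced)


def config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw or {})
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            section = raw.pop(name)
            if not isinstance(section, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            kwargs[name] = _build_section(cls, section)
    top_known = {"quantile_convention", "coloc_scope"}
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs.update(raw)
    return PipelineConfig(**kwargs)


def load_config(path: Union[str, Path, None]) -> PipelineConfig:
    """Load a YAML config file; ``None`` yields all defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw or {})


def config_to_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [_clean(v) for v in obj]
        return obj

    return _clean(d)


def save_config(config: PipelineConfig, path: Union[str, Path]) -> None:
    """Write the effective configuration (provenance copy for outputs)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
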