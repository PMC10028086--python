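"""Pipeline configuration: one structured file controlling every threshold.

The config is a nested key/value document (YAML) with sections mirroring the
pipeline stages; CLI flags override file values.  ``config_keys`` enumerates
every dotted key so the command-line help can document them all.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .classification import ClassifyConfig
from .filtering import FilterConfig
from .statistics import EnrichmentThresholds

__all__ = ["StatsConfig", "PipelineConfig", "config_keys"]


@dataclass(frozen=True)
class StatsConfig:
    droplet_volume_uL: float = 0.00085
    alpha: float = 0.05
    enrichment: EnrichmentThresholds = EnrichmentThresholds()

    def __post_init__(self) -> None:
        if self.droplet_volume_uL <= 0:
            raise ValueError("droplet_volume_uL must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class PipelineConfig:
    filters: FilterConfig = FilterConfig()
    classification: ClassifyConfig = ClassifyConfig()
    stats: StatsConfig = StatsConfig()
    type_aliases: bool = False   # accept GAIN/LOSS tokens in call tables
    min_shared_patients: int = 2
    focal_max_size: int = 1_000_000

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        return _from_dict(cls, data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )


def _from_dict(cls, data: Mapping[str, Any]):
    kwargs = {}
    known = {f.name: f for f in fields(cls)}
    for key, value in data.items():
        if key not in known:
            raise ValueError(f"unknown config key {key!r} for {cls.__name__}")
        ftype = known[key].type
        default = known[key].default
        if is_dataclass(default.__class__) and isinstance(value, Mapping):
            kwargs[key] = _from_dict(default.__class__, value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def config_keys(cls=PipelineConfig, prefix: str = "") -> list[str]:
    """Every dotted config key, e.g. ``filters.min_del_size``."""
    keys: list[str] = []
    for f in fields(cls):
        default = f.default
        if is_dataclass(default.__class__) and not isinstance(default, type):
            keys.extend(config_keys(default.__class__, prefix + f.name + "."))
        else:
            keys.append(prefix + f.name)
    return keys
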