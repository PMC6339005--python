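"""Run configuration: one YAML file resolving every stage's parameters.

Defaults equal the protocol's stated values (300 ms per image, 20 × 10
trials, 2400 → 600 Hz, 40/49 Hz filter edges, 100 ms HDCA windows,
population 100 / crossover 0.85 / mutation 0.1, 5-fold CV, 2-trial logins).
Unknown keys are rejected, and every run can stamp the resolved
configuration (plus its hash) into its output sidecars for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ga import GAConfig
from .simulate import SimConfig


@dataclass(frozen=True)
class PreprocessConfig:
    passband_hz: float = 40.0
    stopband_hz: float = 49.0
    downsample_factor: int = 4
    tmin_ms: float = -200.0
    tmax_ms: float = 1000.0
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    pair_average: bool = True


@dataclass(frozen=True)
class HDCAConfig:
    window_ms: float = 100.0
    classify_tmin_ms: float = 0.0
    classify_tmax_ms: float = 1000.0
    threshold: float = 0.5


@dataclass(frozen=True)
class EvalConfig:
    cv_folds: int = 5
    trials_per_login: int = 2
    familiarity: float = 0.3  # non-blind imposter response strength


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    hdca: HDCAConfig = field(default_factory=HDCAConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    evaluate: EvalConfig = field(default_factory=EvalConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Short stable digest of the resolved configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        return _build(cls, raw, path="")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)


class ConfigError(ValueError):
    """Malformed run configuration (unknown key, wrong type, bad value)."""


_SECTION_TYPES = {
    "sim": SimConfig,
    "preprocess": PreprocessConfig,
    "hdca": HDCAConfig,
    "ga": GAConfig,
    "evaluate": EvalConfig,
}


def _build(cls, raw: dict, path: str):
    """Construct a (possibly nested) config dataclass, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - names
    if unknown:
        where = path or "top level"
        raise ConfigError(f"unknown config key(s) at {where}: {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        sub = _SECTION_TYPES.get(key)
        if sub is not None and path == "":
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            kwargs[key] = _build(sub, value, path=key)
        else:
            if isinstance(value, list):  # YAML has no tuples
                value = tuple(value)
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid config at {path or 'top level'}: {err}") from err
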