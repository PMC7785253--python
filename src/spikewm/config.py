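"""Run configuration: defaults, YAML (de)serialisation, validation, hashing.

Every default is the printed parameter of the modelled system where one
exists (population sizes and initial efficacies; aEIF constants; STP/STDP
constants; stimulus amplitudes; 10 Hz background; 40 ms motor bins); the
remaining fields — integration step, efficacy-to-current scale, phase
durations, analysis windows — are artifact choices documented in
docs/methods.md.  Unknown keys are rejected, and a saved configuration
round-trips to an identical hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields, replace

import yaml

from .embodiment import DecoderParams
from .engine import SimulationParams
from .network import NetworkParams
from .neuron import NeuronParams
from .plasticity import PlasticityParams
from .stimulus import Durations, StimulusParams

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "default_config"]


class ConfigError(ValueError):
    pass


_SECTIONS = {
    "network": NetworkParams,
    "neuron": NeuronParams,
    "plasticity": PlasticityParams,
    "stimulus": StimulusParams,
    "decoder": DecoderParams,
    "simulation": SimulationParams,
    "durations": Durations,
}


@dataclass(frozen=True)
class RunConfig:
    network: NetworkParams = field(default_factory=NetworkParams)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    decoder: DecoderParams = field(default_factory=DecoderParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    durations: Durations = field(default_factory=Durations)
    background_rate_hz: float = 10.0
    window_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.background_rate_hz < 0:
            raise ConfigError("background_rate_hz must be non-negative")
        if not (0 < self.window_frac <= 1):
            raise ConfigError("window_frac must lie in (0, 1]")
        if self.stimulus.n != self.network.n:
            raise ConfigError(
                f"stimulus.n ({self.stimulus.n}) must equal the network size "
                f"({self.network.n})"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["durations"]["incremental_cues_ms"] = list(
            d["durations"]["incremental_cues_ms"])
        return d

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def default_config() -> RunConfig:
    return RunConfig()


def _build_section(name: str, cls, data: dict):
    bad = set(data) - {f.name for f in fields(cls)}
    if bad:
        raise ConfigError(f"unknown key(s) in section '{name}': {sorted(bad)}")
    if name == "durations" and "incremental_cues_ms" in data:
        data = dict(data, incremental_cues_ms=tuple(data["incremental_cues_ms"]))
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in section '{name}': {exc}") from exc


def from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.pop(name, None) or {}
        if not isinstance(section, dict):
            raise ConfigError(f"section '{name}' must be a mapping")
        kwargs[name] = _build_section(name, cls, section)
    top = {f.name for f in fields(RunConfig)} - set(_SECTIONS)
    for key in list(data):
        if key not in top:
            raise ConfigError(f"unknown top-level key: {key!r}")
        kwargs[key] = data.pop(key)
    try:
        return RunConfig(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> RunConfig:
    """Merged defaults plus the overrides in a YAML file (may be empty)."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return from_dict(data or {})


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
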