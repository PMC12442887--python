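"""Run configuration: a YAML-backed bundle of game, agent, accumulator,
forward-model and pipeline parameters plus the session seed.

Unknown keys are rejected with the offending dotted path, and every
invariant violation names the field, so a config file either round-trips
exactly or fails loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .agents import AgentParams
from .erp_pipeline import PipelineConfig
from .game_engine import ConfigError, GameConfig
from .synthetic_eeg import AccumulatorParams, ForwardModel

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulated session bit-for-bit."""

    game: GameConfig = field(default_factory=GameConfig)
    agent: AgentParams = field(default_factory=lambda: AgentParams(kind="accumulator"))
    forward: ForwardModel = field(default_factory=ForwardModel)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int = 0
    participants: int = 1

    def __post_init__(self) -> None:
        # one shared accumulator: the agent's accumulator is authoritative
        if self.participants < 1:
            raise ConfigError(f"participants must be >= 1, got {self.participants}")

    @property
    def accumulator(self) -> AccumulatorParams:
        return self.agent.accumulator


_SECTIONS = {
    "game": GameConfig,
    "agent": AgentParams,
    "forward": ForwardModel,
    "pipeline": PipelineConfig,
}
_SCALARS = ("seed", "participants")


def _coerce(value: Any, default: Any) -> Any:
    if isinstance(default, tuple) and isinstance(value, (list, tuple)):
        return tuple(value)
    return value


def _build_section(cls, mapping: dict, section: str):
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    proto = cls() if section != "agent" else AgentParams(kind="accumulator")
    for key, value in mapping.items():
        if key not in fields:
            raise ConfigError(f"unknown key {section}.{key}")
        if key == "accumulator":
            kwargs[key] = _build_section(AccumulatorParams, value,
                                         f"{section}.accumulator")
        else:
            kwargs[key] = _coerce(value, getattr(proto, key))
    try:
        out = dataclasses.replace(proto, **kwargs)
    except (ValueError, ConfigError) as exc:
        raise ConfigError(f"in section {section!r}: {exc}") from exc
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Parse and validate a YAML config; missing keys take defaults.

    An empty (or absent) file yields the all-defaults configuration.
    Unknown keys raise :class:`~crabrp.game_engine.ConfigError` naming the
    dotted path.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        raw = loaded
    if overrides:
        raw = {**raw, **overrides}

    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            kwargs[key] = _build_section(_SECTIONS[key], value, key)
        elif key in _SCALARS:
            if not isinstance(value, int):
                raise ConfigError(f"{key} must be an integer, got {value!r}")
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown key {key}")
    return RunConfig(**kwargs)


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def config_dict(cfg: RunConfig) -> dict:
    return {
        "game": _to_plain(cfg.game),
        "agent": _to_plain(cfg.agent),
        "forward": _to_plain(cfg.forward),
        "pipeline": _to_plain(cfg.pipeline),
        "seed": cfg.seed,
        "participants": cfg.participants,
    }


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_dict(cfg), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 of the canonicalized configuration."""
    blob = json.dumps(config_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
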