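"""Strict run configuration: one flat YAML file with per-module blocks.

Unknown keys anywhere in the file are rejected before any stage runs, so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dynamics import ModelParams, TransferProtocol
from .synthetic import ExprSimParams, SpacerSimParams

__all__ = ["RunConfig", "ConfigError", "load_config"]

STAGES = ("dynamics", "spacers", "estimators", "expression")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a pipeline run."""

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    log_level: str = "INFO"
    model: ModelParams = field(default_factory=ModelParams)
    protocol: TransferProtocol = field(default_factory=TransferProtocol)
    spacer_sim: SpacerSimParams = field(default_factory=SpacerSimParams)
    expr_sim: ExprSimParams = field(default_factory=ExprSimParams)
    evolution_experiment: bool = True   # enable escape phage for the trajectory panel

    def __post_init__(self):
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ConfigError(f"unknown stages {sorted(bad)}; valid: {STAGES}")


def _build(cls, block: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under '{path}'")
    # YAML lists arrive as lists; tuple-typed fields need conversion
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in block:
            v = block[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    try:
        return cls(**kwargs)
    except ValueError as err:
        raise ConfigError(f"invalid value under '{path}': {err}") from err


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; ``overrides`` (same nesting) win."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
    for key, val in (overrides or {}).items():
        if isinstance(val, dict):
            raw.setdefault(key, {}).update(val)
        else:
            raw[key] = val

    top_known = {"seed", "stages", "log_level", "model", "protocol",
                 "spacer_sim", "expr_sim", "evolution_experiment"}
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")

    def block(name):
        b = raw.get(name, {})
        if not isinstance(b, dict):
            raise ConfigError(f"'{name}' must be a mapping")
        return b

    return RunConfig(
        seed=int(raw.get("seed", 0)),
        stages=tuple(raw.get("stages", STAGES)),
        log_level=str(raw.get("log_level", "INFO")),
        model=_build(ModelParams, block("model"), "model"),
        protocol=_build(TransferProtocol, block("protocol"), "protocol"),
        spacer_sim=_build(SpacerSimParams, block("spacer_sim"), "spacer_sim"),
        expr_sim=_build(ExprSimParams, block("expr_sim"), "expr_sim"),
        evolution_experiment=bool(raw.get("evolution_experiment", True)),
    )
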