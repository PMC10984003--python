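"""Run configuration: schema-validated YAML in, frozen YAML out.

A :class:`RunConfig` bundles the typed section objects the pipeline
stages consume.  Unknown keys are rejected with their full field path;
missing keys fall back to the library defaults (which are the
full-scale protocol values).
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .build import FibrilLayout
from .crosslink import CrossLinkConfig
from .dynamics import TensileProtocol
from .mineral import MineralPattern

__all__ = ["RunConfig", "load_config", "dump_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or malformed run configuration."""


_SECTIONS = {
    "layout": FibrilLayout,
    "mineral": MineralPattern,
    "crosslinks": CrossLinkConfig,
    "protocol": TensileProtocol,
}


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    units: str = "MPa"
    floor_frac: float = 0.01
    drop_frac: float = 0.05


@dataclasses.dataclass(frozen=True)
class RunConfig:
    layout: FibrilLayout = dataclasses.field(default_factory=FibrilLayout)
    mineral: MineralPattern = dataclasses.field(default_factory=MineralPattern)
    crosslinks: CrossLinkConfig = dataclasses.field(default_factory=CrossLinkConfig)
    protocol: TensileProtocol = dataclasses.field(default_factory=TensileProtocol)
    analysis: AnalysisConfig = dataclasses.field(default_factory=AnalysisConfig)
    forcefield_file: str | None = None
    equil_steps: int | None = None   # overrides protocol.t_equil when set
    seed: int = 0
    output_dir: str = "runs/out"


def _build_section(cls, raw: dict, path: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - fields
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{path}'"
        )
    try:
        return cls(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"section '{path}': {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    kw = {}
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_fields
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    for name, cls in _SECTIONS.items():
        section = raw.get(name) or {}
        if not isinstance(section, dict):
            raise ConfigError(f"section '{name}' must be a mapping")
        # tuples serialized as lists
        kw[name] = _build_section(cls, section, name)
    kw["analysis"] = _build_section(AnalysisConfig, raw.get("analysis") or {},
                                    "analysis")
    for scalar in ("forcefield_file", "equil_steps", "seed", "output_dir"):
        if scalar in raw:
            kw[scalar] = raw[scalar]
    return RunConfig(**kw)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration (idempotent round trip)."""
    out = {}
    for name in (*_SECTIONS, "analysis"):
        out[name] = dataclasses.asdict(getattr(cfg, name))
    out["forcefield_file"] = cfg.forcefield_file
    out["equil_steps"] = cfg.equil_steps
    out["seed"] = cfg.seed
    out["output_dir"] = cfg.output_dir
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))
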