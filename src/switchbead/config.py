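"""Run configuration: YAML (de)serialization, seeds, output provenance."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .params import ModelParams, preset

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    ``model`` is either a preset name or a full parameter mapping;
    ``overrides`` are applied on top (e.g. timescale, epsilon,
    scaling_exponent).  ``settings`` holds command-specific options.
    """

    command: str
    model: str | dict = "table1-3bead"
    overrides: dict[str, Any] = field(default_factory=dict)
    settings: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."

    def params(self) -> ModelParams:
        if isinstance(self.model, str):
            return preset(self.model, **self.overrides)
        merged = {**self.model, **self.overrides}
        return ModelParams(**merged)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        return cls(**d)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return RunConfig.from_dict(d)


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha1(cfg.to_yaml().encode()).hexdigest()[:12]


def provenance_header(cfg: RunConfig) -> str:
    """Comment line stamped at the top of every CSV output."""
    return f"# switchbead command={cfg.command} seed={cfg.seed} config={config_hash(cfg)}\n"
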