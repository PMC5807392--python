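"""Run configuration: a TOML file with [model], [protocol], [analysis] sections.

Unspecified fields fall back to the built-in defaults, so an empty config
reproduces the default runs. Configs round-trip losslessly through
``RunConfig.save`` / ``RunConfig.load``.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .params import ModelParameters

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Resolved configuration for a command-line run."""

    model: dict = field(default_factory=dict)      # ModelParameters overrides
    protocol: dict = field(default_factory=dict)   # frequency, count, amplitude, width, onset
    analysis: dict = field(default_factory=dict)   # spike/area thresholds, windows, step
    scan: dict = field(default_factory=dict)       # grids for faithfulness scans
    behavior: dict = field(default_factory=dict)   # generator profiles, n_animals, seed

    def parameters(self, **overrides) -> ModelParameters:
        merged = {**self.model, **{k: v for k, v in overrides.items() if v is not None}}
        return ModelParameters(**merged)

    def protocol_value(self, key: str, default):
        return self.protocol.get(key, default)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        with path.open("rb") as fh:
            data = tomllib.load(fh)
        known = {"model", "protocol", "analysis", "scan", "behavior"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config sections {sorted(unknown)}")
        return cls(**{k: data.get(k, {}) for k in known})

    def save(self, path) -> None:
        path = Path(path)
        lines = []
        for section in ("model", "protocol", "analysis", "scan", "behavior"):
            table = getattr(self, section)
            if not table:
                continue
            lines.append(f"[{section}]")
            for key, value in table.items():
                lines.append(f"{key} = {_toml_value(value)}")
            lines.append("")
        path.write_text("\n".join(lines))

    def to_manifest(self) -> dict:
        return asdict(self)


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return json.dumps(value)
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise TypeError(f"unsupported config value type: {type(value).__name__}")
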