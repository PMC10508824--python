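"""Run configuration: defaults, YAML loading, environment interpolation."""

from __future__ import annotations

import os
import re
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from gsnamer.errors import GsnamerError

_ENV_RE = re.compile(r"\$\{(?P<name>[A-Za-z_][A-Za-z0-9_]*)\}")


@dataclass
class RunConfig:
    """All pipeline knobs in one place; defaults match the shipped protocol."""

    obo_path: str | None = None
    annotations_path: str | None = None
    namespace: str = "biological_process"
    model_id: str = "scripted"
    embedder_id: str = "hash"
    temperature: float = 0.0
    seed: int = 42
    max_tokens: int = 1000
    alpha: float = 0.05
    min_ji: float = 0.1
    percentile_threshold: float = 95.0
    min_set_size: int = 3
    max_set_size: int = 100
    cache_dir: str | None = None
    output_dir: str = "."
    credentials_env: str | None = None

    def validate(self) -> None:
        if not 0.0 <= self.temperature <= 2.0:
            raise GsnamerError("temperature must lie in [0, 2]")
        if self.min_set_size > self.max_set_size:
            raise GsnamerError("min_set_size must be <= max_set_size")
        if not 0.0 < self.alpha <= 1.0:
            raise GsnamerError("alpha must lie in (0, 1]")


def _interpolate(value):
    if isinstance(value, str):
        def _sub(match: re.Match) -> str:
            name = match.group("name")
            if name not in os.environ:
                raise GsnamerError(f"environment variable {name!r} is not set")
            return os.environ[name]

        return _ENV_RE.sub(_sub, value)
    if isinstance(value, dict):
        return {k: _interpolate(v) for k, v in value.items()}
    if isinstance(value, list):
        return [_interpolate(v) for v in value]
    return value


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config, interpolating ``${ENV_VAR}`` references."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise GsnamerError("config file must contain a mapping")
    data = _interpolate(data)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise GsnamerError(f"unknown config keys: {sorted(unknown)}")
    config = RunConfig(**data)
    config.validate()
    return config


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))
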