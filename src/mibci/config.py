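"""Declarative run configuration (YAML, no code execution).

A run config mirrors the per-module configuration dataclasses as nested
sections; unknown keys are rejected by name, defaults are the published
hyperparameter table values baked into each dataclass.  A master seed
fans out to per-stage seeds by named hashing (see :mod:`mibci._seeds`),
so adding a stage never shifts another stage's randomness.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import ModelConfig
from .meta import MetaConfig
from .nas import NASConfig
from .preprocessing import PreprocessConfig
from .synthetic import SimConfig
from .training import TrainConfig

__all__ = ["RunConfig", "load_config", "dump_config", "write_manifest"]


class ConfigError(ValueError):
    pass


_SECTIONS = {
    "model": ModelConfig,
    "preprocess": PreprocessConfig,
    "sim": SimConfig,
    "train": TrainConfig,
    "meta": MetaConfig,
    "nas": NASConfig,
}


@dataclass(frozen=True)
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    meta: MetaConfig = field(default_factory=MetaConfig)
    nas: NASConfig = field(default_factory=NASConfig)
    master_seed: int = 0
    output_dir: str = "runs"


def _build_section(cls, payload: dict, path: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - fields
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section '{path}'")
    coerced = {}
    for key, value in payload.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section '{path}': {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run config; missing keys take defaults."""
    text = Path(path).read_text()
    payload = yaml.safe_load(text) or {}
    if not isinstance(payload, dict):
        raise ConfigError("top-level config must be a mapping")
    top_known = set(_SECTIONS) | {"master_seed", "output_dir"}
    unknown = set(payload) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = payload.get(name, {}) or {}
        if not isinstance(section, dict):
            raise ConfigError(f"section '{name}' must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    kwargs["master_seed"] = int(payload.get("master_seed", 0))
    kwargs["output_dir"] = str(payload.get("output_dir", "runs"))
    return RunConfig(**kwargs)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (list, dict)):
        return obj
    return obj


def dump_config(cfg: RunConfig) -> str:
    """Normalized YAML of a fully resolved config (round-trip stable)."""
    return yaml.safe_dump(_to_plain(cfg), sort_keys=True)


def write_manifest(out_dir, cfg: RunConfig, extra: dict | None = None) -> Path:
    """Reproducibility manifest: config, seed, versions, git hash."""
    import numpy, scipy, sklearn

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        git = subprocess.run(
            ["git", "rev-parse", "HEAD"], capture_output=True, text=True,
            timeout=5, check=False,
        ).stdout.strip() or None
    except Exception:
        git = None
    manifest = {
        "config": _to_plain(cfg),
        "master_seed": cfg.master_seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
        },
        "git_hash": git,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
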