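"""Config parsing, validation and run provenance for the command line.

Configs are YAML (or JSON) mappings whose keys map 1:1 onto the parameter
dataclasses of the analysis modules; unknown keys are rejected by name so a
typo never silently falls back to a default.  Every run writes a resolved
copy of its config and a plain-text log with the seed and package version
into the output directory, and all outputs are written atomically (temp
file + rename).
"""

from __future__ import annotations

import dataclasses
import os
import tempfile
from pathlib import Path

import yaml

from . import __version__

__all__ = [
    "ConfigError",
    "load_config",
    "validate_keys",
    "build_dataclass",
    "atomic_write_text",
    "atomic_write_frame",
    "write_run_log",
]


class ConfigError(ValueError):
    """A config failed schema validation."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def validate_keys(cfg: dict, allowed: set[str], context: str) -> None:
    unknown = sorted(set(cfg) - allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {context} config: {', '.join(unknown)}; "
            f"allowed: {', '.join(sorted(allowed))}"
        )


def build_dataclass(cls, cfg: dict, context: str, **overrides):
    """Instantiate a parameter dataclass from a config mapping, rejecting
    unknown keys and letting explicit overrides win."""
    fields = {f.name for f in dataclasses.fields(cls)}
    validate_keys(cfg, fields, context)
    merged = {**cfg, **{k: v for k, v in overrides.items() if v is not None}}
    # YAML lists for tuple-typed fields
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in merged:
            v = merged[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {context} config: {exc}") from exc


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_frame(path: str | Path, frame, float_format="%.6g") -> None:
    atomic_write_text(path, frame.to_csv(index=False, float_format=float_format))


def write_run_log(out_dir: str | Path, subcommand: str, seed, cfg: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atomic_write_text(
        out / "resolved_config.yaml", yaml.safe_dump(cfg, sort_keys=True)
    )
    atomic_write_text(
        out / "run.log",
        f"polyclust {__version__}\nsubcommand: {subcommand}\nseed: {seed}\n",
    )
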