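"""Run configuration: TOML-backed settings for the end-to-end pipeline.

A config file mirrors the dataclasses of the library::

    seed = 7
    out_dir = "runs/demo"
    n_subjects = 2

    [simulation]        # synthetic.SimConfig fields (seed comes from above)
    duration_s = 120.0

    [preprocess]
    target_fs = 128.0
    cutoff_hz = 60.0
    filter_order = 4

    [digitiser]         # extraction.DigitiserConfig fields
    window_seconds = 4.0
    scale_factor = 1e6
    byte_mode = "lsb"

Absent keys take defaults; unknown keys are rejected by name.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .extraction import DigitiserConfig
from .synthetic import SimConfig

__all__ = ["PreprocessConfig", "RunConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class PreprocessConfig:
    target_fs: float = 128.0
    cutoff_hz: float = 60.0
    filter_order: int = 4


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "gsrtrng-run"
    n_subjects: int = 1
    simulation: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    digitiser: DigitiserConfig = field(default_factory=DigitiserConfig)


_SECTIONS = {
    "simulation": SimConfig,
    "preprocess": PreprocessConfig,
    "digitiser": DigitiserConfig,
}
_TOP_KEYS = {"seed", "out_dir", "n_subjects"}


def _build_section(cls, table: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(table) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in [{section}] "
            f"(known: {sorted(known)})"
        )
    return cls(**table)


def load_config(path) -> RunConfig:
    """Load a TOML run configuration, applying defaults for absent keys."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        data = tomllib.load(fh)

    unknown = set(data) - _TOP_KEYS - set(_SECTIONS)
    if unknown:
        raise ValueError(
            f"unknown top-level key(s) {sorted(unknown)} "
            f"(known: {sorted(_TOP_KEYS | set(_SECTIONS))})"
        )
    top = {k: data[k] for k in _TOP_KEYS if k in data}
    sections = {}
    for name, cls in _SECTIONS.items():
        table = dict(data.get(name, {}))
        if name == "simulation":
            table.setdefault("seed", top.get("seed", RunConfig.seed))
        sections[name] = _build_section(cls, table, name)
    return RunConfig(**top, **sections)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    return repr(v)


def dump_config(config: RunConfig, path) -> None:
    """Write a config back to TOML (inverse of :func:`load_config`)."""
    lines = [f"{k} = {_toml_value(getattr(config, k))}" for k in sorted(_TOP_KEYS)]
    for name in _SECTIONS:
        obj = getattr(config, name)
        lines.append(f"\n[{name}]")
        for f in dataclasses.fields(obj):
            lines.append(f"{f.name} = {_toml_value(getattr(obj, f.name))}")
    Path(path).write_text("\n".join(lines) + "\n")
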