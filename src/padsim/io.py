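"""Configuration handling, structured logging, and file writers.

Run configurations are flat-ish TOML: a ``[params]`` table of NeuronParams
fields (or ``preset = "default"``), stimulus tables, and solver/grid
settings.  Every run echoes its full effective configuration next to its
outputs so results re-run to identical artifacts.
"""

from __future__ import annotations

import json
import logging
import sys
import tomllib
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np

from .params import NeuronParams, PRESETS
from .waveforms import ConductanceInput, CurrentInput

__all__ = [
    "load_config",
    "dump_toml",
    "write_json",
    "params_from_config",
    "conductance_from_config",
    "current_from_config",
    "setup_logging",
    "ConfigError",
]


class ConfigError(ValueError):
    """A configuration file contains unknown or invalid keys."""


def setup_logging(
    log_file: Optional[Union[str, Path]] = None, level: int = logging.INFO
) -> logging.Logger:
    logger = logging.getLogger("padsim")
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"
    )
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    return logger


def load_config(path: Union[str, Path]) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(float(v)) if isinstance(v, float) else repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)!r} to TOML")


def dump_toml(data: dict, path: Optional[Union[str, Path]] = None) -> str:
    """Minimal TOML emitter for (possibly one-level-nested) config dicts."""
    lines = []
    tables = {}
    for k, v in data.items():
        if isinstance(v, dict):
            tables[k] = v
        else:
            lines.append(f"{k} = {_toml_value(v)}")
    for name, tab in tables.items():
        lines.append("")
        lines.append(f"[{name}]")
        for k, v in tab.items():
            lines.append(f"{k} = {_toml_value(v)}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(data: Any, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


def params_from_config(cfg: dict) -> NeuronParams:
    """Build NeuronParams from a ``[params]`` table.

    The table may name a ``preset`` and/or override individual fields;
    unknown keys fail fast, named.
    """
    cfg = dict(cfg)
    preset = cfg.pop("preset", "default")
    if preset not in PRESETS:
        raise ConfigError(
            f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
        )
    try:
        return PRESETS[preset](**cfg)
    except TypeError as exc:
        raise ConfigError(f"invalid params table: {exc}") from exc


def conductance_from_config(cfg: dict) -> ConductanceInput:
    try:
        return ConductanceInput(**cfg)
    except TypeError as exc:
        raise ConfigError(f"invalid conductance table: {exc}") from exc


def current_from_config(cfg: dict) -> CurrentInput:
    try:
        return CurrentInput(**cfg)
    except TypeError as exc:
        raise ConfigError(f"invalid current table: {exc}") from exc
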