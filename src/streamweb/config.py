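"""Configuration files, manifests and bit-stable tabular output.

A run configuration is a flat YAML (or JSON — YAML is a superset)
mapping that mirrors :class:`~streamweb.params.ModelParams` field names
exactly, plus a handful of run-level keys.  Unknown keys are an error —
a silently ignored typo in a rate constant is worse than a crash.  The
free parameters ``alpha``, ``m_h`` and ``D_0`` may be given as the
string ``"calibrate"`` to request calibration at run time.

Every output directory receives a ``manifest.txt`` echoing the full
effective configuration (defaults included), the calibrated values,
the software version and the seed, so any run can be reproduced from
its manifest alone.  Numbers in tabular output are serialized with 12
significant digits, enough to make regression comparisons bit-stable
across platforms without printing float noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .params import ModelParams

__all__ = ["RunConfig", "ConfigError", "load_config", "write_manifest",
           "write_table", "format_value"]

CALIBRATE = "calibrate"

_PARAM_KEYS = tuple(f.name for f in dataclasses.fields(ModelParams))
_RUN_KEYS = ("D_0", "days", "seed", "subsidy_grid", "armoring_grid")


class ConfigError(ValueError):
    """Malformed run configuration."""


@dataclass
class RunConfig:
    """Validated run configuration."""

    params: ModelParams
    calibrate_keys: tuple[str, ...] = ()
    D_0: float | None = None
    days: int = 90
    seed: int = 0
    subsidy_grid: tuple[float, ...] | None = None
    armoring_grid: tuple[float, ...] | None = None

    @property
    def needs_calibration(self) -> bool:
        return bool(self.calibrate_keys) or \
            self.params.alpha is None or self.params.m_h is None


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a flat key-value configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a flat mapping, got {type(raw)}")
    unknown = sorted(set(raw) - set(_PARAM_KEYS) - set(_RUN_KEYS))
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")

    calibrate_keys = []
    param_values = {}
    for k in _PARAM_KEYS:
        if k not in raw:
            continue
        v = raw[k]
        if v == CALIBRATE:
            if k not in ("alpha", "m_h"):
                raise ConfigError(f"key {k} cannot be calibrated")
            calibrate_keys.append(k)
        else:
            param_values[k] = v
    try:
        params = ModelParams(**param_values)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid parameter value: {exc}") from exc

    kwargs: dict = {}
    if "D_0" in raw:
        if raw["D_0"] == CALIBRATE:
            calibrate_keys.append("D_0")
        else:
            kwargs["D_0"] = float(raw["D_0"])
    if "days" in raw:
        kwargs["days"] = int(raw["days"])
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    for grid in ("subsidy_grid", "armoring_grid"):
        if grid in raw:
            v = raw[grid]
            if not isinstance(v, (list, tuple)) or not v:
                raise ConfigError(f"{grid} must be a non-empty list")
            kwargs[grid] = tuple(float(x) for x in v)
    return RunConfig(params=params, calibrate_keys=tuple(calibrate_keys),
                     **kwargs)


def format_value(v) -> str:
    """Serialize one value: floats at 12 significant digits."""
    if isinstance(v, float):
        return f"{v:.12g}"
    return str(v)


def write_manifest(path: str | Path, config: RunConfig,
                   extra: dict | None = None) -> None:
    """Flat key=value manifest echoing every effective setting."""
    from . import __version__
    lines = [f"streamweb_version = {__version__}"]
    for k, v in config.params.to_dict().items():
        lines.append(f"{k} = {format_value(v)}")
    for k in ("D_0", "days", "seed", "subsidy_grid", "armoring_grid"):
        lines.append(f"{k} = {format_value(getattr(config, k))}")
    lines.append(f"calibrate_keys = {','.join(config.calibrate_keys) or 'none'}")
    for k, v in (extra or {}).items():
        lines.append(f"{k} = {format_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """CSV output with 12-significant-digit floats (bit-stable)."""
    df.to_csv(path, index=False, float_format="%.12g")
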