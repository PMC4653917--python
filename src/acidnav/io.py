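"""Run configuration and schema validation for CSV/JSON artifacts.

A run configuration is a flat JSON or YAML mapping whose keys are the union
of the decision parameters, the kinematic constants, the search grid and
score weights, plus ``seed``, ``n`` and ``verbosity``.  Unknown keys are
rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .search import ParameterGrid
from .simulate import DecisionParams, SimConfig
from .stats import CURVE_LABELS, REVERSAL_LABELS

__all__ = [
    "ConfigError",
    "EventValidationError",
    "RunConfig",
    "load_config",
    "dump_config",
    "validate_event_csv",
    "write_events_csv",
]


class ConfigError(ValueError):
    """Invalid or unknown run-configuration content."""


class EventValidationError(ValueError):
    """Event CSV failed schema validation; ``errors`` lists line-numbered issues."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


_PARAM_KEYS = {f.name for f in dc_fields(DecisionParams)}
_SIM_KEYS = {f.name for f in dc_fields(SimConfig)} - {"seed"}
_TOP_KEYS = {"seed", "n", "weights", "grid", "verbosity", "n_per_combo", "gradient", "out"}

_PARAM_DEFAULTS = dict(
    alpha_c=0.5, beta_c=4.3, alpha_r=0.5, beta_r=2.7, phi_c=30.0, dphi_c=10.0
)


@dataclass(frozen=True)
class RunConfig:
    """Validated union of decision, kinematic and search settings."""

    params: DecisionParams
    sim: SimConfig
    seed: Optional[int] = None
    n: int = 3000
    weights: tuple = (1.0, 1.0, 1.0, 1.0)
    grid: Optional[ParameterGrid] = None
    verbosity: str = "info"
    n_per_combo: int = 3000
    gradient: Optional[str] = None
    out: Optional[str] = None

    def require_seed(self) -> int:
        if self.seed is None:
            raise ConfigError("seed is mandatory for stochastic runs")
        return int(self.seed)


def _coerce_number(key: str, value: Any) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"config key {key!r} must be a number, got {value!r}")
    return float(value)


def config_from_mapping(data: Mapping[str, Any]) -> RunConfig:
    """Build a :class:`RunConfig` from a flat mapping, rejecting unknown keys."""
    known = _PARAM_KEYS | _SIM_KEYS | _TOP_KEYS
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    pkw = dict(_PARAM_DEFAULTS)
    for k in _PARAM_KEYS & set(data):
        pkw[k] = _coerce_number(k, data[k])
    skw: dict[str, Any] = {}
    for k in _SIM_KEYS & set(data):
        if k == "max_steps":
            skw[k] = int(_coerce_number(k, data[k]))
        else:
            skw[k] = _coerce_number(k, data[k])
    try:
        params = DecisionParams(**pkw)
        sim = SimConfig(**skw)
    except ValueError as e:
        raise ConfigError(str(e)) from e

    seed = data.get("seed")
    if seed is not None:
        seed = int(_coerce_number("seed", seed))
    grid = None
    if "grid" in data and data["grid"] is not None:
        if not isinstance(data["grid"], Mapping):
            raise ConfigError("grid must be a mapping of value lists")
        extra = set(data["grid"]) - set(ParameterGrid().to_dict())
        if extra:
            raise ConfigError(f"unknown grid keys: {sorted(extra)}")
        try:
            grid = ParameterGrid.from_dict(dict(data["grid"]))
        except ValueError as e:
            raise ConfigError(str(e)) from e
    weights = data.get("weights", (1.0, 1.0, 1.0, 1.0))
    weights = tuple(_coerce_number("weights", w) for w in weights)
    if len(weights) != 4:
        raise ConfigError("weights must have exactly 4 entries")
    return RunConfig(
        params=params,
        sim=sim,
        seed=seed,
        n=int(data.get("n", 3000)),
        weights=weights,
        grid=grid,
        verbosity=str(data.get("verbosity", "info")),
        n_per_combo=int(data.get("n_per_combo", 3000)),
        gradient=data.get("gradient"),
        out=data.get("out"),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())  # YAML is a superset of JSON
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError("config must be a mapping at the top level")
    return config_from_mapping(data)


def dump_config(cfg: RunConfig) -> dict:
    """Flatten a :class:`RunConfig` back to a plain mapping (round-trips)."""
    out: dict[str, Any] = {}
    for f in dc_fields(DecisionParams):
        out[f.name] = getattr(cfg.params, f.name)
    for name in sorted(_SIM_KEYS):
        out[name] = getattr(cfg.sim, name)
    out["seed"] = cfg.seed
    out["n"] = cfg.n
    out["weights"] = list(cfg.weights)
    out["verbosity"] = cfg.verbosity
    out["n_per_combo"] = cfg.n_per_combo
    if cfg.grid is not None:
        out["grid"] = cfg.grid.to_dict()
    if cfg.gradient is not None:
        out["gradient"] = cfg.gradient
    if cfg.out is not None:
        out["out"] = cfg.out
    return out


_VALID_MANEUVERS = REVERSAL_LABELS | CURVE_LABELS | {"none"}
_REQUIRED_COLS = ("maneuver", "angle_deg", "distance_mm")


def validate_event_csv(path: str | Path) -> pd.DataFrame:
    """Read and schema-check an avoidance-event CSV.

    Requires the columns maneuver, angle_deg and distance_mm (worm_id,
    time_s, sequence_index, trial_id, elapsed_s and terminated are optional).
    Collects every problem with its CSV line number (header = line 1) and
    raises :class:`EventValidationError` if any; otherwise returns the table.
    An empty file with a header is a valid empty table.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as e:  # unreadable / unparseable
        raise EventValidationError([f"cannot read {path}: {e}"]) from e
    errors = []
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise EventValidationError([f"missing required columns: {missing}"])
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        m = str(row["maneuver"])
        if m not in _VALID_MANEUVERS:
            errors.append(f"line {line}: unknown maneuver label {m!r}")
        try:
            a = float(row["angle_deg"])
            if not 0.0 <= a <= 90.0:
                errors.append(f"line {line}: angle {a} outside [0, 90]")
        except (TypeError, ValueError):
            errors.append(f"line {line}: non-numeric angle {row['angle_deg']!r}")
        try:
            float(row["distance_mm"])
        except (TypeError, ValueError):
            errors.append(f"line {line}: non-numeric distance {row['distance_mm']!r}")
        if "sequence_index" in df.columns:
            try:
                if int(row["sequence_index"]) < 1:
                    errors.append(f"line {line}: sequence_index must be >= 1")
            except (TypeError, ValueError):
                errors.append(f"line {line}: non-integer sequence_index")
    if errors:
        raise EventValidationError(errors)
    return df


def write_events_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write an event table with fixed 6-significant-digit floats.

    Fixed precision keeps repeated runs byte-identical and diffable.
    """
    df.to_csv(path, index=False, float_format="%.6g")
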