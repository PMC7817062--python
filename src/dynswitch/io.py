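"""Configuration schema and tabular I/O.

Run configurations are YAML files validated against a strict schema
(unknown keys rejected, first violation named).  Tabular results go to
CSV at 15 significant digits so write-then-read round-trips are
lossless at that precision; summaries and saddle-node/event metadata go
to JSON.  Every run directory receives a copy of the resolved
configuration so the run can be reproduced exactly.
"""

from __future__ import annotations

import json
from typing import Dict, List, Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .continuation import ResponseCurve, SaddleNode
from .dynamics import Trajectory
from .params import FeedbackParams, SwitchModulation

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "write_trajectory",
    "read_trajectory",
    "write_curve",
    "read_curve",
    "write_summary",
    "read_summary",
    "write_table",
    "read_table",
]

_FLOAT_FMT = "%.15g"


class ConfigError(ValueError):
    """Configuration rejected; message names the first schema violation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParamsBlock(_Strict):
    a: float = 0.3
    b: float = 1.0
    K: float = 1.0
    n: float = 5.0
    a_prime: float = 0.1
    b_prime: float = 1.0
    K_prime: float = 1.0
    m: float = 5.0
    epsilon: float = 0.05

    def build(self) -> FeedbackParams:
        return FeedbackParams(**self.model_dump())


class ModulationBlock(_Strict):
    a_bar: float = 0.3
    delta_a: float = 0.0
    kappa: float = 5.0
    X_c: Optional[float] = None  # None: midpoint of the static switch folds
    tau: float = 0.0

    def build(self, params: FeedbackParams) -> SwitchModulation:
        X_c = self.X_c
        if X_c is None:
            from .continuation import midpoint_Xc

            X_c = midpoint_Xc(params, self.a_bar)
        return SwitchModulation(
            a_bar=self.a_bar, delta_a=self.delta_a, kappa=self.kappa,
            X_c=X_c, tau=self.tau,
        )


class ExperimentBlock(_Strict):
    k_X: float = 1.0
    t_end: Optional[float] = None
    dt: float = 1e-3
    seed: int = 0
    replicates: int = 200
    sigma: float = 0.6
    omega: int = 20
    delta: Optional[float] = None
    delta_a_values: Optional[List[float]] = None
    kappa_values: Optional[List[float]] = None
    k_X_values: Optional[List[float]] = None
    a_values: Optional[List[float]] = None
    a_grid: Optional[List[float]] = None
    n_sets: int = 500
    X_T: float = 2.0
    D_X: float = 5.0
    D_Y: float = 5.0
    L: float = 100.0
    dx: float = 0.2
    initial_X: float = 0.0
    initial_X_T: float = 0.0


class RunConfig(_Strict):
    """Validated description of one command-line run."""

    model: Literal[
        "transition", "oscillator", "oscillator_full", "three_equation"
    ] = "transition"
    params: ParamsBlock = ParamsBlock()
    modulation: Optional[ModulationBlock] = None
    experiment: ExperimentBlock = ExperimentBlock()
    output_dir: str = "dynswitch_out"


def load_config(path: Optional[str], overrides: Optional[Dict] = None) -> RunConfig:
    """Read and validate a YAML configuration, applying flag overrides.

    Overrides use dotted keys (``experiment.k_X``).  Raises
    ``ConfigError`` naming the first violated field.
    """
    raw: Dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        target = raw
        parts = key.split(".")
        for part in parts[:-1]:
            target = target.setdefault(part, {})
        target[parts[-1]] = value
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigError(f"invalid config field {loc!r}: {first['msg']}") from exc


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Tables

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed table {path}: {exc}") from exc


def write_trajectory(traj: Trajectory, path) -> None:
    """Trajectory CSV with a time column followed by the state columns."""
    write_table(traj.to_frame(), path)


def read_trajectory(path) -> Trajectory:
    df = read_table(path)
    if "t" not in df.columns:
        raise ValueError(f"trajectory file {path} lacks a 't' column")
    data = {c: df[c].to_numpy() for c in df.columns if c != "t"}
    return Trajectory(times=df["t"].to_numpy(), data=data)


def write_curve(curve: ResponseCurve, path, saddle_path=None) -> None:
    curve.to_csv(path)
    if saddle_path is not None:
        with open(saddle_path, "w") as fh:
            fh.write(curve.saddle_nodes_json())


def read_curve(path, varied_parameter: str = "X_T") -> ResponseCurve:
    df = read_table(path)
    return ResponseCurve(
        varied_parameter=varied_parameter,
        parameter=df["parameter"].to_numpy(),
        X=df["X"].to_numpy(),
        stable=df["stable"].to_numpy(dtype=bool),
    )


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, SaddleNode):
        return {"parameter": obj.parameter, "X": obj.X}
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_summary(summary: Dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonify(summary), fh, indent=2)


def read_summary(path) -> Dict:
    with open(path) as fh:
        return json.load(fh)
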