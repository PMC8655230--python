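"""File I/O: paired-series CSV, versioned JSON model files, YAML run configs.

Model files carry every numeric field at full double precision (Python's
shortest-round-trip float repr), so save -> load reproduces a model bitwise.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidConfigError, ModelFormatError, ParseError
from .hebbian import HebbianMatrix
from .learner import PairedSeries, TrainConfig, TrainedModel
from .som import LearningSchedule, SOMPopulation

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "save_model",
    "load_model",
    "read_config",
    "MODEL_FORMAT_VERSION",
]

MODEL_FORMAT_VERSION = "relsom-model-1"


def read_series_csv(path) -> PairedSeries:
    """Parse a paired series from CSV.

    Expects a header and either two numeric columns (time, value; the time
    stamp doubles as the first covariate) or three (time, covariate a,
    covariate b).  Malformed cells and non-increasing times are reported with
    their 1-based data row number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - normalized into ParseError
        raise ParseError(f"{path}: cannot read CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need at least 2 columns (time + covariate), got {df.shape[1]}")
    for col in df.columns[: min(df.shape[1], 3)]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(f"{path}: non-numeric value in column {col!r} at data row {bad[0] + 1}")
        if coerced.isna().any():
            raise ParseError(
                f"{path}: missing value in column {col!r} at data row {int(coerced.index[coerced.isna()][0]) + 1}"
            )
        df[col] = coerced
    t = df.iloc[:, 0].to_numpy(dtype=float)
    steps = np.diff(t)
    if np.any(steps <= 0):
        row = int(np.flatnonzero(steps <= 0)[0]) + 2
        raise ParseError(f"{path}: time stamps must be strictly increasing (data row {row})")
    if df.shape[1] == 2:
        a, b = t, df.iloc[:, 1].to_numpy(dtype=float)
        labels = (str(df.columns[0]), str(df.columns[1]))
    else:
        a = df.iloc[:, 1].to_numpy(dtype=float)
        b = df.iloc[:, 2].to_numpy(dtype=float)
        labels = (str(df.columns[1]), str(df.columns[2]))
    try:
        return PairedSeries(times=t, series_a=a, series_b=b, labels=labels)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_series_csv(series: PairedSeries, path) -> None:
    """Write a paired series with full-precision floats (round-trip exact)."""
    df = pd.DataFrame(
        {"time": series.times, series.labels[0]: series.series_a, series.labels[1]: series.series_b}
    )
    if np.array_equal(series.times, series.series_a):
        df = df.iloc[:, [0, 2]]  # time doubles as covariate a; keep the file 2-column
    df.to_csv(path, index=False, float_format="%.17g")  # round-trip exact


def _schedule_to_dict(s: LearningSchedule) -> dict:
    return {
        "alpha_start": s.alpha_start,
        "alpha_end": s.alpha_end,
        "sigma_start": s.sigma_start,
        "eta_start": s.eta_start,
        "beta_start": s.beta_start,
        "decay_timescale": s.decay_timescale,
        "epochs": s.epochs,
    }


def _config_to_dict(c: TrainConfig) -> dict:
    return {
        "n_neurons": c.n_neurons,
        "schedule": _schedule_to_dict(c.schedule),
        "epsilon": c.epsilon,
        "max_epochs": c.max_epochs,
        "seed": c.seed,
        "normalization": c.normalization,
        "projection_convention": c.projection_convention,
        "width_floor": c.width_floor,
    }


def _config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    sched = d.pop("schedule", None)
    if sched is not None:
        sched = LearningSchedule(**sched)
    try:
        return TrainConfig(schedule=sched, **d)
    except TypeError as exc:
        raise InvalidConfigError(f"bad config keys: {exc}") from exc


def save_model(model: TrainedModel, path) -> None:
    """Serialize a trained model as a versioned JSON document."""
    doc = {
        "format": MODEL_FORMAT_VERSION,
        "pop_a": {
            "preferred_values": model.pop_a.preferred_values.tolist(),
            "tuning_widths": model.pop_a.tuning_widths.tolist(),
        },
        "pop_b": {
            "preferred_values": model.pop_b.preferred_values.tolist(),
            "tuning_widths": model.pop_b.tuning_widths.tolist(),
        },
        "link": {
            "weights": model.link.weights.tolist(),
            "trace_p": model.link.trace_p.tolist(),
            "trace_q": model.link.trace_q.tolist(),
        },
        "norm_bounds": {k: list(v) for k, v in model.norm_bounds.items()},
        "history": list(model.history),
        "converged": model.converged,
        "config": _config_to_dict(model.config),
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> TrainedModel:
    """Load a model file, rejecting unknown versions and truncated documents."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON (truncated file?): {exc}") from exc
    fmt = doc.get("format")
    if fmt != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported model format {fmt!r}; this build reads {MODEL_FORMAT_VERSION!r}. "
            "Re-train or convert the model."
        )
    try:
        return TrainedModel(
            pop_a=SOMPopulation(
                np.array(doc["pop_a"]["preferred_values"]), np.array(doc["pop_a"]["tuning_widths"])
            ),
            pop_b=SOMPopulation(
                np.array(doc["pop_b"]["preferred_values"]), np.array(doc["pop_b"]["tuning_widths"])
            ),
            link=HebbianMatrix(
                np.array(doc["link"]["weights"]),
                np.array(doc["link"]["trace_p"]),
                np.array(doc["link"]["trace_q"]),
            ),
            norm_bounds={k: tuple(v) for k, v in doc["norm_bounds"].items()},
            history=list(doc["history"]),
            converged=bool(doc["converged"]),
            config=_config_from_dict(doc["config"]),
        )
    except KeyError as exc:
        raise ModelFormatError(f"{path}: missing field {exc} (truncated file?)") from exc


def read_config(path) -> TrainConfig:
    """Read a flat YAML (or JSON) run configuration into a TrainConfig."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise InvalidConfigError(f"{path}: config must be a mapping")
    known = {
        "n_neurons", "schedule", "epsilon", "max_epochs", "seed",
        "normalization", "projection_convention", "width_floor",
    }
    unknown = set(raw) - known
    if unknown:
        raise InvalidConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    return _config_from_dict(raw)
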