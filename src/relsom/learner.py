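"""End-to-end relation learning between two irregularly sampled series.

Training normalizes both covariates to the unit interval, encodes each in its
own self-organizing population, and — sample by sample, in seeded shuffled
order — runs competition and cooperation in both maps while a centered
Hebbian rule accumulates the cross-population correlation structure.  The run
relaxes when the per-epoch relative change of all weights drops below a
threshold.  Inference pushes a value through one map, across the Hebbian
matrix, and decodes it from the other map, so any quantity can be recovered
from its partner in either direction; repeated feedback of predictions gives
a recurrent multi-step forecast, and fourfold cross-validation with the full
metric suite quantifies out-of-sample accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import hebbian, som
from .decoder import decode
from .errors import (
    DegenerateInputError,
    ExtrapolationWarning,
    InvalidConfigError,
    InvalidInputError,
    NotTrainedError,
)
from .hebbian import HebbianMatrix
from .metrics import ErrorModel, fit_report
from .som import LearningSchedule, SOMPopulation

__all__ = [
    "PairedSeries",
    "TrainConfig",
    "TrainedModel",
    "normalize",
    "denormalize",
    "train",
    "infer",
    "predict_horizon",
    "cross_validate",
    "decode_relation",
    "last_value_predictions",
]

logger = logging.getLogger("relsom")


@dataclass
class PairedSeries:
    """Two aligned scalar sequences observed at common (irregular) stamps."""

    times: np.ndarray
    series_a: np.ndarray
    series_b: np.ndarray
    labels: tuple[str, str] = ("a", "b")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.series_a = np.asarray(self.series_a, dtype=float)
        self.series_b = np.asarray(self.series_b, dtype=float)
        n = self.times.size
        if n < 3:
            raise InvalidInputError(f"need at least 3 observations, got {n}")
        if self.series_a.size != n or self.series_b.size != n:
            raise InvalidInputError("times, series_a and series_b must have equal length")
        if np.any(np.diff(self.times) <= 0):
            i = int(np.flatnonzero(np.diff(self.times) <= 0)[0]) + 1
            raise InvalidInputError(f"times must be strictly increasing (violated at row {i})")
        for name, v in (("times", self.times), ("series_a", self.series_a), ("series_b", self.series_b)):
            if not np.all(np.isfinite(v)):
                raise InvalidInputError(f"non-finite value in {name}")

    def __len__(self) -> int:
        return self.times.size

    def subset(self, idx: np.ndarray) -> "PairedSeries":
        idx = np.sort(np.asarray(idx))
        return PairedSeries(self.times[idx], self.series_a[idx], self.series_b[idx], self.labels)


@dataclass
class TrainConfig:
    """Run-level constants for one training.

    The defaults follow the reference parametrization: N = 100 neurons per
    map, SOM learning rate decaying over [0.01, 0.1], Hebbian rate 0.9,
    neighborhood starting at N/2, all under an inverse-time law with
    timescale ``max_epochs / 2`` presented samples.
    """

    n_neurons: int = 100
    schedule: LearningSchedule | None = None
    epsilon: float = 1e-3
    max_epochs: int = 500
    seed: int = 42
    normalization: str = "minmax"
    projection_convention: str = "transpose"
    width_floor: float = som.DEFAULT_WIDTH_FLOOR

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise InvalidConfigError("n_neurons must be >= 2")
        if not self.epsilon > 0:
            raise InvalidConfigError("epsilon must be positive")
        if self.max_epochs < 1:
            raise InvalidConfigError("max_epochs must be >= 1")
        if self.normalization not in ("minmax", "maxdiv"):
            raise InvalidConfigError(f"unknown normalization {self.normalization!r}")
        if self.projection_convention not in hebbian.PROJECTION_CONVENTIONS:
            raise InvalidConfigError(
                f"unknown projection convention {self.projection_convention!r}"
            )
        if self.schedule is None:
            self.schedule = LearningSchedule(
                sigma_start=self.n_neurons / 2.0,
                decay_timescale=self.max_epochs / 2.0,
                epochs=self.max_epochs,
            )


@dataclass
class TrainedModel:
    """Both trained populations, the Hebbian link, and run provenance."""

    pop_a: SOMPopulation
    pop_b: SOMPopulation
    link: HebbianMatrix
    norm_bounds: dict
    history: list[float]
    config: TrainConfig
    converged: bool

    def __post_init__(self) -> None:
        if self.history and not (self.converged or len(self.history) >= self.config.max_epochs):
            raise InvalidConfigError("inconsistent training record")


def normalize(series, mode: str = "minmax"):
    """Map a series into [0, 1]; returns ``(normalized, bounds)``.

    ``minmax``: ``(x - min) / (max - min)``.  ``maxdiv``: ``x / max`` (the
    divide-by-maximum convention common in forecasting baselines; requires a
    positive maximum).
    """
    x = np.asarray(series, dtype=float)
    if mode == "minmax":
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi == lo:
            raise DegenerateInputError("constant series cannot be min-max normalized")
        return (x - lo) / (hi - lo), (lo, hi)
    if mode == "maxdiv":
        hi = float(np.max(x))
        if hi <= 0:
            raise DegenerateInputError("maxdiv normalization needs a positive maximum")
        return x / hi, (0.0, hi)
    raise InvalidConfigError(f"unknown normalization {mode!r}")


def denormalize(x, bounds, mode: str = "minmax"):
    lo, hi = bounds
    if mode == "minmax":
        return np.asarray(x) * (hi - lo) + lo
    if mode == "maxdiv":
        return np.asarray(x) * hi
    raise InvalidConfigError(f"unknown normalization {mode!r}")


def _weight_state(pop_a, pop_b, link) -> np.ndarray:
    return np.concatenate(
        [
            pop_a.preferred_values,
            pop_a.tuning_widths,
            pop_b.preferred_values,
            pop_b.tuning_widths,
            link.weights.ravel(),
        ]
    )


def train(data: PairedSeries, cfg: TrainConfig | None = None) -> TrainedModel:
    """Learn both encodings and the cross-population relation from one series pair.

    Per presented sample: activate both maps, pick winners, adapt centers and
    widths under the decaying neighborhood, advance the momentum traces, and
    apply the centered Hebbian update.  Epochs shuffle presentation order
    with the run seed.  The run stops when the epoch-level relative change of
    the concatenated weight state (both maps plus the link) drops to
    ``cfg.epsilon``, or when ``max_epochs`` is exhausted (a warning is logged
    and the model is returned with ``converged=False``).
    """
    cfg = cfg or TrainConfig()
    sched = cfg.schedule
    sa, bounds_a = normalize(data.series_a, cfg.normalization)
    sb, bounds_b = normalize(data.series_b, cfg.normalization)
    pop_a = SOMPopulation.initialize(cfg.n_neurons, float(sa.min()), float(sa.max()))
    pop_b = SOMPopulation.initialize(cfg.n_neurons, float(sb.min()), float(sb.max()))
    link = HebbianMatrix.zeros(cfg.n_neurons)
    rng = np.random.default_rng(cfg.seed)
    n = len(data)
    history: list[float] = []
    converged = False
    k = 0
    prev_state = _weight_state(pop_a, pop_b, link)
    for epoch in range(cfg.max_epochs):
        for i in rng.permutation(n):
            alpha, sigma, eta, beta = som.schedule_at(sched, k)
            sigma = max(sigma, 1e-6)
            a_a = som.activate(pop_a, sa[i])
            a_b = som.activate(pop_b, sb[i])
            som.adapt(pop_a, sa[i], som.winner(a_a), sigma, alpha, cfg.width_floor, inplace=True)
            som.adapt(pop_b, sb[i], som.winner(a_b), sigma, alpha, cfg.width_floor, inplace=True)
            hebbian.update_traces(link, a_a, a_b, max(beta, 1e-6), inplace=True)
            hebbian.hebbian_update(link, a_a, a_b, max(eta, 1e-6), inplace=True)
            k += 1
        state = _weight_state(pop_a, pop_b, link)
        denom = np.linalg.norm(state)
        change = float(np.linalg.norm(state - prev_state) / denom) if denom > 0 else 0.0
        history.append(change)
        prev_state = state
        if change <= cfg.epsilon:
            converged = True
            logger.info("relaxed after %d epochs (change %.2e)", epoch + 1, change)
            break
    if not converged:
        logger.warning(
            "training exhausted %d epochs without relaxing below %.1e (last change %.2e)",
            cfg.max_epochs, cfg.epsilon, history[-1],
        )
    return TrainedModel(
        pop_a=pop_a,
        pop_b=pop_b,
        link=link,
        norm_bounds={"a": bounds_a, "b": bounds_b},
        history=history,
        config=cfg,
        converged=converged,
    )


def _check_trained(model: TrainedModel) -> None:
    if not model.link.is_trained:
        raise NotTrainedError("model link is untrained")


def infer(model: TrainedModel, x: float, direction: str = "a_to_b") -> float:
    """Recover the paired quantity for a single query value.

    Normalizes the query with the source series' bounds, encodes it, projects
    the activity pattern across the Hebbian matrix, decodes it in the target
    map, and denormalizes with the target series' bounds.  Queries more than
    10% of the learned range outside the bounds raise an
    ``ExtrapolationWarning`` (the value is still computed).
    """
    _check_trained(model)
    if direction == "a_to_b":
        src, dst, proj = "a", "b", "p_to_q"
        pop_src, pop_dst = model.pop_a, model.pop_b
    elif direction == "b_to_a":
        src, dst, proj = "b", "a", "q_to_p"
        pop_src, pop_dst = model.pop_b, model.pop_a
    else:
        raise InvalidInputError(f"unknown direction {direction!r}")
    mode = model.config.normalization
    lo, hi = model.norm_bounds[src]
    span = hi - lo
    if x < lo - 0.1 * span or x > hi + 0.1 * span:
        warnings.warn(
            f"query {x} lies outside the learned {src!r} bounds [{lo}, {hi}] by more than "
            "10% of the range",
            ExtrapolationWarning,
            stacklevel=2,
        )
    xn = float(normalize_value(x, model.norm_bounds[src], mode))
    a_src = som.activate(pop_src, xn)
    a_dst = hebbian.project(model.link, a_src, proj, model.config.projection_convention)
    yn = decode(pop_dst, a_dst).value
    return float(denormalize(yn, model.norm_bounds[dst], mode))


def normalize_value(x: float, bounds, mode: str = "minmax") -> float:
    """Normalize one query value with previously learned bounds."""
    lo, hi = bounds
    if mode == "minmax":
        return (float(x) - lo) / (hi - lo)
    if mode == "maxdiv":
        return float(x) / hi
    raise InvalidConfigError(f"unknown normalization {mode!r}")


def predict_horizon(model: TrainedModel, x0: float, steps: int, direction: str = "a_to_b") -> np.ndarray:
    """Recurrent forecast: feed each prediction back as the next query."""
    if steps < 1:
        raise InvalidConfigError("steps must be >= 1")
    out = np.empty(steps)
    x = float(x0)
    for i in range(steps):
        x = infer(model, x, direction)
        out[i] = x
    return out


def decode_relation(model: TrainedModel, grid, direction: str = "a_to_b") -> pd.DataFrame:
    """Tabulate the learned relation ``x -> y_hat`` over a query grid.

    This is the human-readable output of the system: the hidden function
    encoded in the Hebbian matrix, read out point by point.
    """
    _check_trained(model)
    grid = np.asarray(grid, dtype=float)
    ys = np.array([infer(model, float(x), direction) for x in grid])
    return pd.DataFrame({"x": grid, "y": ys})


def _fold_indices(n: int, folds: int, mode: str) -> list[np.ndarray]:
    if mode == "interleaved":
        return [np.arange(n)[np.arange(n) % folds == f] for f in range(folds)]
    if mode == "blocked":
        return [np.array(ix) for ix in np.array_split(np.arange(n), folds)]
    raise InvalidConfigError(f"unknown fold mode {mode!r}")


def cross_validate(
    data: PairedSeries,
    cfg: TrainConfig | None = None,
    folds: int = 4,
    fold_mode: str = "interleaved",
    direction: str = "a_to_b",
    em: ErrorModel | None = None,
    n_params: int = 2,
    weighting: str = "error_model",
) -> pd.DataFrame:
    """Fourfold (by default) cross-validation with the full metric suite.

    Points are assigned to folds interleaved (point ``i`` to fold
    ``i mod folds``) so every fold spans the whole observation window of
    these short ordered series; ``blocked`` contiguous folds are available as
    an alternative.  Returns a DataFrame with one row per fold plus a
    ``"mean"`` row averaging the per-fold metrics.
    """
    if folds < 2:
        raise InvalidConfigError("folds must be >= 2")
    if folds > len(data):
        raise InvalidConfigError(f"folds ({folds}) exceed series length ({len(data)})")
    cfg = cfg or TrainConfig()
    em = em or ErrorModel()
    rows = []
    for f, held in enumerate(_fold_indices(len(data), folds, fold_mode)):
        train_idx = np.setdiff1d(np.arange(len(data)), held)
        model = train(data.subset(train_idx), cfg)
        x = data.series_a[held] if direction == "a_to_b" else data.series_b[held]
        y = data.series_b[held] if direction == "a_to_b" else data.series_a[held]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            y_hat = np.array([infer(model, float(v), direction) for v in x])
        p = min(n_params, held.size - 1)
        rep = fit_report(y, y_hat, em, p=p, weighting=weighting)
        rows.append(
            {"fold": f, "n_obs": rep.n_obs, "sse": rep.sse, "rmse": rep.rmse,
             "smape": rep.smape, "aic": rep.aic, "bic": rep.bic}
        )
    df = pd.DataFrame(rows).set_index("fold")
    df.loc["mean"] = df.mean(axis=0)
    return df


def last_value_predictions(series: np.ndarray, held: np.ndarray) -> np.ndarray:
    """Naive one-step-ahead baseline: carry the previous observation forward.

    For each held-out index ``i > 0`` the prediction is ``series[i - 1]``;
    index 0 has no predecessor and predicts itself (a conservative choice
    that favors the baseline).
    """
    series = np.asarray(series, dtype=float)
    held = np.asarray(held)
    return np.array([series[i - 1] if i > 0 else series[0] for i in held])
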