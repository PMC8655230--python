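"""Evaluation suite for tumor-growth relation learning.

Residuals are weighted by a size-dependent measurement-error model: the
standard deviation of a tumor-size measurement grows subproportionally with
the size, ``sigma_i = sigma * max(y, y_m)^alpha`` (the larger of observation
and prediction sets the scale, so overestimation is penalized against the
predicted size and underestimation against the measured one).  The defaults
``alpha = 0.84`` and ``sigma = 0.21`` are a calibrated trade-off for
volumetric tumor measurements.

On top of that the module provides the standard goodness-of-fit and parsimony
indices — SSE, RMSE, sMAPE, AIC, BIC — and a small report/ranking writer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ShapeError

__all__ = [
    "ErrorModel",
    "FitReport",
    "sigma_i",
    "sse",
    "rmse",
    "smape",
    "aic_bic",
    "fit_report",
    "rank_systems",
]


@dataclass(frozen=True)
class ErrorModel:
    """Size-dependent measurement noise ``sd = sigma_scale * size^alpha_exp``."""

    alpha_exp: float = 0.84
    sigma_scale: float = 0.21

    def __post_init__(self) -> None:
        if not 0 < self.alpha_exp <= 1:
            raise InvalidInputError(f"alpha_exp must lie in (0, 1], got {self.alpha_exp}")
        if self.sigma_scale < 0:
            # 0 is allowed so the model can also serve as a no-noise generator
            raise InvalidInputError(f"sigma_scale must be non-negative, got {self.sigma_scale}")


@dataclass(frozen=True)
class FitReport:
    """One row of an evaluation table (immutable once emitted)."""

    n_obs: int
    n_params: int
    sse: float
    rmse: float
    smape: float
    aic: float
    bic: float


def _pair(y, y_m) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    y_m = np.asarray(y_m, dtype=float).ravel()
    if y.shape != y_m.shape:
        raise ShapeError(f"length mismatch: {y.size} observations vs {y_m.size} predictions")
    if y.size == 0:
        raise InvalidInputError("empty input")
    return y, y_m


def sigma_i(y, y_m, em: ErrorModel = ErrorModel()) -> np.ndarray | float:
    """Per-point error sd: ``sigma * y_m^alpha`` when overestimating (y_m >= y),
    ``sigma * y^alpha`` when underestimating.  Both branches coincide at y = y_m."""
    scalar = np.isscalar(y) and np.isscalar(y_m)
    y, y_m = _pair(y, y_m)
    if np.any(y < 0) or np.any(y_m < 0):
        raise InvalidInputError("tumor sizes must be non-negative")
    if np.any((y == 0) & (y_m == 0)):
        raise InvalidInputError("y and y_m must not both be zero at the same point")
    out = em.sigma_scale * np.where(y_m >= y, y_m, y) ** em.alpha_exp
    return float(out[0]) if scalar else out


def sse(y, y_m, em: ErrorModel = ErrorModel(), weighting: str = "error_model") -> float:
    """Sum of squared errors.

    ``error_model`` (default): ``sum(((y - y_m) / sigma_i)^2) * sigma^2`` —
    weighted least squares under the measurement-error model, rescaled by the
    global noise scale so a perfect fit is 0 and units stay comparable with
    the plain form.  ``plain``: unweighted ``sum((y - y_m)^2)``.
    """
    y, y_m = _pair(y, y_m)
    if weighting == "plain":
        return float(np.sum((y - y_m) ** 2))
    if weighting != "error_model":
        raise InvalidInputError(f"unknown SSE weighting {weighting!r}")
    resid = y - y_m
    out = np.zeros_like(resid)
    nz = resid != 0.0
    if np.any(nz):
        s = sigma_i(y[nz], y_m[nz], em)
        out[nz] = (resid[nz] / s) ** 2 * em.sigma_scale**2
    return float(np.sum(out))


def rmse(y, y_m, em: ErrorModel = ErrorModel(), p: int = 2, weighting: str = "error_model") -> float:
    """Root mean squared error ``sqrt(SSE / (N - p))`` with p fitted parameters."""
    y, y_m = _pair(y, y_m)
    if y.size <= p:
        raise InvalidInputError(f"need more observations ({y.size}) than parameters ({p})")
    return float(math.sqrt(sse(y, y_m, em, weighting) / (y.size - p)))


def smape(y, y_m) -> float:
    """Symmetric mean absolute percentage error, bounded in [0, 2]:
    ``mean(2 |y - y_m| / (|y| + |y_m|))``."""
    y, y_m = _pair(y, y_m)
    denom = np.abs(y) + np.abs(y_m)
    bad = np.flatnonzero(denom == 0)
    if bad.size:
        raise InvalidInputError(f"|y| + |y_m| is zero at index {bad[0]}")
    return float(np.mean(2.0 * np.abs(y - y_m) / denom))


def aic_bic(sse_value: float, n: int, p: int) -> tuple[float, float]:
    """Information criteria from a least-squares fit:
    ``AIC = N ln(SSE/N) + 2p``, ``BIC = N ln(SSE/N) + ln(N) p``.

    A perfect fit (SSE = 0) would give -inf; the NaN sentinel is returned
    instead so downstream tables stay finite-checkable.
    """
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    if sse_value < 0:
        raise InvalidInputError(f"SSE must be non-negative, got {sse_value}")
    if sse_value == 0:
        return (math.nan, math.nan)
    core = n * math.log(sse_value / n)
    return (core + 2.0 * p, core + math.log(n) * p)


def fit_report(y, y_m, em: ErrorModel = ErrorModel(), p: int = 2, weighting: str = "error_model") -> FitReport:
    """Assemble the full metric row (SSE, RMSE, sMAPE, AIC, BIC) in one pass."""
    y, y_m = _pair(y, y_m)
    s = sse(y, y_m, em, weighting)
    aic, bic = aic_bic(s, y.size, p)
    return FitReport(
        n_obs=int(y.size),
        n_params=int(p),
        sse=s,
        rmse=rmse(y, y_m, em, p, weighting),
        smape=smape(y, y_m),
        aic=aic,
        bic=bic,
    )


def rank_systems(table: pd.DataFrame) -> pd.Series:
    """Rank competing systems: a system leads when it is best (minimal) in at
    least ``ceil(m/2)`` of the ``m`` metric columns; ties and the remaining
    order are resolved by the average per-metric rank.

    ``table`` has one row per system and one (lower-is-better) column per
    metric; returns integer ranks (1 = best) indexed like ``table``.
    """
    if table.empty:
        raise InvalidInputError("empty ranking table")
    per_metric = table.rank(axis=0, method="min")
    wins = (per_metric == 1).sum(axis=1)
    majority = math.ceil(table.shape[1] / 2)
    order = pd.DataFrame(
        {"lead": -(wins >= majority).astype(int), "mean_rank": per_metric.mean(axis=1)}
    ).sort_values(["lead", "mean_rank"]).index
    return pd.Series(np.arange(1, len(order) + 1), index=order, name="Rank").reindex(table.index)
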