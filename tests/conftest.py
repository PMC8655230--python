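"""Shared fixtures: cached trained reference models and ground-truth helpers.

Training the N = 100 reference models is the expensive part of the suite, so
each relation (identity, cubic, logistic, DCIS) is trained once per session
and shared by every test that needs it.
"""

from __future__ import annotations

import functools

import numpy as np
import pytest

import relsom as rs

REFERENCE_SEED = 7


def reference_config(**overrides) -> rs.TrainConfig:
    kw = dict(seed=REFERENCE_SEED, epsilon=1e-4, max_epochs=1500)
    kw.update(overrides)
    return rs.TrainConfig(**kw)


def _identity_series(n: int = 300) -> rs.PairedSeries:
    x = np.linspace(0.0, 1.0, n)
    return rs.PairedSeries(times=np.arange(1.0, n + 1.0), series_a=x, series_b=x)


@functools.lru_cache(maxsize=None)
def reference_model(kind: str):
    """Train (once per session) the N=100 model for a named noiseless relation.

    Returns ``(model, series)``; the exact generating law is available via
    :func:`ground_truth`.
    """
    if kind == "identity":
        data = _identity_series()
    elif kind in ("cubic", "logistic"):
        data = rs.growth_curve(rs.GrowthSpec(law=kind, seed=3))
    elif kind == "dcis":
        data = rs.dcis_relation_series(300, seed=3)
    else:
        raise ValueError(kind)
    return rs.train(data, reference_config()), data


def ground_truth(kind: str, x: np.ndarray) -> np.ndarray:
    """Exact value of the generating law at query points ``x`` (input units)."""
    if kind == "identity":
        return np.asarray(x, dtype=float)
    if kind in ("cubic", "logistic"):
        return rs.growth_law_value(rs.GrowthSpec(law=kind, seed=3), x)
    if kind == "dcis":
        return rs.dcis_A(1.0, np.asarray(x, dtype=float))
    raise ValueError(kind)


def normalized_relation_rmse(kind: str, n_grid: int = 50) -> float:
    """RMSE (in normalized target units) of the decoded relation vs the law."""
    model, data = reference_model(kind)
    xs = np.linspace(data.series_a.min(), data.series_a.max(), n_grid)
    rel = rs.decode_relation(model, xs)
    lo, hi = model.norm_bounds["b"]
    err = (rel["y"].to_numpy() - ground_truth(kind, xs)) / (hi - lo)
    return float(np.sqrt(np.mean(err**2)))


@pytest.fixture(scope="session")
def identity_model():
    return reference_model("identity")[0]


@functools.lru_cache(maxsize=None)
def small_model(relation: str = "identity"):
    """A fast 40-neuron model on 120 points for unit-level behavior tests."""
    x = np.linspace(0.0, 1.0, 120)
    y = x if relation == "identity" else 1.0 - x
    data = rs.PairedSeries(np.arange(1.0, 121.0), x, y)
    return rs.train(data, reference_config(n_neurons=40, max_epochs=400))


@pytest.fixture(scope="session")
def small_identity_model():
    return small_model("identity")
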