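"""Cross-population Hebbian correlation matrix.

The two population codes are linked all-to-all by an ``N x N`` weight matrix
learned with a covariance (centered Hebbian) rule: each weight grows when the
two neurons' activities co-fluctuate above their running averages and shrinks
when they are anticorrelated.  After training, the ridge of the matrix — the
column of maximal weight in each row — is a human-readable picture of the
hidden function relating the two encoded quantities, and projecting an
activity pattern through the matrix transfers evidence about one quantity
into the other population's code.

Conventions: ``weights[i, j]`` couples neuron ``i`` of population *p* (rows)
with neuron ``j`` of population *q* (columns), so the forward projection
q -> p is the plain matrix-vector product ``W @ a_q``.  For the reverse
projection p -> q two conventions are provided: the mathematically standard
``transpose`` (default) and the literal ``rot90`` clockwise rotation
``W'[i, j] = W[N - 1 - j, i]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, NotTrainedError, ShapeError

__all__ = ["HebbianMatrix", "update_traces", "hebbian_update", "project", "ridge"]

PROJECTION_CONVENTIONS = ("transpose", "rot90")


@dataclass
class HebbianMatrix:
    """Cross-population weights plus momentum-averaged activity traces.

    Attributes
    ----------
    weights : ndarray, shape (N_p, N_q)
        Correlation weights; start at zero (an all-zero matrix is the
        detectable "untrained" state) and may go negative for anticorrelated
        neuron pairs.  No normalization or clipping is applied.
    trace_p, trace_q : ndarray
        Exponential moving averages of the two populations' activations.
    """

    weights: np.ndarray
    trace_p: np.ndarray
    trace_q: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.trace_p = np.asarray(self.trace_p, dtype=float)
        self.trace_q = np.asarray(self.trace_q, dtype=float)
        if self.weights.ndim != 2:
            raise ShapeError("weights must be a matrix")
        if self.weights.shape != (self.trace_p.size, self.trace_q.size):
            raise ShapeError(
                f"weights shape {self.weights.shape} does not match traces "
                f"({self.trace_p.size}, {self.trace_q.size})"
            )
        if not np.all(np.isfinite(self.weights)):
            raise InvalidInputError("non-finite Hebbian weight")

    @classmethod
    def zeros(cls, n_p: int, n_q: int | None = None) -> "HebbianMatrix":
        n_q = n_p if n_q is None else n_q
        return cls(np.zeros((n_p, n_q)), np.zeros(n_p), np.zeros(n_q))

    @property
    def is_trained(self) -> bool:
        return bool(np.any(self.weights != 0.0))

    def copy(self) -> "HebbianMatrix":
        return HebbianMatrix(self.weights.copy(), self.trace_p.copy(), self.trace_q.copy())


def _check_lengths(hm: HebbianMatrix, a_p: np.ndarray, a_q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a_p = np.asarray(a_p, dtype=float)
    a_q = np.asarray(a_q, dtype=float)
    if a_p.shape != hm.trace_p.shape or a_q.shape != hm.trace_q.shape:
        raise ShapeError(
            f"activation lengths ({a_p.size}, {a_q.size}) do not match matrix "
            f"({hm.trace_p.size}, {hm.trace_q.size})"
        )
    return a_p, a_q


def update_traces(
    hm: HebbianMatrix,
    a_p: np.ndarray,
    a_q: np.ndarray,
    beta: float,
    inplace: bool = False,
) -> HebbianMatrix:
    """Momentum update ``abar(k) = (1 - beta) abar(k-1) + beta a(k)`` for both traces."""
    if not 0 < beta <= 1:
        raise InvalidInputError(f"beta must lie in (0, 1], got {beta}")
    a_p, a_q = _check_lengths(hm, a_p, a_q)
    out = hm if inplace else hm.copy()
    out.trace_p *= 1.0 - beta
    out.trace_p += beta * a_p
    out.trace_q *= 1.0 - beta
    out.trace_q += beta * a_q
    return out


def hebbian_update(
    hm: HebbianMatrix,
    a_p: np.ndarray,
    a_q: np.ndarray,
    eta: float,
    inplace: bool = False,
) -> HebbianMatrix:
    """Covariance rule ``dW = eta * outer(a_p - abar_p, a_q - abar_q)``.

    Assumes the traces have already been advanced to the current step.
    Correlated deviations strengthen a weight; anticorrelated ones weaken it.
    """
    if not 0 < eta <= 1:
        raise InvalidInputError(f"eta must lie in (0, 1], got {eta}")
    a_p, a_q = _check_lengths(hm, a_p, a_q)
    out = hm if inplace else hm.copy()
    out.weights += eta * np.outer(a_p - out.trace_p, a_q - out.trace_q)
    return out


def reverse_weights(hm: HebbianMatrix, convention: str = "transpose") -> np.ndarray:
    """Weight matrix used for the p -> q projection under the chosen convention.

    ``transpose`` returns ``W.T``; ``rot90`` returns the clockwise rotation
    ``W'[i, j] = W[N - 1 - j, i]`` (the literal printed rule; only meaningful
    for square matrices).
    """
    if convention == "transpose":
        return hm.weights.T
    if convention == "rot90":
        if hm.weights.shape[0] != hm.weights.shape[1]:
            raise ShapeError("rot90 convention requires a square matrix")
        return np.rot90(hm.weights, k=-1)
    raise InvalidInputError(f"unknown projection convention {convention!r}")


def project(
    hm: HebbianMatrix,
    activation: np.ndarray,
    direction: str = "q_to_p",
    convention: str = "transpose",
) -> np.ndarray:
    """Transfer an activity pattern through the matrix to the paired population.

    ``q_to_p`` computes ``W @ a_q``; ``p_to_q`` uses the reverse matrix under
    ``convention``.  Linear in the activation.  Raises if the matrix is still
    all zeros (untrained).
    """
    if not hm.is_trained:
        raise NotTrainedError("Hebbian matrix is all zeros; train before projecting")
    a = np.asarray(activation, dtype=float)
    if direction == "q_to_p":
        if a.shape != hm.trace_q.shape:
            raise ShapeError(f"expected length {hm.trace_q.size}, got {a.size}")
        out = hm.weights @ a
    elif direction == "p_to_q":
        if a.shape != hm.trace_p.shape:
            raise ShapeError(f"expected length {hm.trace_p.size}, got {a.size}")
        out = reverse_weights(hm, convention) @ a
    else:
        raise InvalidInputError(f"unknown direction {direction!r}")
    if not np.all(np.isfinite(out)):
        raise InvalidInputError("projection produced non-finite values")
    return out


def ridge(hm: HebbianMatrix) -> np.ndarray:
    """Per-row argmax of the weights (ties to the lowest column index).

    The ridge is the learned relation read directly off the matrix: row ``i``
    of population p is most strongly tied to column ``ridge[i]`` of
    population q.
    """
    if not hm.is_trained:
        raise NotTrainedError("Hebbian matrix is all zeros; train before reading the ridge")
    return np.argmax(hm.weights, axis=1)
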