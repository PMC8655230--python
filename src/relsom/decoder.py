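"""Population-code decoding: activity pattern -> real-world scalar.

Two readouts are provided.  The fast closed-form readout inverts the winning
neuron's Gaussian tuning curve to get a displacement ``d`` from its preferred
value and applies a half-lattice sign rule (``decode_sign_rule``).  The
default high-accuracy readout (``decode``) brackets the winner between the
preferred values where the pattern falls below half its peak and minimizes,
with Brent's derivative-free bounded scalar method, the squared distance
between the normalized candidate response pattern and the normalized observed
pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import InvalidInputError, NotDecodableError, NumericFailureError
from .som import SOMPopulation, activate

__all__ = ["DecodeResult", "displacement", "decode", "decode_sign_rule"]


@dataclass(frozen=True)
class DecodeResult:
    """Decoded scalar plus the evidence used to produce it."""

    value: float
    winner_index: int
    displacement: float
    bound_lo: float
    bound_hi: float


def displacement(a_i: float, xi_i: float) -> float:
    """Distance from a neuron's preferred value implied by its activation.

    Analytic inverse of the Gaussian tuning curve:
    ``d = sqrt(max(0, -2 xi^2 ln(sqrt(2 pi) xi a)))``.  Returns 0 at (or,
    through the clamp, numerically above) the tuning-curve peak
    ``1 / (sqrt(2 pi) xi)``.
    """
    if not a_i > 0:
        raise InvalidInputError(f"activation must be positive, got {a_i}")
    if not xi_i > 0:
        raise InvalidInputError(f"tuning width must be positive, got {xi_i}")
    arg = -2.0 * xi_i**2 * np.log(np.sqrt(2.0 * np.pi) * xi_i * a_i)
    return float(np.sqrt(max(0.0, arg)))


def decode_sign_rule(pop: SOMPopulation, winner_index: int, d: float) -> float:
    """Half-lattice sign rule: add ``d`` in the upper half, subtract below.

    With 1-based lattice index ``i = winner_index + 1`` and ``N`` neurons:
    ``y = w_i + d`` if ``i >= N/2`` else ``w_i - d``.
    """
    if not 0 <= winner_index < pop.n_neurons:
        raise InvalidInputError(f"winner index {winner_index} out of range")
    if d < 0:
        raise InvalidInputError(f"displacement must be >= 0, got {d}")
    w = pop.preferred_values[winner_index]
    if winner_index + 1 >= pop.n_neurons / 2.0:
        return float(w + d)
    return float(w - d)


def _bracket(pop: SOMPopulation, a: np.ndarray, b: int) -> tuple[float, float]:
    """Self-learned bounds around the winner.

    Walk out from the winner to the nearest lattice sites where the pattern
    either drops below half its peak or starts rising again (i.e. leaves the
    winner's basin — projected patterns can be multi-lump, and the bracket
    must not swallow a neighboring lump); take their preferred values, or the
    immediate neighbors when neither condition is ever met.  At a lattice
    extreme the bracket is extended one inter-neuron spacing beyond the edge
    preferred value, so values compressed by residual map contraction stay
    reachable.
    """
    w = pop.preferred_values
    n = pop.n_neurons
    half = a[b] / 2.0
    lo_idx = b - 1 if b > 0 else b
    for i in range(b - 1, -1, -1):
        lo_idx = i
        if a[i] < half or a[i] > 1.02 * a[i + 1]:
            break
    hi_idx = b + 1 if b < n - 1 else b
    for i in range(b + 1, n):
        hi_idx = i
        if a[i] < half or a[i] > 1.02 * a[i - 1]:
            break
    lo, hi = float(w[lo_idx]), float(w[hi_idx])
    if b == 0:
        lo = float(w[0] - abs(w[1] - w[0]))
    if b == n - 1:
        hi = float(w[n - 1] + abs(w[n - 1] - w[n - 2]))
    if not hi > lo:  # collapsed map region; fall back to a symmetric bracket
        span = max(abs(w[-1] - w[0]) / n, 1e-9)
        lo, hi = float(w[b] - span), float(w[b] + span)
    return lo, hi


def decode(
    pop: SOMPopulation,
    a_proj: np.ndarray,
    xatol: float = 1e-6,
    maxiter: int = 200,
) -> DecodeResult:
    """Brent-refined readout of a (projected) activity pattern.

    Negative entries (possible after projecting through a matrix with
    anticorrelation weights) carry no positional evidence and are clipped to
    zero.  The decoded value minimizes, over the self-learned bracket,

        c(y) = sum_i (activate(pop, y)_i / ||.|| - a_proj_i / ||.||)^2

    where both patterns are scaled to unit Euclidean norm.
    """
    a = np.clip(np.asarray(a_proj, dtype=float), 0.0, None)
    if a.shape != (pop.n_neurons,):
        raise InvalidInputError(f"expected activation of length {pop.n_neurons}, got {a.size}")
    norm = np.linalg.norm(a)
    if not norm > 0:
        raise NotDecodableError("activity pattern has no positive entries")
    a /= norm
    b = int(np.argmax(a))
    lo, hi = _bracket(pop, a, b)

    def cost(y: float) -> float:
        v = activate(pop, y)
        v = v / np.linalg.norm(v)
        return float(np.sum((v - a) ** 2))

    # The cost can be multimodal inside the bracket (projected patterns are
    # lumpy); a coarse scan isolates the global basin and Brent refines it.
    coarse = np.linspace(lo, hi, 41)
    j = int(np.argmin([cost(y) for y in coarse]))
    b_lo, b_hi = coarse[max(j - 1, 0)], coarse[min(j + 1, 40)]
    res = minimize_scalar(
        cost, bounds=(b_lo, b_hi), method="bounded", options={"xatol": xatol, "maxiter": maxiter}
    )
    if not res.success or not np.isfinite(res.x):
        raise NumericFailureError(
            f"bounded Brent minimization failed on bracket [{lo}, {hi}]: {res.message}"
        )
    # A projected pattern carries an arbitrary overall scale, so the winner's
    # amplitude cannot be fed through the tuning-curve inverse; report the
    # realized displacement of the refined value from the winner instead.
    d = abs(float(res.x) - float(pop.preferred_values[b]))
    return DecodeResult(
        value=float(res.x),
        winner_index=b,
        displacement=d,
        bound_lo=lo,
        bound_hi=hi,
    )
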