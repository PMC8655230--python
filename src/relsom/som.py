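"""1-D self-organizing population code with adaptive Gaussian tuning curves.

A scalar quantity is encoded by a lattice of ``N`` neurons.  Neuron ``i``
carries a preferred value ``w_i`` (the input it responds to maximally) and a
tuning width ``xi_i``; its response to an input ``s`` is a Gaussian density

    a_i(s) = exp(-(s - w_i)^2 / (2 xi_i^2)) / (sqrt(2 pi) xi_i).

Learning combines competition (the most active neuron wins) with cooperation
(a Gaussian neighborhood kernel over lattice distance spreads the winner's
update), so that adjacent neurons specialize on adjacent regions of the input
space and the neuron density tracks the input density: frequently observed
regions end up covered by many narrowly tuned neurons, rare regions by few
broadly tuned ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigError, InvalidInputError, NumericFailureError

__all__ = [
    "SOMPopulation",
    "LearningSchedule",
    "activate",
    "winner",
    "neighborhood",
    "adapt",
    "schedule_at",
    "fit_som",
]

#: Minimum tuning width, as a fraction of the (normalized) data range.  The
#: activation diverges as xi -> 0, and the width update can transiently drive
#: xi negative on a far-off sample, so widths are floored after every update.
DEFAULT_WIDTH_FLOOR = 1e-3


@dataclass
class SOMPopulation:
    """A 1-D lattice of Gaussian-tuned neurons.

    Attributes
    ----------
    preferred_values : ndarray, shape (N,)
        Tuning-curve centers ``w_i`` in input units.
    tuning_widths : ndarray, shape (N,)
        Tuning-curve widths ``xi_i`` in input units; strictly positive.
    """

    preferred_values: np.ndarray
    tuning_widths: np.ndarray

    def __post_init__(self) -> None:
        self.preferred_values = np.asarray(self.preferred_values, dtype=float)
        self.tuning_widths = np.asarray(self.tuning_widths, dtype=float)
        if self.preferred_values.ndim != 1 or self.tuning_widths.ndim != 1:
            raise InvalidInputError("preferred values and widths must be 1-D vectors")
        if self.preferred_values.shape != self.tuning_widths.shape:
            raise InvalidInputError("preferred values and widths must have equal length")
        if self.n_neurons < 2:
            raise InvalidInputError("a population needs at least 2 neurons")
        bad = np.flatnonzero(~(self.tuning_widths > 0))
        if bad.size:
            raise InvalidInputError(f"non-positive tuning width at neuron index {bad[0]}")
        if not np.all(np.isfinite(self.preferred_values)):
            raise InvalidInputError("non-finite preferred value")

    @property
    def n_neurons(self) -> int:
        return self.preferred_values.size

    @property
    def lattice_positions(self) -> np.ndarray:
        """Integer lattice coordinates ``r_i`` = 0..N-1."""
        return np.arange(self.n_neurons)

    def copy(self) -> "SOMPopulation":
        return SOMPopulation(self.preferred_values.copy(), self.tuning_widths.copy())

    @classmethod
    def initialize(cls, n_neurons: int, lo: float, hi: float) -> "SOMPopulation":
        """Evenly spaced, twist-free start over the observed data range.

        Widths start at ``(hi - lo) / N`` so neighboring tuning curves overlap
        at initialization.
        """
        if n_neurons < 2:
            raise InvalidInputError("n_neurons must be >= 2")
        if not (np.isfinite(lo) and np.isfinite(hi)) or not hi > lo:
            raise InvalidInputError("initialization range must be finite with hi > lo")
        centers = np.linspace(lo, hi, n_neurons)
        widths = np.full(n_neurons, (hi - lo) / n_neurons)
        return cls(centers, widths)


@dataclass
class LearningSchedule:
    """Inverse-time decay schedules for all per-sample learning rates.

    Each rate follows ``x(k) = x_end + (x_start - x_end) / (1 + k / tau)``
    where ``k`` counts presented samples.  The neighborhood width sigma and the
    Hebbian rates eta, beta decay toward zero (``x_end = 0``); the SOM learning
    rate alpha decays to a floor ``alpha_end`` so the map keeps tracking late
    samples.

    Defaults follow the reference parametrization: alpha in [0.01, 0.1],
    eta = 0.9, sigma(0) = N/2 (set by the caller who knows N).
    """

    alpha_start: float = 0.1
    alpha_end: float = 0.01
    sigma_start: float = 50.0
    eta_start: float = 0.9
    beta_start: float = 0.9
    decay_timescale: float = 250.0
    epochs: int = 500

    def __post_init__(self) -> None:
        for name in ("alpha_start", "alpha_end", "eta_start", "beta_start"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InvalidConfigError(f"{name} must lie in (0, 1], got {v}")
        if self.alpha_end > self.alpha_start:
            raise InvalidConfigError("alpha_end must not exceed alpha_start")
        if self.sigma_start <= 0:
            raise InvalidConfigError("sigma_start must be positive")
        if self.decay_timescale <= 0:
            raise InvalidConfigError("decay_timescale must be positive")
        if self.epochs < 1:
            raise InvalidConfigError("epochs must be >= 1")


def activate(pop: SOMPopulation, s: float) -> np.ndarray:
    """Gaussian population response of every neuron to the scalar input ``s``.

    Returns the vector ``a`` with
    ``a_i = exp(-(s - w_i)^2 / (2 xi_i^2)) / (sqrt(2 pi) xi_i)``;
    all entries are finite and strictly positive.
    """
    s = float(s)
    if not np.isfinite(s):
        raise InvalidInputError(f"input value must be finite, got {s}")
    w, xi = pop.preferred_values, pop.tuning_widths
    a = np.exp(-((s - w) ** 2) / (2.0 * xi**2)) / (np.sqrt(2.0 * np.pi) * xi)
    return a


def winner(activation: np.ndarray) -> int:
    """Index of the most active neuron; ties break to the lowest index."""
    a = np.asarray(activation, dtype=float)
    if a.size == 0:
        raise InvalidInputError("activation vector is empty")
    if np.any(np.isnan(a)):
        raise InvalidInputError(f"NaN activation at index {int(np.flatnonzero(np.isnan(a))[0])}")
    return int(np.argmax(a))


def neighborhood(pop: SOMPopulation, b: int, sigma: float) -> np.ndarray:
    """Cooperation kernel ``h_{b,i} = exp(-(r_i - r_b)^2 / (2 sigma^2))``.

    ``sigma`` is in lattice units; the kernel is 1 at the winner ``b``,
    symmetric about it, and strictly decreasing with lattice distance.
    """
    if sigma <= 0:
        raise InvalidInputError(f"kernel width must be positive, got {sigma}")
    if not 0 <= b < pop.n_neurons:
        raise InvalidInputError(f"winner index {b} out of range [0, {pop.n_neurons})")
    d = pop.lattice_positions - b
    return np.exp(-(d.astype(float) ** 2) / (2.0 * sigma**2))


def adapt(
    pop: SOMPopulation,
    s: float,
    b: int,
    sigma: float,
    alpha: float,
    width_floor: float = DEFAULT_WIDTH_FLOOR,
    inplace: bool = False,
) -> SOMPopulation:
    """One competitive/cooperative update of centers and widths.

    Centers move toward the sample, widths track the local squared distance::

        dw_i  = alpha * h_{b,i} * (s - w_i)
        dxi_i = alpha * h_{b,i} * ((s - w_i)^2 - xi_i^2)

    Widths are floored at ``width_floor`` after the update (the raw rule can
    momentarily drive a width negative on a far-off sample).
    """
    if not 0 < alpha <= 1:
        raise InvalidInputError(f"learning rate must lie in (0, 1], got {alpha}")
    h = neighborhood(pop, b, sigma)
    target = pop if inplace else pop.copy()
    delta = s - target.preferred_values
    target.preferred_values += alpha * h * delta
    target.tuning_widths += alpha * h * (delta**2 - target.tuning_widths**2)
    np.maximum(target.tuning_widths, width_floor, out=target.tuning_widths)
    if not (
        np.all(np.isfinite(target.preferred_values))
        and np.all(np.isfinite(target.tuning_widths))
    ):
        raise NumericFailureError(
            f"non-finite population state after adapt(s={s}, b={b}, sigma={sigma}, alpha={alpha})"
        )
    return target


def schedule_at(sched: LearningSchedule, k: int) -> tuple[float, float, float, float]:
    """Evaluate ``(alpha, sigma, eta, beta)`` at presented-sample index ``k``.

    All four are non-increasing in ``k``; at ``k = 0`` the start values are
    returned exactly.
    """
    if k < 0:
        raise InvalidInputError(f"step index must be non-negative, got {k}")
    decay = 1.0 / (1.0 + k / sched.decay_timescale)
    alpha = sched.alpha_end + (sched.alpha_start - sched.alpha_end) * decay
    sigma = sched.sigma_start * decay
    eta = sched.eta_start * decay
    beta = sched.beta_start * decay
    return alpha, sigma, eta, beta


def fit_som(
    samples: np.ndarray,
    n_neurons: int,
    sched: LearningSchedule,
    seed: int,
    epochs: int = 1,
    width_floor: float = DEFAULT_WIDTH_FLOOR,
) -> SOMPopulation:
    """Train a single population on a 1-D sample set (presentation-shuffled).

    Convenience driver for studying the encoding in isolation (topographic
    order, density matching, width adaptation); the paired relation learner
    has its own training loop.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 2 or not np.all(np.isfinite(samples)):
        raise InvalidInputError("need >= 2 finite samples")
    lo, hi = samples.min(), samples.max()
    if not hi > lo:
        raise InvalidInputError("samples must not be constant")
    pop = SOMPopulation.initialize(n_neurons, lo, hi)
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(epochs):
        for s in samples[rng.permutation(samples.size)]:
            alpha, sigma, _, _ = schedule_at(sched, k)
            sigma = max(sigma, 1e-6)
            a = activate(pop, s)
            adapt(pop, s, winner(a), sigma, alpha, width_floor, inplace=True)
            k += 1
    return pop
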