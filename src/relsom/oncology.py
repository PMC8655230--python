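"""Synthetic oncology generators and their closed-form ground truths.

Everything the relation learner is exercised on can be generated here with a
seed: classic tumor growth laws sampled on irregular schedules (emulating
caliper/imaging follow-up series of 5-23 points at 1-7 measurements per
week), the ductal carcinoma in situ (DCIS) diffusion "master equation"
linking apoptosis-to-proliferation ratio A to tumor radius R and nutrient
penetration length L, the quiescent->proliferative / quiescent->apoptotic
phenotypic transition rates, a saturating intracellular drug-uptake curve,
and the size-dependent measurement-noise model reused as a noise generator.

Each generator is paired with the analytic law it samples, so tests and the
acceptance checks always have an exact ground truth to compare a learned
relation against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigError, InvalidInputError
from .learner import PairedSeries
from .metrics import ErrorModel

__all__ = [
    "GrowthSpec",
    "GROWTH_LAWS",
    "growth_law_value",
    "growth_curve",
    "dcis_A",
    "dcis_dataset",
    "dcis_relation_series",
    "phenotypic_rates",
    "pk_uptake",
    "apply_noise",
]


def _cubic(t: np.ndarray, p: dict) -> np.ndarray:
    return p["scale"] * t**3


def _power(t: np.ndarray, p: dict) -> np.ndarray:
    return p["scale"] * t ** p["exponent"]


def _exponential(t: np.ndarray, p: dict) -> np.ndarray:
    return p["v0"] * np.exp(p["rate"] * t)


def _logistic(t: np.ndarray, p: dict) -> np.ndarray:
    v0, cap, r = p["v0"], p["capacity"], p["rate"]
    return cap / (1.0 + (cap - v0) / v0 * np.exp(-r * t))


def _gompertz(t: np.ndarray, p: dict) -> np.ndarray:
    v0, cap, b = p["v0"], p["capacity"], p["rate"]
    return cap * np.exp(np.log(v0 / cap) * np.exp(-b * t))


GROWTH_LAWS = {
    "cubic": _cubic,
    "power": _power,
    "exponential": _exponential,
    "logistic": _logistic,
    "gompertz": _gompertz,
}


def _default_params(law: str, horizon: float) -> dict:
    """Coefficients chosen so each curve spans ~[0, 1] over the horizon."""
    h = horizon
    return {
        "cubic": {"scale": 1.0 / h**3},
        "power": {"scale": 1.0 / h**0.75, "exponent": 0.75},
        "exponential": {"v0": 1e-3, "rate": np.log(1e3) / h},
        "logistic": {"v0": 0.01, "capacity": 1.0, "rate": 10.0 / h},
        "gompertz": {"v0": 0.01, "capacity": 1.0, "rate": 6.0 / h},
    }[law]


@dataclass
class GrowthSpec:
    """Sampling plan for one synthetic tumor growth series.

    ``sampling_rate`` is in measurements/week (clinical follow-up densities
    run 1-7), ``horizon`` in weeks, and ``jitter`` perturbs each stamp by a
    uniform fraction of the inter-sample spacing (strict monotonicity is
    guaranteed for jitter < 0.5).
    """

    law: str = "cubic"
    params: dict = field(default_factory=dict)
    horizon: float = 150.0
    sampling_rate: float = 2.0
    jitter: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.law not in GROWTH_LAWS:
            raise InvalidConfigError(
                f"unknown growth law {self.law!r}; choose from {sorted(GROWTH_LAWS)}"
            )
        if not self.horizon > 0:
            raise InvalidConfigError("horizon must be positive")
        if not 1.0 <= self.sampling_rate <= 7.0:
            raise InvalidConfigError("sampling_rate must lie in [1, 7] per week")
        if not 0.0 <= self.jitter < 0.5:
            raise InvalidConfigError("jitter must lie in [0, 0.5)")
        merged = _default_params(self.law, self.horizon)
        merged.update(self.params)
        self.params = merged


def growth_law_value(spec: GrowthSpec, t) -> np.ndarray:
    """Exact value of the spec's growth law at time(s) ``t`` (the oracle)."""
    return GROWTH_LAWS[spec.law](np.asarray(t, dtype=float), spec.params)


def growth_curve(spec: GrowthSpec) -> PairedSeries:
    """Sample the growth law on an irregular schedule.

    Stamps sit on the grid ``i / rate`` for ``i = 1..round(horizon * rate)``,
    each perturbed by seeded uniform jitter; values are noiseless (apply
    ``apply_noise`` separately for the measurement-error model).
    """
    n = int(round(spec.horizon * spec.sampling_rate))
    if n < 2:
        raise InvalidConfigError("horizon * sampling_rate must give at least 2 points")
    dt = 1.0 / spec.sampling_rate
    times = dt * np.arange(1, n + 1)
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        times = times + rng.uniform(-spec.jitter, spec.jitter, size=n) * dt
    values = growth_law_value(spec, times)
    return PairedSeries(times=times, series_a=times, series_b=values,
                        labels=("time_weeks", spec.law))


def dcis_A(L, R):
    """Apoptosis-to-proliferation ratio of an in-situ ductal tumor.

    ``A = (3L/R) (1/tanh(R/L) - L/R)``: a spherical tumor of radius ``R`` fed
    by nutrient diffusing a penetration length ``L`` into the tissue balances
    proliferation at the rim against apoptosis in the core; A depends on the
    dimensionless ratio R/L only and falls from 1 (tiny tumor, fully
    nourished) toward 0 as the core outgrows the nutrient supply.

    Evaluated as ``3/rho (coth(rho) - 1/rho)``; for rho = R/L < 0.05 the
    direct form cancels catastrophically (coth(rho) ~ 1/rho), so the Taylor
    expansion ``1 - rho^2/15 + 2 rho^4/315 - rho^6/1575`` is used there
    (both branches agree to ~1e-12 at the switch).
    """
    L = np.asarray(L, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(L <= 0) or np.any(R <= 0):
        raise InvalidInputError("L and R must be positive")
    rho = R / L
    small = rho < 0.05
    safe = np.where(small, 1.0, rho)
    direct = 3.0 / safe * (1.0 / np.tanh(safe) - 1.0 / safe)
    taylor = 1.0 - rho**2 / 15.0 + 2.0 * rho**4 / 315.0 - rho**6 / 1575.0
    out = np.where(small, taylor, direct)
    return float(out) if out.ndim == 0 else out


def dcis_dataset(n: int, L_range=(0.05, 0.25), R_range=(0.1, 2.5), seed: int = 0):
    """Seeded table of (L, R, A) records with A computed exactly from the law.

    Default ranges are millimetre-scale: diffusion penetration lengths of
    0.05-0.25 mm and in-situ tumor radii of 0.1-2.5 mm.
    Returns a pandas DataFrame with columns L, R, A.
    """
    import pandas as pd

    if n < 1:
        raise InvalidInputError("n must be >= 1")
    for lo, hi in (L_range, R_range):
        if not (0 < lo < hi):
            raise InvalidConfigError("ranges must be positive with lo < hi")
    rng = np.random.default_rng(seed)
    L = rng.uniform(*L_range, size=n)
    R = rng.uniform(*R_range, size=n)
    return pd.DataFrame({"L": L, "R": R, "A": dcis_A(L, R)})


def dcis_relation_series(n: int = 300, ratio_range=(0.1, 20.0), seed: int = 0) -> PairedSeries:
    """The DCIS law as a learnable paired series: x = R/L, y = A(R/L).

    A depends on R and L only through their ratio, so sampling the ratio
    directly yields a clean one-dimensional relation for the learner.
    """
    lo, hi = ratio_range
    if not (0 < lo < hi):
        raise InvalidConfigError("ratio_range must be positive with lo < hi")
    rng = np.random.default_rng(seed)
    rho = np.sort(rng.uniform(lo, hi, size=n))
    return PairedSeries(times=rho, series_a=rho, series_b=dcis_A(1.0, rho),
                        labels=("radius_over_penetration", "apoptosis_to_proliferation"))


def phenotypic_rates(tau_P: float, tau_A: float, PI: float, AI: float) -> tuple[float, float]:
    """Quiescent->proliferative and quiescent->apoptotic transition rates.

    From cell cycle time ``tau_P``, apoptosis time ``tau_A``, proliferation
    index ``PI`` and apoptosis index ``AI`` (fractions of cells caught in
    each state):

        alpha_P = [ (PI + PI^2)/tau_P - AI*PI/tau_A ] / (1 - AI - PI)
        alpha_A = [ (AI - AI^2)/tau_A + AI*PI/tau_P ] / (1 - AI - PI)
    """
    if tau_P <= 0 or tau_A <= 0:
        raise InvalidInputError("cycle/apoptosis times must be positive")
    if PI < 0 or AI < 0:
        raise InvalidInputError("indices must be non-negative")
    denom = 1.0 - AI - PI
    if denom <= 0:
        raise InvalidInputError(f"AI + PI must be < 1, got {AI + PI}")
    alpha_P = ((PI + PI**2) / tau_P - AI * PI / tau_A) / denom
    alpha_A = ((AI - AI**2) / tau_A + AI * PI / tau_P) / denom
    return float(alpha_P), float(alpha_A)


@dataclass(frozen=True)
class PKParams:
    """Saturating-uptake coefficients (synthetic stand-in kinetics)."""

    plateau_max: float = 10.0  # uM, intracellular ceiling
    km: float = 1.0  # uM, half-saturation of plateau and rate
    k0: float = 2.0  # 1/h, uptake rate scale


def pk_uptake(extracellular_conc: float, times, params: PKParams = PKParams()) -> np.ndarray:
    """Intracellular drug concentration during uptake at fixed bath concentration.

    Synthetic single-compartment kinetics: ``C(t) = C_p (1 - exp(-k t))`` with
    plateau ``C_p = plateau_max * c_e / (c_e + km)`` and rate
    ``k = k0 * c_e / (c_e + km)``, both strictly increasing in the
    extracellular concentration ``c_e`` — hence the lowest bath concentration
    takes the longest (time to 95% plateau is ``3/k``) to level off.
    """
    c_e = float(extracellular_conc)
    if not c_e > 0:
        raise InvalidInputError("extracellular concentration must be positive")
    t = np.asarray(times, dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    sat = c_e / (c_e + params.km)
    return params.plateau_max * sat * (1.0 - np.exp(-params.k0 * sat * t))


def apply_noise(series, em: ErrorModel = ErrorModel(), seed: int = 0) -> np.ndarray:
    """Corrupt a non-negative series with the size-dependent error model.

    Adds seeded Gaussian noise of sd ``sigma_scale * y^alpha_exp`` per point
    and clamps the result at zero.
    """
    y = np.asarray(series, dtype=float)
    if np.any(y < 0):
        raise InvalidInputError("series must be non-negative")
    rng = np.random.default_rng(seed)
    noisy = y + rng.normal(0.0, 1.0, size=y.shape) * em.sigma_scale * y**em.alpha_exp
    return np.clip(noisy, 0.0, None)
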