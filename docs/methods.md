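# Methods

This note records the modeling assumptions behind `relsom`, the parameters
that matter and why their defaults are what they are, what the synthetic
generators do and do not emulate, and the numerical choices made where the
design was genuinely open.

## Model and assumptions

The system couples two one-dimensional self-organizing maps (SOMs) through a
Hebbian correlation matrix.  Its core assumptions:

- **Scalar, paired observations.** Both covariates are scalar and observed
  at the same (possibly irregular) stamps.  The relation to be learned is a
  function of one covariate against the other; multivalued relations are
  outside the model class (the ridge readout picks one branch).
- **Distributed population coding.** A value is represented by the whole
  activity pattern of a map, not a single unit.  Gaussian tuning curves with
  adaptive widths make the code smooth, so decoding can interpolate between
  the training samples — this is what lets models trained on 20-point
  clinical-length series answer queries at unseen inputs.
- **Correlation equals relation.** The cross-map weights are built from
  centered co-fluctuations (a covariance rule).  Because training presents
  the paired samples in shuffled order, the momentum traces approximate each
  map's mean activation, and the accumulated weights approximate the
  activation covariance; its row-wise ridge then traces y = f(x).  Negative
  weights (anticorrelation) are kept — they sharpen the projection — and no
  weight normalization or clipping is applied.
- **Stationarity.** The relation is assumed fixed over the observation
  window.  A treatment switch mid-series would be smeared into one relation.

## Parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| `n_neurons` (N) | 100 | — | neurons per map; decode quantization ~1/N of the range |
| `alpha_start/end` | 0.1 / 0.01 | — | SOM learning-rate decay bracket |
| `sigma_start` | N/2 | lattice units | initial cooperation radius |
| `eta_start` | 0.9 | — | Hebbian rate, decays toward 0 |
| `beta_start` | 0.9 | — | trace momentum, decays toward 0 |
| `decay_timescale` (τ) | max_epochs/2 | presented samples | inverse-time law x(k) = x_end + (x_start − x_end)/(1 + k/τ); σ, η, β use x_end = 0 |
| `epsilon` (Δε) | 1e-4 | relative | epoch-level relaxation threshold |
| `max_epochs` | 1500 | epochs | training budget |
| `width_floor` | 1e-3 | normalized range | lower bound on tuning widths |
| error model α, σ | 0.84, 0.21 | — | measurement sd = σ·size^α |

The step index k counts presented samples, matching the per-sample update
rules.  The relaxation measure is the relative Euclidean change, per epoch,
of the concatenated weight state (both maps' centers and widths plus the
Hebbian matrix).

**Why Δε = 1e-4 and 1500 epochs.** Tuning-width relaxation is the slowest
mode of the dynamics: once the neighborhood has shrunk, a width decays
roughly like Δ(1/ξ) ≈ α per win, so reaching the quantization scale from a
mid-training width takes thousands of presentations per neuron at the α
floor of 0.01.  Stopping at a looser threshold leaves widths several lattice
spacings wide, which smears the projected activity bumps and biases decoded
values toward the center of the range by ~4% — enough to break the
round-trip accuracy the decoder is otherwise capable of (max error ≲ 2/N on
an identity relation).  With these defaults training typically uses the full
budget and ends with the epoch change plateaued at the α-floor jitter level
(2–5 × 10⁻⁴); that is the intended relaxed state, reported honestly as
`converged=False` with a logged warning rather than masked.

**Initialization.** Centers start evenly spaced over the observed
(normalized) range and widths at range/N: a deterministic, twist-free start.
The Hebbian matrix and traces start at zero, which doubles as the detectable
"untrained" state.

## Decoding

The closed-form readout inverts the winner's tuning curve,
d = √(max(0, −2ξ² ln(√(2π) ξ a))), and applies the half-lattice sign rule
(add d in the upper half of the lattice, subtract in the lower).  The sign
rule is exposed verbatim (`decode_sign_rule`) but the default path refines
the estimate: the pattern is bracketed between the preferred values where it
falls below half its peak or leaves the winner's basin (starts rising again
— on sparsely trained models the projected pattern is multi-lump and an
unbounded half-max walk would swallow neighboring lumps), falling back to
the winner's immediate neighbors, and extending one inter-neuron spacing
beyond a lattice extreme so edge values compressed by residual map
contraction stay reachable.  Then the
squared distance between the unit-norm candidate activation pattern and the
unit-norm observed pattern is minimized over the bracket — a 41-point coarse
scan first isolates the global basin (projected patterns can make the cost
multimodal), then Brent's bounded derivative-free minimizer (SciPy's
`bounded` method; xatol 1e-6, ≤200 iterations) refines within it.  Projected
patterns carry an arbitrary overall scale, so their negative entries are
clipped and the amplitude is never interpreted through the tuning-curve
inverse.  A displacement formula sometimes quoted without the radical,
2ξ²log(2πaξ²), is dimensionally inconsistent with inverting the Gaussian
activation; the analytic inverse above is what reproduces encode→decode
self-consistency.

For the reverse projection two conventions exist: the matrix transpose
(default; the mathematically standard adjoint, making q→p and p→q exact
mirrors) and a literal clockwise rot90 (W'[i,j] = W[N−1−j, i]), selectable
via `projection_convention` for compatibility with descriptions that state
the rotation form.  Which is "intended" cannot be settled from the rotation
wording alone; both are provided and tested.

## Cross-validation and baselines

Folds are interleaved by default (point i → fold i mod k): on 5–23-point
ordered series, contiguous blocks would turn interpolation into
extrapolation and measure something else.  Blocked folds remain available
(`fold_mode="blocked"`).  The one-step-ahead comparison against
last-value-carried-forward excludes the first observation, where a
carry-forward prediction is undefined; `last_value_predictions` falls back
to predicting the first value itself if asked.  AIC/BIC at SSE = 0 return a
NaN sentinel rather than −∞.

The weighted SSE is Σ((yᵢ − y_mᵢ)/σᵢ)²·σ², i.e. residuals are measured in
units of the size-dependent measurement sd and rescaled by the global noise
scale; `weighting="plain"` gives the unweighted form for non-volumetric
series.

## Synthetic data: what it does and does not emulate

The generators reproduce the *shape* of clinical follow-up data — series of
5–23 points at 1–7 measurements/week, jittered stamps, size-dependent
multiplicative-like noise (additive Gaussian with sd σ·y^α, clamped at 0) —
and provide exact ground truth for five growth laws, the DCIS master
equation (a function of R/L only, so the paired series samples the ratio
directly), the phenotypic transition-rate law, and a saturating drug-uptake
curve.  Default growth coefficients scale each curve to ≈[0, 1] over its
horizon so normalized errors are comparable across laws.

The drug-uptake kinetics are a deliberately simple synthetic stand-in (one
saturating compartment with rate and plateau both increasing in the bath
concentration); they assert only the qualitative ordering that lower
extracellular concentration takes longer to plateau, not any published
compartment model's coefficients.

Passing tests on these generators demonstrates that the machinery recovers
known noiseless or mildly noisy relations of realistic shape and length.
They do not demonstrate performance on real cohorts: real series carry
serially correlated measurement error, treatment-induced regime changes,
and censoring, none of which are generated here.

## Numerical choices and degenerate inputs

- Winner ties break to the lowest index; ridge ties to the lowest column —
  determinism over symmetry.
- Widths are floored (default 1e-3 of the normalized range) after every
  update; the raw width rule can transiently drive ξ negative on a far-off
  sample and the activation diverges as ξ → 0.
- σ(k) in the training loop is floored at 1e-6 lattice units to keep the
  kernel defined arbitrarily late in training.
- The DCIS law switches to a three-term Taylor expansion
  1 − ρ²/15 + 2ρ⁴/315 − ρ⁶/1575 for ρ = R/L < 0.05, where the direct
  coth form loses ~8 digits to cancellation; the branches agree to ~1e-12
  at the switch.
- Constant series cannot be min–max normalized (raised as degenerate);
  `maxdiv` normalization requires a positive maximum.
- Queries beyond 10% of the learned range outside the bounds trigger an
  `ExtrapolationWarning` but still return a value (clamped into the decode
  bracket by construction).
- Model JSON stores floats via Python's shortest round-trip repr; CSV I/O
  uses %.17g and round-trip float parsing, so both are bit-exact.

## Problem sizes used in the checks

The acceptance script and system tests train N = 100 maps on 300-point
noiseless series for relation recovery (identity, cubic, logistic, DCIS),
run fourfold cross-validation on a 24-point Gompertz series (the upper end
of the clinical-length regime), fit standalone maps on 5,000-sample uniform
and 80/20 bimodal sets for the self-organization checks, and use 1,000-draw
randomized oracles for the closed-form primitives.  These sizes were chosen
to match the data regime the method targets while keeping a full run in the
minutes range on one CPU.

## Known limitations

- One relation per trained model; no multi-way (≥3 population) linking.
- 1-D lattices only; no batch SOM, growing maps, or 2-D/toroidal topologies.
- The decoded relation inherits SOM quantization: accuracy is bounded by
  ~1/N of the range, and edge neurons keep a small inward bias (the maps'
  neighborhood is asymmetric at the lattice boundary; activity saturates
  there).
- Training cost is O(epochs · samples · N²) in time; the per-sample Hebbian
  outer product dominates.
- Recurrent multi-step forecasting compounds decode error; it is faithful
  to the learned relation, not a calibrated forecaster.
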