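# Methods

## Model

Each neuron's spike train on repeated trials of length `T` is a point
process with conditional intensity

```
log λ(t | H_t, X_t) = f1(t) + f2(t − t*) + f3(Φ_t)
```

- `f1(t)`: trial-locked stimulus (PSTH) effect, cubic B-splines over `[0, T]`
  (10 knots by default).
- `f2(τ)`, `τ = t − t*`: effect of the time since the neuron's own most
  recent spike, cubic B-splines on log-spaced knots over `(1 ms, 200 ms]`
  (8 knots).  Beyond the last knot the curve extrapolates as a constant
  (the recovered plateau); bins before a trial's first spike carry history
  multiplier 1.
- `f3(φ)`: oscillation-phase effect on a circular-spline basis — truncated
  cosine series `r_k(φ) = Σ_{m=1..4} w_m cos(m(φ − φ_k))` around 6 equally
  spaced knots on `[−π, π]`.  The printed series weight `w_m = 2/(2πm)^4`
  makes the raw basis functions ~10⁻³ in amplitude, so `BasisSet` rescales
  them to unit peak (a pure reparameterization) to keep the ridge penalty
  comparable across blocks.  The literal cosine argument `2πm(φ − φ_k)` has
  period 1 in radian phase; the package defaults to the 2π-periodic
  convention `m(φ − φ_k)` and retains the literal form behind
  `convention="literal"`.

The *reduced* model omits `f3` and is fitted by the same code path without
ever touching phase inputs.

## Likelihood and fitting

Trials are binned at Δ = 1 ms; with at most one spike per bin the
log likelihood is `L = Σ_k [y_k log p_k − p_k]`, `p_k = λ(t_k|·)Δ`
(Poisson approximation to the Bernoulli bin).  Fitting minimizes
`Q = −L + (penalty/2)·Θᵀ P Θ` by back-fitting: cyclic Newton/IRLS updates of
the stimulus, history and phase coefficient blocks (order `α → β → γ`, up to
3 guarded Newton steps per block per cycle, step halving so accepted steps
never increase `Q`), stopping when `|Q₁ − Q₀| ≤ 10⁻⁶` across a cycle
(max 100 cycles; the convergence flag is honest and non-convergence warns).
A singular block Hessian receives a small ridge bump.

**Penalty.**  The default ridge weight is 1.0 on all blocks, with the
constant direction of the stimulus and history blocks projected out
(`P = I − J/p`).  Those constants set the overall firing-rate level and the
arbitrary split of a constant between `f1` and `f2`; shrinking them drags
the fitted rate toward 1 Hz (0 on the log scale) and couples the penalty to
the gauge, which measurably distorted trial-onset rates and inflated
synchrony predictions by several percent in our calibration runs.  The
fully penalized objective is available via `unpenalized_intercept=False`.
The circular basis contains no constant (its columns integrate to zero over
the circle), so the phase block is penalized in full; the all-ones γ
direction maps to the zero function and is harmlessly shrunk to zero.

**Identifiability.**  The multiplicative form is invariant to moving
constants between terms.  During fitting the gauge is pinned by the
convention `f2 = 0` at the end of the history span, which makes the model
internally consistent (no-history bins ≡ long-lag bins).  After
convergence the canonical normalization is applied once:
`mean(exp f2) = 1` over the history span and `(1/2π)∫ exp(f3) dφ = 1`
(trapezoid rule, 1000 points), with the constants absorbed into `f1` —
exactly (to machine precision) via the B-spline partition of unity for the
stimulus and history blocks, and via an explicit scalar offset for the
phase term.  The renormalization leaves the intensity unchanged at every
bin where the history term is active; the handful of bins before a trial's
first spike (multiplier fixed at 1) can shift by the small history
constant, a deliberate trade-off documented here because no normalization
of an undefined lag exists.

**Initialization.**  `α` from a least-squares projection of the smoothed
log-PSTH (floored at 0.1 Hz); `β = γ = 0`.  Bootstrap refits warm-start
from the data fit.

**Uncertainty and fit checks.**  Pointwise 95% confidence bands come from a
parametric bootstrap: simulate from the fitted model conditioned on the
observed phase series, refit, take 2.5/97.5 percentiles per curve
(non-convergent refits are dropped with a warning; >10% dropped is an
error).  Goodness of fit uses time rescaling: transformed inter-spike
intervals `z = 1 − exp(−∫λ̂)` tested against uniformity by
Kolmogorov–Smirnov.

## Synchrony ratio and test

`N_pred = Σ_trials Σ_{δ-bins} [∫_bin λ̂_A dt][∫_bin λ̂_B dt]` with δ = 5 ms,
the inner integrals accumulated from the 1 ms grid and conditioned on each
neuron's own observed history and the shared phase series.  Three counting
conventions for `N_obs` are implemented:

- `pairs` (default): per δ-bin, `count_A · count_B`.  Under conditional
  independence `E[N_obs] = N_pred` exactly, so `log ζ = 0` holds without
  finite-rate corrections.
- `binned`: per δ-bin, `min(count_A, count_B)` (matched pairs).  At 25 Hz
  and δ = 5 ms this undercounts multi-spike bins by ~3% relative to
  `N_pred` (measured), a small negative offset in `log ζ̂` that the
  bootstrap test automatically calibrates away.
- `interval`: greedy matching of spike pairs closer than δ, each spike used
  once.

All three agree when no δ-bin holds two spikes of one neuron.
Injection-based analyses (the power pipeline, injected-ζ recovery) use
`binned`, because injected synchronous events are matched pairs by
construction and `E[ζ̂] = ζ` is exact under that pairing.

The bootstrap test simulates `G = 400` conditionally independent
pair-datasets from the fitted models (no refit per replicate — the draws
measure count and history variability around the fitted intensities),
computes `log ζ_i` for each with the same counting convention, and reports
`p = #{|log ζ_i| > |log ζ̂|}/G`, the draw standard deviation as the SE, and
a normal-theory 95% CI.  The smallest attainable nonzero p is `1/G`.

## Spike-phase-histogram bias

With constant stimulus `C`, history multiplier `λ2` and phase modulation
`λ3` under an oscillation of frequency `f`, the phase at one spike given
the phase at the previous spike has density obtained from the waiting-time
density `f(t) = λ(t) exp(−∫λ)` summed over the lag set
`{(φ − φ0)/ω + k/f}`, `ω = 2πf`.  Discretizing phase into `m = 64` bins
gives a column-stochastic transition matrix `A` (entries computed as CDF
differences over each phase bin and cycle, with the cycle sum truncated
when the survival probability falls below 10⁻⁸ — so columns sum to 1 up to
that truncation).  The stationary spike-phase distribution is the
eigenvector of `A` with eigenvalue 1 (the extraction takes the eigenvalue
nearest 1, errors if it deviates by more than 10⁻⁴, clips the eigenvector
at 0 and renormalizes).  For Poisson firing (`λ2 ≡ 1`) the stationary
distribution is exactly `λ3(φ)/2π`; with refractoriness it deviates in a
rate-dependent way — the histogram's bias.  The MISE comparison
(`compare_estimators`) quantifies this: integrated squared error of
histogram vs GLM estimates of `λ3` across sample sizes, with the
variance / squared-bias split about the pointwise mean curve, and the
histogram bin count chosen to minimize MISE over a candidate grid.

## Simulators

Generation is discrete-time Bernoulli at Δ = 1 ms, exactly matching the
fitting likelihood: at each bin the hazard is
`λ1(t_k)·λ3(Φ_k)·λ2((j−½)Δ)` with `j` the integer lag to the last generated
spike; spikes are placed at bin centers so rebinned lags reproduce the
generation lags.  The hot loop is JIT-compiled (numba) with uniforms
pre-drawn from a seeded numpy Generator; identical spec + seed gives
byte-identical spike trains.  An Ogata-thinning continuous-time generator
cross-checks the discretization.  Validity guard: `λ_max·Δ ≥ 1` is an
error, `≥ 0.2` a warning.

Oscillations are linear phase ramps `wrap(φ0 + 2πft)` with a fresh uniform
initial phase per trial (or fixed φ0), shared across a neuron pair when a
common drive is wanted.

**Synchrony injection.**  To impose coefficient ζ on an independent pair:
per δ-bin, remove existing coincident pairs; draw a synchronous event with
probability `ζ·(λ_A δ)(λ_B δ)` and place it at an identical time in both
trains; thin the surviving non-synchronous spikes with
`p_j = (λ_j − ζλ_Aλ_Bδ)/(λ_j − λ_Aλ_Bδ)` so marginal rates are preserved in
expectation (probabilities outside [0, 1] are an error naming the bin).
A synchronous event replaces any surviving spike in its 1 ms bin to keep
one spike per bin.

**Scenario presets** (`scenarios.py`) are declared reconstructions of the
study conditions — the exact curves behind the published figures are not
printed anywhere:

- stimulus `λ1(t) = C(1 + 0.4 sin(2π·2t))` Hz (a 2 Hz fluctuation like the
  slow current component of the patch-clamp experiment), with `C`
  calibrated by a deterministic renewal computation so the realized mean
  rate equals the requested value despite refractoriness;
- history `λ2(τ) = (1 − e^{−τ/4 ms})`, normalized to mean 1 over the
  history span (relative refractory period);
- phase `λ3(φ) = 1 + a·cos(φ − φ_pref)`, which integrates to 1 over the
  circle as the identifiability constraint requires.  `a = 0.4` matches the
  printed single-neuron comparison generator (`1 + 0.4 cos(φ + π)`); the
  neuron-pair demonstration uses `a = 0.7`, chosen by the package's own
  power formula so that a 50-trial demonstration detects the reduced-model
  excess (≈ e^{a²/2·…} ≈ 0.22 in log ζ, about four bootstrap SEs) — with
  `a = 0.4` the excess (0.08) is below the resolution of 50 trials;
- oscillation 40 Hz (the gamma-band drive of the slice experiment),
  uniform random initial phase per trial;
- pair scenarios express a preferred-phase difference as
  `λ3⁽B⁾(φ) = λ3⁽A⁾(φ − ΔΦ_pref)`.

## Power analysis

Closed form: with `log ζ̂ ≈ N(log ζ, (1/ζ)/(N T λ1 λ2 δ))`, the trial count
for power 1−β at one-sided level α is

```
N = ⌈ (1/(T λ1 λ2 δ)) · ((z_{1−α} − z_{β}/√ζ) / log ζ)² ⌉
```

The `√ζ` follows from the variance expression; a variant dividing by ζ
(matching one printed layout of the formula) is available via
`formula="printed"`.  At T = 2 s, 25 Hz and δ = 5 ms this gives N = 69 at
ζ = 1.125 and N = 8 at ζ = 1.4.  The simulation route
(`simulate_power`) runs the full inject → fit → test pipeline per replicate
and reports the rejection fraction with a binomial SE; `mode="fast"`
replaces the bootstrap p value with the normal approximation.

## LFP preprocessing

Band-pass: Chebyshev type II, order 4, 40 dB stopband, 4–25 Hz default,
applied forward–backward (zero phase) because the extracted phase feeds the
model — a causal filter would delay the signal and bias preferred-phase
estimates.  Instantaneous phase is the analytic-signal angle (phase 0 at
local maxima, cosine convention).  Per-neuron LFP is the unweighted mean
over the electrode's 8-adjacent present channels (4-adjacency by flag;
edge/corner channels use the neighbors they have; a channel with none is an
error).  Spike-triggered averages exclude clipped windows and report the
exclusion count.

## What the simulations do and do not show

The generators produce GLM neurons: the model class is exactly correct, so
passing tests demonstrate correct estimation, calibration and test
behavior under the stated model, not robustness to real-data violations
(bursting beyond one-spike history, non-stationary oscillation frequency
and amplitude, spike-sorting errors, amplitude-dependent modulation).  The
published slice and array experiments play that role in the original study
and are out of scope here; the mis-specification direction is partially
covered by fitting phase-free models to phase-modulated data.

## Numerical choices and problem sizes

- Bin width Δ = 1 ms; synchrony window δ = 5 ms; bootstrap G = 400
  (p-resolution 1/400); convergence tolerance 10⁻⁶ on Q; normalization
  integrals on 1000-point trapezoid grids; transition operator at m = 64
  phase bins with survival truncation 10⁻⁸.
- Monte-Carlo sizes: the acceptance script uses 200 seeded datasets for the
  null calibration and amplitude-recovery studies and 200 replicates for
  injection recovery (a few minutes on one CPU); the test suite runs the
  same checks at reduced sizes (dozens of seeds) with tolerances computed
  from the realized Monte-Carlo SEs, so the assertions scale honestly with
  the sizes used.

## Known limitations

- Per-δ-bin counting conventions differ at O(λδ) when bins can hold two
  spikes of one neuron; the default (`pairs`) is the one whose expectation
  matches the conditional-independence prediction identically (see above).
- The plug-in `N_pred` inherits a small upward finite-sample bias from
  `E[exp(f̂)] > exp(f)` (about +1% at 2,500 spikes per fit, shrinking with
  data); the bootstrap test is calibrated regardless because its null
  draws share the fitted intensities.
- No coupling filters between neurons, no amplitude covariates, no
  higher-order (three-way) synchrony, no lagged-synchrony windows.
- The transition-operator bias theory assumes a constant stimulus, as the
  eigenvector construction requires a time-invariant kernel.
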