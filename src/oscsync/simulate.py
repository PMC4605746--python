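"""Spike-train generators: GLM neurons with oscillatory drive, plus the
synchrony-injection (thinning) procedure used in the power analysis.

Generation is discrete-time Bernoulli at the model bin width (1 ms default):
at each bin the conditional intensity is computed from the trial's
history-free drive lambda1(t)*lambda3(phi_t) and the auto-history multiplier
lambda2 at the lag since the last generated spike, and a spike is drawn with
probability lambda*dt.  This matches the fitting likelihood exactly.  An
Ogata-thinning continuous-time generator is provided as an independent
cross-check of the discretization.

`inject_synchrony` converts a conditionally independent pair into a pair
with synchrony coefficient zeta: synchronous spikes in 5 ms bins are removed
and replaced by events drawn with per-bin probability
zeta*lambda1*lambda2*delta^2 (placed at identical times in both trains), and
the remaining non-synchronous spikes are thinned so each neuron's marginal
rate is preserved in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._kernels import simulate_bins
from .basis import wrap_phase
from .spikedata import BinnedDesign, CovariateSeries, SpikeTrainSet

__all__ = [
    "GeneratorSpec",
    "SimulatedDataset",
    "make_oscillation",
    "simulate_spike_trains",
    "simulate_spike_trains_ogata",
    "simulate_from_model",
    "inject_synchrony",
    "lags_from_counts",
    "design_from_counts",
]


@dataclass
class GeneratorSpec:
    """Ground-truth conditional intensity for simulation.

    lambda1: stimulus rate in Hz — a scalar or a callable of trial time.
    lambda2: auto-history multiplier, callable of lag (s), or None (Poisson).
    lambda3: phase-modulation multiplier, callable of phase, or None.  For
        recovery tests it should satisfy (1/2pi) int lambda3 dphi = 1.
    freq: oscillation frequency in Hz (required when lambda3 is present).
    initial_phase: "uniform" for a fresh random initial phase per trial, or
        a fixed phase in radians shared by all trials.
    """

    lambda1: object = 25.0
    lambda2: object = None
    lambda3: object = None
    freq: float = 40.0
    initial_phase: object = "uniform"
    trial_length: float = 2.0
    n_trials: int = 50
    dt: float = 1e-3
    history_span: float = 0.2

    @property
    def n_bins(self) -> int:
        return int(round(self.trial_length / self.dt))

    def bin_times(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.dt

    def lambda1_values(self) -> np.ndarray:
        t = self.bin_times()
        if callable(self.lambda1):
            return np.asarray(self.lambda1(t), dtype=float)
        return np.full(self.n_bins, float(self.lambda1))

    def log_hist_table(self) -> np.ndarray:
        """log lambda2 at lag bins j=1..L, lag (j-0.5)*dt; zeros if Poisson."""
        if self.lambda2 is None:
            return np.zeros(1)
        L = int(round(self.history_span / self.dt))
        lags = (np.arange(1, L + 1) - 0.5) * self.dt
        vals = np.asarray(self.lambda2(lags), dtype=float)
        if np.any(vals < 0):
            raise ValueError("lambda2 must be a nonnegative multiplier")
        return np.log(np.maximum(vals, 1e-300))


@dataclass
class SimulatedDataset:
    """Spike trains plus the covariates and per-bin intensities used."""

    spikes: SpikeTrainSet
    covariates: list
    counts: np.ndarray
    intensity: np.ndarray
    dt: float
    trial_length: float

    def design(self) -> BinnedDesign:
        phases = None
        if self.covariates and self.covariates[0].phase is not None:
            phases = np.vstack([c.phase for c in self.covariates])
        return design_from_counts(self.counts, self.dt, self.trial_length,
                                  phases=phases,
                                  trial_ids=self.spikes.trial_ids())


def make_oscillation(freq: float, trial_length: float, dt: float,
                     n_trials: int, initial_phase="uniform",
                     seed=None) -> list:
    """Per-trial phase series Phi_t = wrap(phi0 + 2*pi*f*t) on the bin grid.

    initial_phase "uniform" draws phi0 ~ U[-pi, pi) independently per trial;
    a float fixes phi0 for every trial.  Returns a list of CovariateSeries.
    """
    if freq <= 0:
        raise ValueError("oscillation frequency must be positive")
    rng = np.random.default_rng(seed)
    K = int(round(trial_length / dt))
    t = np.arange(K) * dt
    out = []
    for i in range(n_trials):
        if initial_phase == "uniform":
            phi0 = rng.uniform(-np.pi, np.pi)
        else:
            phi0 = float(initial_phase)
        out.append(CovariateSeries(i, t, phase=wrap_phase(phi0 + 2 * np.pi * freq * t)))
    return out


def _spike_times_from_counts(counts_row: np.ndarray, dt: float) -> np.ndarray:
    """Spikes are placed at the centers of their bins."""
    return (np.flatnonzero(counts_row) + 0.5) * dt


def lags_from_counts(counts: np.ndarray, dt: float):
    """(lags, has_history) per bin for spikes placed at bin centers.

    lag at bin k is k*dt - (last spike time before bin k), matching what
    bin_spikes computes when the trains are rebinned.
    """
    n, K = counts.shape
    idx = np.arange(K)
    spike_pos = np.where(counts > 0, idx[None, :], -1)
    cummax = np.maximum.accumulate(spike_pos, axis=1)
    last_before = np.concatenate(
        [np.full((n, 1), -1, dtype=int), cummax[:, :-1]], axis=1)
    has = last_before >= 0
    lags = np.where(has, (idx[None, :] - last_before - 0.5) * dt, 0.0)
    return lags, has


def design_from_counts(counts, dt, trial_length, phases=None,
                       trial_ids=None) -> BinnedDesign:
    """Binned design directly from a counts array (spikes at bin centers)."""
    counts = np.asarray(counts, dtype=np.int8)
    lags, has = lags_from_counts(counts, dt)
    if trial_ids is None:
        trial_ids = list(range(counts.shape[0]))
    return BinnedDesign(dt, list(trial_ids), counts, lags,
                        None if phases is None else np.asarray(phases, float),
                        has, trial_length)


def _check_poisson_approx(max_rate: float, dt: float) -> None:
    if max_rate * dt >= 1.0:
        raise ValueError(
            f"lambda_max*dt = {max_rate * dt:.3g} >= 1: the per-bin Bernoulli "
            "approximation is invalid; reduce dt")
    if max_rate * dt >= 0.2:
        warnings.warn(
            f"lambda_max*dt = {max_rate * dt:.3g} >= 0.2: the Poisson "
            "approximation is becoming inaccurate", RuntimeWarning)


def simulate_spike_trains(spec: GeneratorSpec, seed=None,
                          neuron_id: str = "sim",
                          covariates: list | None = None) -> SimulatedDataset:
    """Generate spike trains from a GeneratorSpec.

    If `covariates` is given (a list of per-trial CovariateSeries with phase),
    the oscillation phases are taken from it — used to share one oscillation
    across a neuron pair; otherwise phases are drawn per the spec.
    """
    rng = np.random.default_rng(seed)
    K = spec.n_bins
    n = spec.n_trials
    lam1 = spec.lambda1_values()
    if np.any(lam1 <= 0):
        raise ValueError("lambda1 must be positive")

    if spec.lambda3 is not None:
        if covariates is None:
            covariates = make_oscillation(
                spec.freq, spec.trial_length, spec.dt, n,
                spec.initial_phase, seed=rng.integers(2 ** 31))
        phases = np.vstack([c.phase for c in covariates])
        lam3 = np.asarray(spec.lambda3(phases), dtype=float)
        if np.any(lam3 <= 0):
            raise ValueError("lambda3 must be a positive multiplier")
        base_log = np.log(lam1)[None, :] + np.log(lam3)
    else:
        covariates = covariates or []
        base_log = np.broadcast_to(np.log(lam1)[None, :], (n, K)).copy()

    log_hist = spec.log_hist_table()
    _check_poisson_approx(float(np.exp(base_log.max() + max(log_hist.max(), 0.0))),
                          spec.dt)
    uniforms = rng.random((n, K))
    counts, lam = simulate_bins(np.ascontiguousarray(base_log), log_hist,
                                spec.dt, uniforms)
    trials = {i: _spike_times_from_counts(counts[i], spec.dt)
              for i in range(n)}
    spikes = SpikeTrainSet(neuron_id, trials, spec.trial_length)
    return SimulatedDataset(spikes, covariates, counts, lam, spec.dt,
                            spec.trial_length)


def simulate_spike_trains_ogata(spec: GeneratorSpec, seed=None,
                                neuron_id: str = "sim") -> SimulatedDataset:
    """Continuous-time generation by Ogata thinning (cross-check mode).

    Slower, pure-Python; used to validate the discrete-time generator.
    Spike times are continuous; the returned counts/intensity are on the bin
    grid for compatibility (two spikes in one bin raise in bin_spikes, as
    they would for real data binned too coarsely).
    """
    rng = np.random.default_rng(seed)
    T, dt, n = spec.trial_length, spec.dt, spec.n_trials
    lam1 = spec.lambda1
    lam1_fn = lam1 if callable(lam1) else (lambda t: np.full_like(np.atleast_1d(t), float(lam1)))
    covariates = None
    if spec.lambda3 is not None:
        covariates = make_oscillation(spec.freq, T, dt, n, spec.initial_phase,
                                      seed=rng.integers(2 ** 31))

    def hazard(t, t_last, phi0):
        v = float(np.asarray(lam1_fn(np.atleast_1d(t)))[0])
        if spec.lambda2 is not None and t_last is not None:
            lag = min(max(t - t_last, 1e-12), spec.history_span)
            v *= float(np.asarray(spec.lambda2(np.atleast_1d(lag)))[0])
        if spec.lambda3 is not None:
            phi = wrap_phase(phi0 + 2 * np.pi * spec.freq * t)
            v *= float(np.asarray(spec.lambda3(np.atleast_1d(phi)))[0])
        return v

    # global hazard bound
    tg = np.linspace(0, T, 2001)
    M = float(np.max(lam1_fn(tg)))
    if spec.lambda2 is not None:
        lag_grid = np.linspace(1e-6, spec.history_span, 1001)
        M *= float(np.max(spec.lambda2(lag_grid)))
    if spec.lambda3 is not None:
        phig = np.linspace(-np.pi, np.pi, 721)
        M *= float(np.max(spec.lambda3(phig)))
    M *= 1.05

    trials = {}
    for i in range(n):
        phi0 = 0.0
        if covariates is not None:
            phi0 = float(covariates[i].phase[0])
        t, t_last, times = 0.0, None, []
        while True:
            t += rng.exponential(1.0 / M)
            if t > T:
                break
            if rng.random() < hazard(t, t_last, phi0) / M:
                times.append(t)
                t_last = t
        trials[i] = np.asarray(times)
    spikes = SpikeTrainSet(neuron_id, trials, T)
    K = spec.n_bins
    counts = np.zeros((n, K), dtype=np.int8)
    for i in range(n):
        idx = np.minimum((trials[i] / dt).astype(int), K - 1)
        counts[i, idx] = 1
    return SimulatedDataset(spikes, covariates or [], counts,
                            np.zeros((n, K)), dt, T)


# ---------------------------------------------------------------------------
# Simulation from a fitted model (parametric bootstrap)
# ---------------------------------------------------------------------------

def model_tables(model, design: BinnedDesign):
    """(base_log, log_hist) tables for generating from a fitted model,
    conditioning on the design's phase series."""
    spec = model.spec
    K = design.n_bins
    dt = design.bin_width
    t = design.bin_times
    base = model.f1(t) if spec.include_stimulus else np.zeros(K)
    base = np.broadcast_to(base[None, :], design.counts.shape).copy()
    if spec.include_phase:
        if design.phase_per_bin is None:
            raise ValueError("model has a phase term but design has no phases")
        base += model.f3(design.phase_per_bin.reshape(-1)).reshape(base.shape)
    if spec.include_history:
        lo, hi = spec.history_basis.span
        L = int(round(hi / dt))
        lags = (np.arange(1, L + 1) - 0.5) * dt
        log_hist = model.f2(lags)
    else:
        log_hist = np.zeros(1)
    return base, log_hist


def simulate_from_model(model, design: BinnedDesign, seed=None) -> BinnedDesign:
    """Draw one dataset from a fitted model, conditioned on the design's
    trial structure and phase series.  Returns a BinnedDesign ready to refit."""
    rng = np.random.default_rng(seed)
    base_log, log_hist = model_tables(model, design)
    uniforms = rng.random(base_log.shape)
    counts, _ = simulate_bins(np.ascontiguousarray(base_log), log_hist,
                              design.bin_width, uniforms)
    return design_from_counts(counts, design.bin_width, design.trial_length,
                              phases=design.phase_per_bin,
                              trial_ids=design.trial_ids)


# ---------------------------------------------------------------------------
# Synchrony injection with marginal-preserving thinning
# ---------------------------------------------------------------------------

def inject_synchrony(simA: SimulatedDataset, simB: SimulatedDataset,
                     zeta: float, delta: float = 5e-3,
                     seed=None):
    """Impose synchrony coefficient `zeta` on an independent pair.

    Per delta-bin: existing coincidences are removed, new synchronous events
    are drawn ~ Poisson(zeta * lambdaA*delta * lambdaB*delta) and placed at
    identical times in both trains, and the surviving non-synchronous spikes
    are thinned with

        p_j(t) = (lambda_j - zeta*lambdaA*lambdaB*delta)
                 / (lambda_j - lambdaA*lambdaB*delta)

    so each neuron's marginal intensity is preserved in expectation.  With
    zeta = 1 every probability is 1 and the pair is returned unchanged in
    distribution.  Returns (spikesA, spikesB) SpikeTrainSets.
    """
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    if simA.dt != simB.dt or simA.counts.shape != simB.counts.shape:
        raise ValueError("pair must share trial structure and bin width")
    rng = np.random.default_rng(seed)
    dt = simA.dt
    g = int(round(delta / dt))
    n, K = simA.counts.shape
    if K % g:
        raise ValueError("delta must be a whole number of model bins")
    n_groups = K // g

    lamA, lamB = simA.intensity, simB.intensity
    # thinning feasibility: p in [0, 1] everywhere a spike could survive
    numerA = lamA - zeta * lamA * lamB * delta
    if np.any(numerA <= 0) or np.any(lamB - zeta * lamA * lamB * delta <= 0):
        i, k = np.unravel_index(int(np.argmin(numerA)), numerA.shape)
        raise ValueError(
            f"thinning probability outside [0,1] at trial {i}, bin {k}: "
            "zeta too large for these rates")

    trialsA, trialsB = {}, {}
    tidsA = simA.spikes.trial_ids()
    tidsB = simB.spikes.trial_ids()
    for i in range(n):
        cA = simA.counts[i].astype(np.int64).reshape(n_groups, g)
        cB = simB.counts[i].astype(np.int64).reshape(n_groups, g)
        keepA = simA.counts[i].astype(bool).copy()
        keepB = simB.counts[i].astype(bool).copy()
        # remove existing coincidences (min-count pairs, earliest first)
        both = np.flatnonzero((cA.sum(1) > 0) & (cB.sum(1) > 0))
        for grp in both:
            m = min(cA[grp].sum(), cB[grp].sum())
            for keep, c in ((keepA, cA), (keepB, cB)):
                bins = grp * g + np.flatnonzero(c[grp])[:m]
                keep[bins] = False
        # thin surviving non-synchronous spikes
        for keep, lam_self, lam_other in ((keepA, lamA[i], lamB[i]),
                                          (keepB, lamB[i], lamA[i])):
            spikes = np.flatnonzero(keep)
            cross = lam_self[spikes] * lam_other[spikes] * delta
            p = (lam_self[spikes] - zeta * cross) / (lam_self[spikes] - cross)
            keep[spikes[rng.random(spikes.size) >= p]] = False
        # inject synchronous events: per delta-bin, a synchronous spike
        # occurs with probability zeta*lambdaA*lambdaB*delta^2
        PA = np.add.reduceat(lamA[i] * dt, np.arange(0, K, g))
        PB = np.add.reduceat(lamB[i] * dt, np.arange(0, K, g))
        p_sync = zeta * PA * PB
        if np.any(p_sync > 1.0):
            raise ValueError("synchronous-event probability exceeds 1; "
                             "zeta too large for these rates")
        hit = np.flatnonzero(rng.random(n_groups) < p_sync)
        sync_bins = hit * g + rng.integers(0, g, size=hit.size)
        # a sync event replaces any surviving spike in its 1 ms bin
        keepA[sync_bins] = False
        keepB[sync_bins] = False
        timesA = np.sort(np.concatenate(
            [(np.flatnonzero(keepA) + 0.5) * dt, (sync_bins + 0.5) * dt]))
        timesB = np.sort(np.concatenate(
            [(np.flatnonzero(keepB) + 0.5) * dt, (sync_bins + 0.5) * dt]))
        trialsA[tidsA[i]] = timesA
        trialsB[tidsB[i]] = timesB

    T = simA.trial_length
    return (SpikeTrainSet(simA.spikes.neuron_id, trialsA, T),
            SpikeTrainSet(simB.spikes.neuron_id, trialsB, T))
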