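"""Spike-phase histograms, the transition-operator theory of their bias,
and histogram-vs-GLM estimation error.

The spike phase histogram estimates the distribution P_data(phi) of
oscillation phases at spike times.  For Poisson firing this equals
lambda3(phi)/2pi, but with an auto-history effect the phase of each spike
depends on the phase of the previous one, and P_data becomes the stationary
distribution of a phase-to-phase transition operator:

    P = A P,   A_ij = P(phi_k in bin i | phi_{k-1} in bin j),

built from the waiting-time density f(t) = lambda(t) exp(-int lambda) of
the next spike, summed over the lag set {(phi - phi0)/w + k/f : k >= 0}
(w = 2 pi f).  P is the eigenvector of A with eigenvalue 1; for non-Poisson
firing it differs from lambda3/2pi in a rate-dependent way, which is the
histogram's bias.  The GLM estimator of lambda3 has no such bias, which the
MISE comparison (variance + bias^2 decomposition) quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import wrap_phase
from .spikedata import SpikeTrainSet

__all__ = [
    "PhaseDistribution",
    "EstimationErrorSummary",
    "spike_phase_histogram",
    "waiting_time_density",
    "theoretical_phase_distribution",
    "compare_estimators",
]

TWO_PI = 2.0 * np.pi


@dataclass
class PhaseDistribution:
    """Binned probability density over phase [-pi, pi)."""

    bin_edges: np.ndarray
    mass: np.ndarray  # density: sum(mass * widths) = 1
    kind: str = "empirical"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if np.any(self.mass < -1e-12):
            raise ValueError("phase distribution mass must be nonnegative")
        widths = np.diff(self.bin_edges)
        total = float((self.mass * widths).sum())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mass integrates to {total:.6g}, not 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def as_modulation(self) -> np.ndarray:
        """Rescale to the lambda3 scale (density * 2pi), so a flat
        distribution maps to multiplier 1."""
        return self.mass * TWO_PI

    def evaluate(self, phi) -> np.ndarray:
        """Step-function density at arbitrary phases."""
        idx = np.clip(np.searchsorted(self.bin_edges, wrap_phase(phi),
                                      side="right") - 1, 0, len(self.mass) - 1)
        return self.mass[idx]


@dataclass
class EstimationErrorSummary:
    """MISE of a lambda3 estimator and its variance/bias^2 split."""

    method: str
    n_trials: int
    mise: float
    variance_component: float
    bias_sq_component: float
    n_datasets: int = 0
    extra: dict | None = None


def spike_phase_histogram(spikes: SpikeTrainSet, covariates,
                          n_bins: int = 16) -> PhaseDistribution:
    """Empirical distribution of oscillation phases at spike times.

    `covariates` is a dict trial_id -> CovariateSeries (or list in trial
    order) carrying the per-trial phase series; the phase at each spike is
    read off the covariate grid bin containing the spike.
    """
    if not isinstance(covariates, dict):
        covariates = {c.trial_id: c for c in covariates}
    phases = []
    for tid, times in spikes.trials.items():
        cov = covariates[tid]
        if times.size == 0:
            continue
        idx = np.minimum((times / cov.dt).astype(int), len(cov.phase) - 1)
        phases.append(cov.phase[idx])
    if not phases:
        raise ValueError("no spikes: cannot form a spike phase histogram")
    phases = np.concatenate(phases)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(phases, edges)
    mass = counts / counts.sum() / np.diff(edges)
    return PhaseDistribution(edges, mass, kind="empirical")


# ---------------------------------------------------------------------------
# Waiting-time density and the transition operator
# ---------------------------------------------------------------------------

def waiting_time_density(base_rate: float, lambda2, lambda3, freq: float,
                         phi0: float, t_grid: np.ndarray) -> np.ndarray:
    """Density of the time to the next spike after a spike at phase phi0.

    The conditional intensity is lambda(t) = C * lambda2(t) * lambda3(phi0 +
    w t) with w = 2 pi f; the density is f(t) = lambda(t) exp(-int_0^t
    lambda).  lambda2/lambda3 may be None (factor 1).  Evaluated on `t_grid`
    (which should start at or near 0 and be finely spaced).
    """
    t = np.asarray(t_grid, dtype=float)
    lam = np.full(t.shape, float(base_rate))
    if lambda2 is not None:
        lam = lam * np.asarray(lambda2(np.maximum(t, 1e-12)), dtype=float)
    if lambda3 is not None:
        phi = phi0 + TWO_PI * freq * t
        lam = lam * np.asarray(lambda3(phi), dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (lam[1:] + lam[:-1]) * np.diff(t))])
    return lam * np.exp(-cum)


def _survival_horizon(base_rate: float, lambda2, tol: float = 1e-8) -> float:
    """Time by which the next-spike survival probability drops below tol."""
    dt = 1e-3
    t = np.arange(1, 200001) * dt
    lam = np.full(t.shape, float(base_rate))
    if lambda2 is not None:
        lam = lam * np.asarray(lambda2(np.maximum(t, 1e-12)), dtype=float)
    # lambda3 >= 1 - a > 0 only scales the horizon; ignore (conservative
    # margin applied by the caller)
    surv = np.exp(-np.cumsum(lam) * dt)
    idx = np.searchsorted(-surv, -tol)
    return float(t[min(idx, len(t) - 1)])


def theoretical_phase_distribution(base_rate: float, lambda2, lambda3,
                                   freq: float, m: int = 64,
                                   return_eigenvalue: bool = False):
    """Stationary spike-phase distribution predicted by the transition
    operator (the theoretical spike phase histogram).

    Builds the m x m transition matrix A by integrating the waiting-time
    density over each phase bin across all oscillation cycles up to the
    survival horizon, then extracts the eigenvector with eigenvalue nearest
    1 (clipped to nonnegative and renormalized; A is column-stochastic up to
    the survival-truncation error).
    """
    if m < 16:
        raise ValueError("need at least 16 phase bins")
    w = TWO_PI * freq
    # generous horizon: lambda3 can dip to small values, slowing escape
    t_max = 3.0 * _survival_horizon(base_rate, lambda2) + 2.0 / freq
    dt = min(1e-4, 1.0 / (50.0 * base_rate), 1.0 / (20.0 * m * freq))
    t = np.arange(0.0, t_max + dt, dt)
    edges = np.linspace(-np.pi, np.pi, m + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    k_max = int(np.ceil(t_max * freq)) + 1

    A = np.zeros((m, m))
    for j, phi0 in enumerate(centers):
        dens = waiting_time_density(base_rate, lambda2, lambda3, freq, phi0, t)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(t))])
        for i in range(m):
            lo = (edges[i] - phi0) / w + np.arange(k_max + 1) / freq
            hi = (edges[i + 1] - phi0) / w + np.arange(k_max + 1) / freq
            lo = np.clip(lo, 0.0, t[-1])
            hi = np.clip(hi, 0.0, t[-1])
            A[i, j] = np.sum(np.interp(hi, t, cdf) - np.interp(lo, t, cdf))

    eigvals, eigvecs = np.linalg.eig(A)
    k = int(np.argmin(np.abs(eigvals - 1.0)))
    lam_near_1 = eigvals[k]
    if abs(lam_near_1 - 1.0) > 1e-4:
        raise RuntimeError(
            f"no eigenvalue within 1e-4 of 1 (nearest: {lam_near_1:.6g}); "
            "the model or discretization is invalid")
    vec = np.real(eigvecs[:, k])
    if vec.sum() < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)
    mass = vec / (vec.sum() * np.diff(edges))
    dist = PhaseDistribution(edges, mass, kind="theoretical")
    if return_eigenvalue:
        return dist, float(np.real(lam_near_1))
    return dist


# ---------------------------------------------------------------------------
# Histogram vs GLM estimation error
# ---------------------------------------------------------------------------

def integrated_squared_error(curve_values, truth_values, phi_grid) -> float:
    """ISE = int [lambda3_hat - lambda3]^2 dphi on a uniform grid."""
    diff = np.asarray(curve_values) - np.asarray(truth_values)
    return float(np.trapezoid(diff ** 2, phi_grid))


def _mise_decomposition(estimates: np.ndarray, truth: np.ndarray,
                        phi_grid: np.ndarray):
    """MISE = mean ISE; variance and bias^2 components about the pointwise
    sample mean curve (they sum to the MISE up to integration error)."""
    mean_curve = estimates.mean(axis=0)
    var = np.trapezoid(((estimates - mean_curve) ** 2).mean(axis=0), phi_grid)
    bias2 = np.trapezoid((mean_curve - truth) ** 2, phi_grid)
    mise = np.mean([np.trapezoid((e - truth) ** 2, phi_grid) for e in estimates])
    return float(mise), float(var), float(bias2)


def compare_estimators(truth_lambda3, scenario, trial_counts,
                       n_datasets: int = 20, seed=None,
                       histogram_bins=(4, 6, 8, 12, 16, 24, 32),
                       n_grid: int = 256, model_spec=None) -> list:
    """Histogram vs GLM estimation of lambda3 across sample sizes.

    For each trial count: simulate `n_datasets` datasets from `scenario` (a
    GeneratorSpec), estimate lambda3 by (a) the spike phase histogram on the
    MISE-minimizing bin count from `histogram_bins` and (b) the full GLM,
    and report MISE with its variance/bias^2 split.  Returns a list of
    EstimationErrorSummary (two per trial count).
    """
    from dataclasses import replace as _rep

    from .ppglm import ModelSpec, fit
    from .simulate import simulate_spike_trains

    rng = np.random.default_rng(seed)
    phi_grid = np.linspace(-np.pi, np.pi, n_grid)
    truth = np.asarray(truth_lambda3(phi_grid), dtype=float)
    out = []
    for n_trials in trial_counts:
        spec_n = _rep(scenario, n_trials=int(n_trials))
        hist_curves = {nb: [] for nb in histogram_bins}
        glm_curves = []
        for _ in range(n_datasets):
            sim = simulate_spike_trains(spec_n, seed=int(rng.integers(2 ** 31)))
            for nb in histogram_bins:
                try:
                    h = spike_phase_histogram(sim.spikes, sim.covariates, nb)
                except ValueError:
                    continue
                hist_curves[nb].append(h.evaluate(phi_grid) * TWO_PI)
            design = sim.design()
            mspec = model_spec if model_spec is not None else ModelSpec(
                include_history=scenario.lambda2 is not None)
            model = fit(design, mspec)
            glm_curves.append(model.phase_curve(phi_grid))
        # histogram: MISE-minimizing bin count
        best = None
        for nb, curves in hist_curves.items():
            if not curves:
                continue
            mise, var, b2 = _mise_decomposition(np.vstack(curves), truth, phi_grid)
            if best is None or mise < best[0]:
                best = (mise, var, b2, nb)
        out.append(EstimationErrorSummary(
            "histogram", int(n_trials), best[0], best[1], best[2],
            n_datasets=n_datasets, extra={"n_bins": best[3]}))
        mise, var, b2 = _mise_decomposition(np.vstack(glm_curves), truth, phi_grid)
        out.append(EstimationErrorSummary(
            "glm", int(n_trials), mise, var, b2, n_datasets=n_datasets))
    return out
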