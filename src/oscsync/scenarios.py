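"""Reference simulation scenarios.

These are reconstructions of the study's simulation conditions: GLM neurons
with a smooth trial-locked stimulus effect, a relative-refractory
auto-history effect, and a cosine phase-modulation curve with a per-neuron
preferred phase, driven by a shared oscillation with a fresh random initial
phase each trial.  The exact curve shapes behind the published figures are
not printed anywhere, so these presets declare their parameters explicitly
and are labelled reconstructions, not reproductions.

Ground-truth curves are pre-normalized the same way the fitted model is
(history multiplier averaging 1 over the history span, phase multiplier
averaging 1 over the circle) so fitted and true curves are directly
comparable, and the base rate is calibrated so the realized mean firing
rate matches the requested rate despite refractoriness.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .simulate import GeneratorSpec

__all__ = [
    "cosine_modulation",
    "relative_refractory",
    "calibrate_base_rate",
    "fluctuating_stimulus",
    "single_neuron",
    "sinusoid_modulation_generator",
    "independent_pair",
    "phase_shifted_pair",
]

HISTORY_SPAN = 0.2
LAG_MIN = 1e-3


def cosine_modulation(amplitude: float = 0.4, preferred_phase: float = 0.0):
    """lambda3(phi) = 1 + a*cos(phi - phi_pref); satisfies
    (1/2pi) int lambda3 dphi = 1 for |a| < 1."""
    if not abs(amplitude) < 1:
        raise ValueError("|amplitude| must be < 1 for a positive multiplier")

    def lam3(phi):
        return 1.0 + amplitude * np.cos(np.asarray(phi) - preferred_phase)

    return lam3


def relative_refractory(tau: float = 0.004, span: float = HISTORY_SPAN):
    """Relative-refractory history multiplier, normalized to mean 1 over
    [LAG_MIN, span]: suppression right after a spike, recovery with time
    constant `tau`."""
    grid = np.linspace(LAG_MIN, span, 2000)
    raw = 1.0 - np.exp(-grid / tau)
    norm = np.trapezoid(raw, grid) / (span - LAG_MIN)

    def lam2(lag):
        return (1.0 - np.exp(-np.asarray(lag) / tau)) / norm

    return lam2


def calibrate_base_rate(target_rate: float, lambda2=None,
                        dt: float = 1e-4) -> float:
    """Base rate C (Hz) such that a neuron with hazard C*lambda2(lag)
    fires at `target_rate` on average (renewal calculation).

    The rotating phase modulation averages to multiplier 1 and is ignored
    here; its effect on the realized rate is second order.
    """
    if lambda2 is None:
        return float(target_rate)
    t_max = 20.0 / target_rate
    tau = np.arange(1, int(t_max / dt) + 1) * dt
    mult = np.asarray(lambda2(np.clip(tau, LAG_MIN, HISTORY_SPAN)))

    def realized(C):
        hazard = C * mult
        surv = np.exp(-np.cumsum(hazard) * dt)
        mean_isi = dt * (0.5 + surv[:-1].sum() + 0.5 * surv[-1])
        # tail beyond t_max: hazard is flat there
        mean_isi += surv[-1] / hazard[-1]
        return 1.0 / mean_isi

    return float(brentq(lambda C: realized(C) - target_rate,
                        target_rate * 0.5, target_rate * 10.0, xtol=1e-8))


def fluctuating_stimulus(base_rate: float, depth: float = 0.4,
                         freq: float = 2.0):
    """Smooth trial-locked stimulus rate lambda1(t) = C*(1 + depth*sin(2 pi f t)),
    time-averaging to C over whole periods."""

    def lam1(t):
        return base_rate * (1.0 + depth * np.sin(2 * np.pi * freq * np.asarray(t)))

    return lam1


def single_neuron(mean_rate: float = 25.0, trial_length: float = 2.0,
                  n_trials: int = 50, *, preferred_phase: float = 0.0,
                  mod_amplitude: float = 0.4, osc_freq: float = 40.0,
                  stim_depth: float = 0.4, refractory_tau: float = 0.004,
                  poisson: bool = False, dt: float = 1e-3) -> GeneratorSpec:
    """Full-model GLM neuron: fluctuating stimulus, relative-refractory
    history (unless `poisson`), cosine phase modulation."""
    lam2 = None if poisson else relative_refractory(refractory_tau)
    base = calibrate_base_rate(mean_rate, lam2)
    return GeneratorSpec(
        lambda1=fluctuating_stimulus(base, stim_depth),
        lambda2=lam2,
        lambda3=cosine_modulation(mod_amplitude, preferred_phase),
        freq=osc_freq,
        initial_phase="uniform",
        trial_length=trial_length,
        n_trials=n_trials,
        dt=dt,
        history_span=HISTORY_SPAN,
    )


def sinusoid_modulation_generator(mean_rate: float = 10.0,
                                  trial_length: float = 2.0,
                                  n_trials: int = 50,
                                  osc_freq: float = 40.0,
                                  dt: float = 1e-3) -> GeneratorSpec:
    """Poisson neuron with the sinusoidal modulation used in the
    rate-independence comparison: lambda3(phi) = 1 + 0.4*cos(phi + pi)."""
    return GeneratorSpec(
        lambda1=float(mean_rate),
        lambda2=None,
        lambda3=cosine_modulation(0.4, np.pi),
        freq=osc_freq,
        initial_phase="uniform",
        trial_length=trial_length,
        n_trials=n_trials,
        dt=dt,
    )


def independent_pair(mean_rate: float = 25.0, trial_length: float = 2.0,
                     n_trials: int = 50, delta_phi_pref: float = 0.0,
                     **kwargs):
    """Two conditionally independent neurons sharing an oscillatory drive.

    Neuron B's phase-modulation curve is neuron A's shifted by
    `delta_phi_pref`.  Simulate with a shared phase series (pass the same
    covariates to both) to realize the common drive.
    """
    a = single_neuron(mean_rate, trial_length, n_trials,
                      preferred_phase=0.0, **kwargs)
    b = single_neuron(mean_rate, trial_length, n_trials,
                      preferred_phase=delta_phi_pref, **kwargs)
    return a, b


# alias emphasising the role of the preferred-phase offset
phase_shifted_pair = independent_pair
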