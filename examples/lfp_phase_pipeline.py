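"""From raw LFP to phase modulation: the full preprocessing path.

A synthetic LFP carries a 10 Hz oscillation plus broadband noise; spikes
are generated with a phase modulation locked to that oscillation.  The LFP
is band-pass filtered (Chebyshev II, zero-phase), the instantaneous phase
extracted with the Hilbert transform, and the GLM fitted on the extracted
phase recovers the modulation.  A spike-triggered average confirms the
phase locking directly.
"""

import numpy as np

import oscsync as osc
from oscsync.lfp import bandpass, instantaneous_phase, spike_triggered_average
from oscsync.scenarios import cosine_modulation
from oscsync.simulate import GeneratorSpec, make_oscillation, \
    simulate_spike_trains
from oscsync.spikedata import CovariateSeries, bin_spikes

rng = np.random.default_rng(0)
f_osc, T, n_trials, fs = 10.0, 2.0, 40, 1000.0

true_phase = make_oscillation(f_osc, T, 1e-3, n_trials, "uniform", seed=1)
gen = GeneratorSpec(lambda1=25.0, lambda3=cosine_modulation(0.5, 0.0),
                    freq=f_osc, trial_length=T, n_trials=n_trials)
sim = simulate_spike_trains(gen, seed=2, covariates=true_phase)

extracted = []
lfps = {}
for cov in true_phase:
    lfp = np.cos(cov.phase) + 0.5 * rng.standard_normal(len(cov.phase))
    lfps[cov.trial_id] = lfp
    phase = instantaneous_phase(bandpass(lfp, fs))
    extracted.append(CovariateSeries(cov.trial_id, cov.sample_times,
                                     phase=phase))

design = bin_spikes(sim.spikes, {c.trial_id: c for c in extracted})
model = osc.fit(design, osc.ModelSpec(include_history=False))
phi = np.linspace(-np.pi, np.pi, 128)
lam3 = model.phase_curve(phi)
print(f"recovered modulation amplitude {(lam3.max() - lam3.min()) / 2:.3f} "
      "(true 0.5) from Hilbert phases of the noisy LFP")
print(f"preferred phase {phi[np.argmax(lam3)]:+.2f} rad (true 0.0, "
      "phase 0 = oscillation peak)")

lags, sta, n_used, _ = spike_triggered_average(sim.spikes, lfps, fs,
                                               window=(0.15, 0.15))
print(f"spike-triggered average over {n_used} spikes peaks at "
      f"{lags[np.argmax(sta)] * 1000:+.0f} ms lag "
      "(phase locking visible directly in the LFP)")
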