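"""Simulate a GLM neuron and recover its three firing-rate components.

A neuron is driven by a fluctuating stimulus (2 Hz, 25 Hz mean rate), its
own refractory history, and a 40 Hz oscillation whose phase modulates the
rate as 1 + 0.4 cos(phi).  The full point-process GLM is fitted to 30
trials and the recovered curves are compared to the generating truth.
"""

import numpy as np

import oscsync as osc
from oscsync.scenarios import single_neuron

gen = single_neuron(mean_rate=25.0, trial_length=2.0, n_trials=30,
                    preferred_phase=0.0, mod_amplitude=0.4)
sim = osc.simulate_spike_trains(gen, seed=42)
print(f"simulated {sim.spikes.n_spikes} spikes over {sim.spikes.n_trials} "
      f"trials ({sim.spikes.mean_rate():.1f} Hz)")

design = sim.design()
model = osc.fit(design, osc.ModelSpec())
print(f"fit converged: {model.converged} after {model.n_iterations} cycles")

phi = np.linspace(-np.pi, np.pi, 200)
lam3 = model.phase_curve(phi)
amp = (lam3.max() - lam3.min()) / 2
pref = phi[np.argmax(lam3)]
print(f"phase modulation: amplitude {amp:.3f} (true 0.4), "
      f"preferred phase {pref:+.2f} rad (true 0.0)")

tau = np.array([0.002, 0.005, 0.010, 0.050])
print("history multiplier at 2/5/10/50 ms:",
      np.round(model.history_curve(tau), 2),
      " (recovers the relative refractory period)")

ks, p = osc.goodness_of_fit(model, design)
print(f"time-rescaling goodness of fit: KS = {ks:.4f}, p = {p:.3f} "
      "(large p: no evidence of misfit)")
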