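"""Does a shared oscillation explain the synchrony of a neuron pair?

Two conditionally independent neurons share a 40 Hz oscillatory drive with
the same preferred phase, which synchronizes their spikes beyond what
stimulus and refractory effects predict.  The phase-free (reduced) model
under-predicts the coincidences and the bootstrap test rejects
log zeta = 0; adding the oscillation-phase term (full model) explains them.
"""

import oscsync as osc
from oscsync.scenarios import independent_pair
from oscsync.simulate import make_oscillation, simulate_spike_trains

n_trials = 50
genA, genB = independent_pair(25.0, 2.0, n_trials, delta_phi_pref=0.0,
                              mod_amplitude=0.7)
shared = make_oscillation(40.0, 2.0, 1e-3, n_trials, "uniform", seed=1)
simA = simulate_spike_trains(genA, seed=2, neuron_id="A", covariates=shared)
simB = simulate_spike_trains(genB, seed=3, neuron_id="B", covariates=shared)
dA, dB = simA.design(), simB.design()

for label, spec in [("reduced (stimulus + history)",
                     osc.ModelSpec(include_phase=False)),
                    ("full (stimulus + history + phase)", osc.ModelSpec())]:
    mA = osc.fit(dA, spec)
    mB = osc.fit(dB, spec)
    res = osc.estimate_zeta(simA.spikes, simB.spikes, mA, mB, dA, dB)
    res = osc.bootstrap_test(mA, mB, dA, dB, res, G=400, seed=9)
    print(f"{label}:")
    print(f"  N_obs = {res.n_obs}, N_pred = {res.n_pred:.1f}, "
          f"log zeta_hat = {res.log_zeta_hat:+.3f} "
          f"(se {res.bootstrap_se:.3f}), p = {res.p_value:.4f}")

print("\nreduced model: small p, observed synchrony exceeds the prediction;")
print("full model: large p, the oscillation phase accounts for the excess.")
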