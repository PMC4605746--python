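import pytest

import oscsync as osc
from oscsync.scenarios import single_neuron


@pytest.fixture(scope="session")
def phase_modulated_dataset():
    """One full-generator dataset (stimulus + refractory history + cosine
    phase modulation, 25 Hz, 30 trials) shared across tests."""
    gen = single_neuron(25.0, 2.0, 30, preferred_phase=0.0)
    sim = osc.simulate_spike_trains(gen, seed=1234)
    return gen, sim


@pytest.fixture(scope="session")
def fitted_full_model(phase_modulated_dataset):
    """Full-model fit of the shared dataset."""
    _, sim = phase_modulated_dataset
    design = sim.design()
    model = osc.fit(design, osc.ModelSpec())
    return model, design
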