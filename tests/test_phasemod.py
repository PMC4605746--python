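import numpy as np
import pytest

import oscsync as osc
from oscsync.phasemod import (spike_phase_histogram,
                              theoretical_phase_distribution,
                              waiting_time_density, _mise_decomposition,
                              compare_estimators)
from oscsync.scenarios import cosine_modulation, relative_refractory
from oscsync.simulate import (GeneratorSpec, make_oscillation,
                              simulate_spike_trains)


class TestHistogram:
    def test_uniform_phases_give_flat_histogram(self):
        gen = GeneratorSpec(lambda1=30.0, lambda3=None, n_trials=50)
        sim = simulate_spike_trains(gen, seed=0)
        covs = make_oscillation(40.0, 2.0, 1e-3, 50, "uniform", seed=1)
        h = spike_phase_histogram(sim.spikes, covs, n_bins=8)
        n = sim.spikes.n_spikes
        width = 2 * np.pi / 8
        se = np.sqrt((1 / 8) * (1 - 1 / 8) / n) / width
        np.testing.assert_allclose(h.mass, 1 / (2 * np.pi), atol=5 * se)

    def test_total_mass_is_one(self):
        gen = GeneratorSpec(lambda1=20.0, lambda3=cosine_modulation(0.4),
                            n_trials=20)
        sim = simulate_spike_trains(gen, seed=2)
        h = spike_phase_histogram(sim.spikes, sim.covariates, 16)
        assert (h.mass * np.diff(h.bin_edges)).sum() == pytest.approx(1.0)

    def test_poisson_histogram_estimates_lambda3_over_2pi(self):
        lam3 = cosine_modulation(0.4, np.pi)
        gen = GeneratorSpec(lambda1=20.0, lambda3=lam3, freq=40.0,
                            n_trials=200)
        sim = simulate_spike_trains(gen, seed=3)
        h = spike_phase_histogram(sim.spikes, sim.covariates, 16)
        truth = lam3(h.bin_centers) / (2 * np.pi)
        # ~4 sigma of the per-bin sampling noise plus the half-bin phase
        # sampling offset
        np.testing.assert_allclose(h.mass, truth, atol=0.03)

    def test_zero_spikes_is_error(self):
        sts = osc.SpikeTrainSet("A", {0: np.empty(0)}, 1.0)
        from oscsync.spikedata import CovariateSeries
        cov = CovariateSeries(0, np.arange(0, 1.0, 1e-3),
                              phase=np.zeros(1000))
        with pytest.raises(ValueError, match="no spikes"):
            spike_phase_histogram(sts, [cov], 8)


class TestWaitingTime:
    def test_constant_rate_gives_exponential(self):
        C = 25.0
        t = np.linspace(0, 0.8, 8001)
        f = waiting_time_density(C, None, None, 40.0, 0.0, t)
        np.testing.assert_allclose(f, C * np.exp(-C * t), rtol=1e-6)

    def test_density_integrates_to_one(self):
        C = 25.0
        t = np.linspace(0, 20.0 / C, 20001)
        f = waiting_time_density(C, relative_refractory(),
                                 cosine_modulation(0.4), 40.0, 0.7, t)
        assert np.trapezoid(f, t) == pytest.approx(1.0, abs=1e-4)

    def test_matches_empirical_isi_distribution(self):
        lam2 = relative_refractory(0.008)
        gen = GeneratorSpec(lambda1=50.0, lambda2=lam2, lambda3=None,
                            n_trials=200)
        sim = simulate_spike_trains(gen, seed=4)
        isis = np.concatenate([np.diff(t) for t in sim.spikes.trials.values()])
        t = np.linspace(0, 0.2, 2001)
        f = waiting_time_density(50.0, lam2, None, 40.0, 0.0, t)
        cdf = np.cumsum(f) * (t[1] - t[0])
        # compare empirical and theoretical CDFs on a grid
        qs = np.linspace(0.01, 0.15, 15)
        emp = np.array([(isis <= q).mean() for q in qs])
        theo = np.interp(qs, t, cdf / cdf[-1])
        # the generator is discrete-time Bernoulli at 1 ms, the density is
        # continuous-time: a few-percent CDF offset is the discretization
        assert np.max(np.abs(emp - theo)) < 0.04


class TestTransitionOperator:
    def test_columns_sum_to_one_and_eigenvalue_unity(self):
        dist, ev = theoretical_phase_distribution(
            50.0, relative_refractory(0.008), cosine_modulation(0.4, np.pi),
            10.0, m=32, return_eigenvalue=True)
        assert ev == pytest.approx(1.0, abs=1e-4)
        assert (dist.mass >= 0).all()

    def test_poisson_case_returns_lambda3_over_2pi(self):
        lam3 = cosine_modulation(0.4, np.pi)
        dist = theoretical_phase_distribution(20.0, None, lam3, 6.0, m=64)
        truth = lam3(dist.bin_centers) / (2 * np.pi)
        np.testing.assert_allclose(dist.mass, truth, atol=2e-3)

    def test_poisson_fixed_point_identity(self):
        # plugging lambda3/2pi into the discretized operator returns itself
        lam3 = cosine_modulation(0.3, 0.5)
        dist = theoretical_phase_distribution(30.0, None, lam3, 8.0, m=32)
        truth = lam3(dist.bin_centers) / (2 * np.pi)
        np.testing.assert_allclose(dist.mass, truth, atol=3e-3)

    def test_non_poisson_bias_matches_simulation(self):
        lam2 = relative_refractory(0.008)
        lam3 = cosine_modulation(0.4, np.pi)
        m = 16
        dist = theoretical_phase_distribution(50.0, lam2, lam3, 10.0, m=m)
        truth_poisson = lam3(dist.bin_centers) / (2 * np.pi)
        # prediction deviates from lambda3/2pi for non-Poisson firing
        assert np.max(np.abs(dist.mass - truth_poisson)) * 2 * np.pi > 0.04
        # and matches a long simulation's spike phase histogram
        gen = GeneratorSpec(lambda1=50.0, lambda2=lam2, lambda3=lam3,
                            freq=10.0, trial_length=2.0, n_trials=600)
        sim = simulate_spike_trains(gen, seed=5)
        h = spike_phase_histogram(sim.spikes, sim.covariates, m)
        n = sim.spikes.n_spikes
        width = 2 * np.pi / m
        se = np.sqrt(dist.mass * width * (1 - dist.mass * width) / n) / width
        assert np.all(np.abs(h.mass - dist.mass) <= 4 * se + 1e-4)

    def test_refinement_stability_in_m(self):
        lam2 = relative_refractory(0.008)
        lam3 = cosine_modulation(0.4, np.pi)
        d32 = theoretical_phase_distribution(50.0, lam2, lam3, 10.0, m=32)
        d64 = theoretical_phase_distribution(50.0, lam2, lam3, 10.0, m=64)
        coarse = d64.mass.reshape(32, 2).mean(axis=1)
        np.testing.assert_allclose(coarse, d32.mass, atol=0.02 / (2 * np.pi))

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            theoretical_phase_distribution(20.0, None, None, 10.0, m=8)


class TestMise:
    def test_zero_error_for_perfect_estimate(self):
        phi = np.linspace(-np.pi, np.pi, 100)
        truth = 1 + 0.4 * np.cos(phi)
        mise, var, b2 = _mise_decomposition(np.tile(truth, (5, 1)), truth, phi)
        assert mise == pytest.approx(0.0, abs=1e-12)

    def test_variance_plus_bias_sq_equals_mise(self):
        rng = np.random.default_rng(0)
        phi = np.linspace(-np.pi, np.pi, 100)
        truth = 1 + 0.4 * np.cos(phi)
        est = truth + 0.2 + 0.1 * rng.standard_normal((20, 100))
        mise, var, b2 = _mise_decomposition(est, truth, phi)
        assert var + b2 == pytest.approx(mise, rel=1e-6)

    def test_histogram_bias_exceeds_glm_in_non_poisson_regime(self):
        # with history effects present, the spike
        # phase histogram's MISE stays above the GLM's as trials grow
        lam3 = cosine_modulation(0.4, np.pi)
        scenario = GeneratorSpec(lambda1=50.0,
                                 lambda2=relative_refractory(0.008),
                                 lambda3=lam3, freq=10.0, trial_length=2.0,
                                 n_trials=40)
        out = compare_estimators(lam3, scenario, trial_counts=[40],
                                 n_datasets=5, seed=6,
                                 histogram_bins=(8, 16, 24))
        hist = next(o for o in out if o.method == "histogram")
        glm = next(o for o in out if o.method == "glm")
        assert hist.mise > glm.mise
        assert hist.bias_sq_component > glm.bias_sq_component
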