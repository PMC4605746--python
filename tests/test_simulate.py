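import numpy as np
import pytest
from scipy import stats

import oscsync as osc
from oscsync.simulate import (GeneratorSpec, inject_synchrony,
                              lags_from_counts, make_oscillation,
                              simulate_spike_trains,
                              simulate_spike_trains_ogata)
from oscsync.scenarios import cosine_modulation, independent_pair
from oscsync.synchrony import _predict_from_bin_expectations


class TestOscillation:
    def test_phase_advances_f_cycles(self):
        covs = make_oscillation(40.0, 2.0, 1e-3, 1, initial_phase=0.0)
        unwrapped = np.unwrap(covs[0].phase)
        cycles = (unwrapped[-1] - unwrapped[0]) / (2 * np.pi)
        assert cycles == pytest.approx(40.0 * 2.0, rel=1e-3)

    def test_fixed_initial_phase_at_half_period(self):
        f = 25.0  # half-period = 20 ms lands exactly on a bin edge
        covs = make_oscillation(f, 2.0, 1e-3, 1, initial_phase=0.0)
        k = int(round(1 / (2 * f) / 1e-3))
        assert abs(covs[0].phase[k]) == pytest.approx(np.pi, abs=1e-6)

    def test_uniform_initial_phases_by_ks(self):
        covs = make_oscillation(40.0, 0.1, 1e-3, 1000, "uniform", seed=0)
        phi0 = np.array([c.phase[0] for c in covs])
        u = (phi0 + np.pi) / (2 * np.pi)
        assert stats.kstest(u, "uniform").pvalue > 0.01


class TestGeneration:
    def test_seed_determinism_byte_for_byte(self):
        gen = GeneratorSpec(lambda1=25.0, lambda3=cosine_modulation(0.4),
                            n_trials=5)
        a = simulate_spike_trains(gen, seed=7)
        b = simulate_spike_trains(gen, seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)
        for tid in a.spikes.trials:
            np.testing.assert_array_equal(a.spikes.trials[tid],
                                          b.spikes.trials[tid])

    def test_homogeneous_poisson_count_dispersion(self):
        gen = GeneratorSpec(lambda1=25.0, trial_length=2.0, n_trials=400)
        sim = simulate_spike_trains(gen, seed=1)
        counts = sim.counts.sum(axis=1)
        assert counts.mean() == pytest.approx(50.0, abs=4 * 50 ** 0.5 / 20)
        # binomial thinning at p = lambda*dt makes variance slightly sub-Poisson
        assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.15)

    def test_hard_refractory_forbids_short_isis(self):
        def lam2(tau):
            return np.where(np.asarray(tau) < 0.003, 1e-12, 1.0)

        gen = GeneratorSpec(lambda1=60.0, lambda2=lam2, n_trials=30)
        sim = simulate_spike_trains(gen, seed=2)
        isis = np.concatenate([np.diff(t) for t in sim.spikes.trials.values()])
        assert isis.min() >= 0.003
        assert isis.std() / isis.mean() < 1.0  # more regular than Poisson

    def test_preferred_phase_matches_circular_mean(self):
        phi_star = 1.0
        gen = GeneratorSpec(lambda1=20.0, lambda3=cosine_modulation(0.6, phi_star),
                            freq=40.0, n_trials=100)
        sim = simulate_spike_trains(gen, seed=3)
        phases = []
        for i, (tid, times) in enumerate(sim.spikes.trials.items()):
            cov = sim.covariates[i]
            idx = np.minimum((times / cov.dt).astype(int), len(cov.phase) - 1)
            phases.append(cov.phase[idx])
        z = np.exp(1j * np.concatenate(phases)).mean()
        assert np.angle(z) == pytest.approx(phi_star, abs=0.1)

    def test_rate_too_high_for_bin_width_rejected(self):
        gen = GeneratorSpec(lambda1=1500.0, n_trials=1)
        with pytest.raises(ValueError, match="reduce dt"):
            simulate_spike_trains(gen, seed=0)

    def test_discrete_and_ogata_generators_agree_on_rate_and_isi(self):
        gen = GeneratorSpec(lambda1=30.0,
                            lambda2=lambda tau: 1 - np.exp(-np.asarray(tau) / 0.004),
                            n_trials=60)
        d = simulate_spike_trains(gen, seed=4)
        c = simulate_spike_trains_ogata(gen, seed=5)
        rd, rc = d.spikes.mean_rate(), c.spikes.mean_rate()
        assert rd == pytest.approx(rc, rel=0.08)
        isi_d = np.concatenate([np.diff(t) for t in d.spikes.trials.values()])
        isi_c = np.concatenate([np.diff(t) for t in c.spikes.trials.values()])
        assert stats.ks_2samp(isi_d, isi_c).pvalue > 0.01

    def test_lags_from_counts_matches_bin_spikes(self):
        gen = GeneratorSpec(lambda1=25.0, n_trials=3)
        sim = simulate_spike_trains(gen, seed=6)
        from oscsync.spikedata import bin_spikes
        d_direct = sim.design()
        d_rebinned = bin_spikes(sim.spikes, bin_width=1e-3)
        np.testing.assert_array_equal(d_direct.counts, d_rebinned.counts)
        np.testing.assert_allclose(d_direct.last_spike_lag,
                                   d_rebinned.last_spike_lag, atol=1e-12)


class TestInjection:
    @staticmethod
    def _pair(n_trials=20, seed=0):
        rng = np.random.default_rng(seed)
        genA, genB = independent_pair(25.0, 2.0, n_trials)
        shared = make_oscillation(40.0, 2.0, 1e-3, n_trials, "uniform",
                                  seed=int(rng.integers(2 ** 31)))
        simA = simulate_spike_trains(genA, int(rng.integers(2 ** 31)), "A",
                                     shared)
        simB = simulate_spike_trains(genB, int(rng.integers(2 ** 31)), "B",
                                     shared)
        return simA, simB

    def test_zeta_one_keeps_all_nonsync_spikes(self):
        simA, simB = self._pair()
        spA, spB = inject_synchrony(simA, simB, 1.0, seed=1)
        # thinning probability is exactly 1 at zeta = 1: rates match closely
        assert spA.n_spikes == pytest.approx(simA.spikes.n_spikes, rel=0.02)
        assert spB.n_spikes == pytest.approx(simB.spikes.n_spikes, rel=0.02)

    def test_marginal_rates_preserved(self):
        rates_in, rates_out = [], []
        for s in range(8):
            simA, simB = self._pair(seed=s)
            spA, _ = inject_synchrony(simA, simB, 1.4, seed=100 + s)
            rates_in.append(simA.spikes.mean_rate())
            rates_out.append(spA.mean_rate())
        diff = np.array(rates_out) - np.array(rates_in)
        se = np.std(diff) / np.sqrt(len(diff))
        assert abs(diff.mean()) <= 3 * se + 0.05

    def test_mean_zeta_hat_equals_injected_zeta(self):
        zs = []
        for s in range(25):
            simA, simB = self._pair(seed=200 + s)
            spA, spB = inject_synchrony(simA, simB, 1.4, seed=300 + s)
            n_obs = osc.count_observed_sync(spA, spB, convention="binned")
            n_pred = _predict_from_bin_expectations(
                simA.intensity * 1e-3, simB.intensity * 1e-3, 1e-3, 5e-3)
            zs.append(n_obs / n_pred)
        se = np.std(zs) / np.sqrt(len(zs))
        assert np.mean(zs) == pytest.approx(1.4, abs=3 * se)

    def test_infeasible_zeta_rejected(self):
        simA, simB = self._pair()
        with pytest.raises(ValueError, match="thinning|probability"):
            inject_synchrony(simA, simB, 500.0, seed=1)


def test_empirical_psth_converges_to_generator_rate():
    gen = GeneratorSpec(lambda1=lambda t: 25.0 * (1 + 0.4 * np.sin(2 * np.pi * np.asarray(t))),
                        n_trials=1000, trial_length=1.0)
    sim = simulate_spike_trains(gen, seed=8)
    psth = sim.counts.mean(axis=0) / 1e-3
    # coarse-bin the PSTH to 50 ms for a stable comparison
    coarse = psth.reshape(20, 50).mean(axis=1)
    t_mid = (np.arange(20) + 0.5) * 0.05
    truth = 25.0 * (1 + 0.4 * np.sin(2 * np.pi * t_mid))
    se = np.sqrt(truth / (1e-3 * 50 * 1000))
    assert np.all(np.abs(coarse - truth) < 4 * se)
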