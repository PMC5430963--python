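"""Volley-driven model without leak: spike order, signals, weight rule."""

import math

import numpy as np
import pytest
from scipy import stats

from sln import analytics as A
from sln.sif import (DisconnectedNeuronError, SifNeuronParams,
                     SifPlasticityParams, SynapsePopulation, VolleyConfig,
                     assign_signals, run_sif, sample_volley,
                     signal_frequency_mc, update_trace_and_weights)


def _binary_pop(d, d_s, params):
    w = np.full(d, params.w_w)
    w[:d_s] = params.w_s
    return SynapsePopulation(w, params.M, w_w=params.w_w)


class TestSampleVolley:
    def test_threshold_exactly_met_fires_at_last_strong(self, rng):
        params = SifPlasticityParams()
        pop = _binary_pop(20, 10, params)
        out = sample_volley(VolleyConfig(d=20), pop, SifNeuronParams(), rng)
        assert out.post_spiked
        # the crossing arrival is the 10th strong arrival
        strong_before = np.sum(pop.weights[out.arrival_order[:out.post_rank + 1]] > 0)
        assert strong_before == 10
        assert pop.weights[out.arrival_order[out.post_rank]] == 1.0

    def test_subthreshold_population_never_fires(self, rng):
        params = SifPlasticityParams()
        pop = _binary_pop(100, 5, params)
        out = sample_volley(VolleyConfig(), pop, SifNeuronParams(), rng)
        assert not out.post_spiked and out.post_rank is None

    def test_post_rank_is_theta_v_th_strong_arrival(self, rng):
        """With p_r = 1 and binary weights, the postsynaptic spike always
        rides on the theta_v-th strong arrival."""
        params = SifPlasticityParams()
        nrn = SifNeuronParams()
        pop = _binary_pop(100, 40, params)
        for _ in range(50):
            out = sample_volley(VolleyConfig(), pop, nrn, rng)
            w_in_order = pop.weights[out.arrival_order]
            assert w_in_order[:out.post_rank + 1].sum() == nrn.theta_v

    def test_firing_probability_matches_binomial_tail(self):
        params = SifPlasticityParams()
        nrn = SifNeuronParams()
        cfg = VolleyConfig(p_r=0.5)
        pop = _binary_pop(100, 40, params)
        rng = np.random.default_rng(7)
        n = 20_000
        fired = sum(sample_volley(cfg, pop, nrn, rng).post_spiked
                    for _ in range(n)) / n
        p_exact = float(stats.binom.sf(9, 40, 0.5))
        se = math.sqrt(p_exact * (1 - p_exact) / n)
        assert fired == pytest.approx(p_exact, abs=3 * se)

    def test_gaussian_rank_sigma0_is_index_order(self, rng):
        params = SifPlasticityParams()
        pop = _binary_pop(30, 15, params)
        cfg = VolleyConfig(d=30, order_model="gaussian_rank", sigma_Z=0.0)
        out = sample_volley(cfg, pop, SifNeuronParams(), rng)
        assert np.array_equal(out.arrival_order, np.arange(30))

    def test_gaussian_rank_large_sigma_is_uniform(self):
        """Rank of the first synapse is chi-square-uniform for sigma_Z >> 1."""
        params = SifPlasticityParams()
        d = 10
        pop = _binary_pop(d, d, params)
        cfg = VolleyConfig(d=d, order_model="gaussian_rank", sigma_Z=50.0)
        rng = np.random.default_rng(3)
        counts = np.zeros(d)
        n = 4000
        for _ in range(n):
            out = sample_volley(cfg, pop, SifNeuronParams(theta_v=d), rng)
            counts[np.flatnonzero(out.arrival_order == 0)[0]] += 1
        chi2 = ((counts - n / d) ** 2 / (n / d)).sum()
        assert chi2 < stats.chi2.ppf(0.999, d - 1)


class TestSignals:
    def test_no_postsynaptic_spike_no_signals(self, rng):
        params = SifPlasticityParams()
        pop = _binary_pop(100, 5, params)
        out = sample_volley(VolleyConfig(), pop, SifNeuronParams(), rng)
        syn, sig = assign_signals(out, pop)
        assert syn.size == 0 and sig.size == 0

    def test_exact_threshold_all_strong_potentiate(self, rng):
        params = SifPlasticityParams()
        pop = _binary_pop(10, 10, params)
        out = sample_volley(VolleyConfig(d=10), pop, SifNeuronParams(), rng)
        syn, sig = assign_signals(out, pop)
        assert sig[np.isin(syn, np.arange(10))].all()

    def test_signal_conservation(self, rng):
        """Each transmitting synapse gets exactly one signal iff the neuron
        fired; order splits them into 1s then 0s."""
        params = SifPlasticityParams()
        pop = _binary_pop(100, 30, params)
        cfg = VolleyConfig(p_r=0.6)
        for _ in range(30):
            out = sample_volley(cfg, pop, SifNeuronParams(), rng)
            syn, sig = assign_signals(out, pop)
            if out.post_spiked:
                assert np.array_equal(np.sort(syn),
                                      np.flatnonzero(out.transmitted))
                assert sig.sum() == out.post_rank + 1
                assert np.all(np.diff(sig.astype(int)) <= 0)
            else:
                assert syn.size == 0

    def test_strong_signal_fraction_is_theta_over_ds(self):
        # deterministic transmission: exactly theta_v of d_s strong get 1
        mc = signal_frequency_mc(20, 100, 10, 1.0, 5000, seed=1)
        assert mc["freq_strong"] == pytest.approx(0.5, abs=1e-12)
        assert mc["freq_weak"] == pytest.approx(
            A.p_early(20, 10, 1.0, strong=False), abs=3 * mc["se_weak"])


class TestWeightUpdate:
    def _due_pop(self, params, weights):
        pop = SynapsePopulation(np.asarray(weights, float), params.M,
                                w_w=params.w_w)
        return pop

    def _force_update(self, pop, params, signal, rng):
        events = []
        for _ in range(params.cadence):
            syn = np.arange(pop.d, dtype=np.int64)
            sig = np.full(pop.d, signal, dtype=np.uint8)
            events += update_trace_and_weights(pop, syn, sig, params, rng)
        return events

    def test_saturated_trace_flips_weak_to_strong(self, rng):
        params = SifPlasticityParams(p_w_to_s=1.0)
        pop = self._due_pop(params, [0.0, 1.0])
        events = self._force_update(pop, params, 1, rng)
        assert pop.weights[0] == params.w_s
        assert pop.weights[1] == params.w_s  # already strong, no event for it
        assert events == [(0, 0.0, 1.0)]

    def test_trace_inside_band_never_changes_weight(self, rng):
        # alternate signals so m = 0.487 inside [0.26, 0.72]
        params = SifPlasticityParams(p_s_to_w=1.0, p_w_to_s=1.0)
        pop = self._due_pop(params, [0.0, 1.0])
        for k in range(params.M):
            syn = np.arange(2, dtype=np.int64)
            sig = np.full(2, k % 2, dtype=np.uint8)
            update_trace_and_weights(pop, syn, sig, params, rng)
        assert np.array_equal(pop.weights, [0.0, 1.0])

    def test_additive_and_multiplicative_arithmetic(self, rng):
        for scheme, expected in (("additive", 9.0), ("multiplicative", 8.0)):
            params = SifPlasticityParams(weight_scheme=scheme, p_s_to_w=1.0,
                                         omega=1.0, c_d=0.2, zeta=0.0)
            pop = self._due_pop(params, [10.0])
            self._force_update(pop, params, 0, rng)
            assert pop.weights[0] == pytest.approx(expected)

    def test_additive_depression_clips_at_zero(self, rng):
        params = SifPlasticityParams(weight_scheme="additive", p_s_to_w=1.0,
                                     omega=1.0)
        pop = self._due_pop(params, [0.5])
        self._force_update(pop, params, 0, rng)
        assert pop.weights[0] == 0.0

    def test_first_update_needs_full_cadence(self, rng):
        params = SifPlasticityParams(p_s_to_w=1.0)
        pop = self._due_pop(params, [1.0])
        for _ in range(params.M - 1):
            update_trace_and_weights(pop, np.array([0]),
                                     np.array([0], dtype=np.uint8), params,
                                     rng)
        assert pop.weights[0] == 1.0  # not yet evaluated
        update_trace_and_weights(pop, np.array([0]),
                                 np.array([0], dtype=np.uint8), params, rng)
        assert pop.weights[0] == 0.0

    def test_trace_stays_in_unit_interval(self, rng):
        params = SifPlasticityParams()
        pop = _binary_pop(100, 30, params)
        cfg = VolleyConfig(p_r=0.8)
        nrn = SifNeuronParams()
        for _ in range(100):
            out = sample_volley(cfg, pop, nrn, rng)
            syn, sig = assign_signals(out, pop)
            update_trace_and_weights(pop, syn, sig, params, rng)
        m = pop.traces()
        m = m[~np.isnan(m)]
        assert np.all((m >= 0.0) & (m <= 1.0))


class TestRunSif:
    def test_static_when_update_probabilities_zero(self, sif_defaults):
        cfg, nrn, _ = sif_defaults
        params = SifPlasticityParams(p_s_to_w=0.0, p_w_to_s=0.0)
        res = run_sif(cfg, nrn, params, 20, init_d_s=30, seed=0)
        assert np.all(res.n_strong == 30)

    def test_terminal_state_independent_of_initialization(self, sif_defaults):
        cfg, nrn, params = sif_defaults
        terminals = {}
        for init in (20, 80):
            vals = [run_sif(cfg, nrn, params, 80, init_d_s=init,
                            seed=s).n_strong[-1] for s in range(6)]
            terminals[init] = (np.mean(vals), np.std(vals, ddof=1))
        gap = abs(terminals[20][0] - terminals[80][0])
        assert gap <= 3 * max(terminals[20][1], terminals[80][1], 1.0)

    def test_depression_only_does_not_undershoot(self, sif_defaults):
        cfg, nrn, _ = sif_defaults
        params = SifPlasticityParams(p_w_to_s=0.0)
        res = run_sif(cfg, nrn, params, 80, init_d_s=30, seed=5)
        assert np.all(res.n_strong >= nrn.theta_v)
        assert 15 <= res.n_strong[-1] <= 25

    def test_population_size_conserved_and_weights_nonnegative(self,
                                                               sif_defaults):
        cfg, nrn, params = sif_defaults
        res = run_sif(cfg, nrn, params, 40, init_d_s=50, seed=2)
        assert len(res.final_weights) == cfg.d
        assert np.all(res.final_weights >= 0)

    def test_disconnected_population_aborts(self, sif_defaults):
        cfg, nrn, params = sif_defaults
        with pytest.raises(DisconnectedNeuronError):
            run_sif(cfg, nrn, params, 10, init_d_s=5, seed=0)

    def test_reproducible_given_seed(self, sif_defaults):
        cfg, nrn, params = sif_defaults
        a = run_sif(cfg, nrn, params, 30, init_d_s=40, seed=9)
        b = run_sif(cfg, nrn, params, 30, init_d_s=40, seed=9)
        assert np.array_equal(a.n_strong, b.n_strong)
        assert np.array_equal(a.final_weights, b.final_weights)

    def test_probabilistic_cadence_recomputed(self, sif_defaults):
        """p_r < 1 stretches the update cadence to ~2M/(p_r Pr[fire])."""
        _, nrn, params = sif_defaults
        cfg = VolleyConfig(p_r=0.5)
        res = run_sif(cfg, nrn, params, 5, init_d_s=40, seed=1)
        expected_L = math.ceil(2 * params.M / (0.5 * A.prob_fire(40, 10, 0.5)))
        assert res.volley_index[0] == expected_L
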