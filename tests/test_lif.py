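"""Conductance LIF model: membrane, input, DSP bookkeeping, traces."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from sln import analytics as A
from sln.lif import (DspState, LifParams, LifSynapseState, MembraneState,
                     RULE_PRESETS, SlnRuleParams, UpDownConfig,
                     DisconnectedNeuronError, apply_weight_rule,
                     generate_input, latency_stats, run_lif, scale_windows,
                     simulate_membrane, step_membrane, up_onsets,
                     update_dsp, update_trace)


class TestMembrane:
    def test_leak_only_relaxes_monotonically_to_rest(self):
        p = LifParams()
        state = MembraneState(v=p.V_r)  # -60 above rest -70
        vs = []
        for _ in range(1500):
            state, spiked = step_membrane(state, 0.0, p)
            assert not spiked
            vs.append(state.v)
        assert all(a >= b for a, b in zip(vs[:-1], vs[1:]))
        assert vs[-1] == pytest.approx(p.E_L, abs=0.01)

    def test_conductance_decays_with_tau_syn(self):
        p = LifParams()
        state = MembraneState(v=p.E_L, g_e=1.0)
        state, _ = step_membrane(state, 0.0, p)
        state, _ = step_membrane(state, 0.0, p)
        assert state.g_e == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_membrane_bounded_between_reversal_potentials(self):
        p = LifParams()
        rng = np.random.default_rng(0)
        arr = np.sort(rng.uniform(0, 30, 40))
        spikes, v = simulate_membrane(arr, np.full(40, 40.0), p, 60.0,
                                      record_v=True)
        assert v.min() >= p.E_L - 1e-9
        assert v.max() <= p.E_e

    def test_coarse_grid_matches_fine_grid_oracle(self):
        """0.1 ms production grid against a 0.01 ms reference integration."""
        p = LifParams()
        rng = np.random.default_rng(42)
        counts = {0.1: [], 0.01: []}
        lats = {0.1: [], 0.01: []}
        for trial in range(12):
            arr = np.sort(rng.uniform(1.0, 31.0, rng.poisson(24)))
            w = np.full(arr.size, 40.0)
            for dt in (0.1, 0.01):
                sp, _ = simulate_membrane(arr, w, p, 80.0, dt=dt)
                counts[dt].append(len(sp))
                if len(sp):
                    lats[dt].append(sp[0])
        se = np.std(counts[0.01], ddof=1) / math.sqrt(len(counts[0.01]))
        assert np.mean(counts[0.1]) == pytest.approx(np.mean(counts[0.01]),
                                                     abs=max(3 * se, 0.25))
        assert np.mean(lats[0.1]) == pytest.approx(np.mean(lats[0.01]),
                                                   abs=0.2)


class TestInputGeneration:
    def test_up_phase_poisson_mean(self, rng):
        cfg = UpDownConfig(d=200)
        duration = 50 * (cfg.T_U + cfg.T_D) + cfg.T_D
        spikes, _ = generate_input(cfg, duration, rng)
        total = sum(len(s) for s in spikes)
        n_phase_neuron = 200 * len(up_onsets(cfg, duration - cfg.T_U))
        mean = total / n_phase_neuron
        lam = cfg.lambda_U / 1000.0 * cfg.T_U  # 1.2 expected
        se = math.sqrt(lam / n_phase_neuron)
        assert mean == pytest.approx(lam, abs=3 * se)

    def test_silent_down_phases(self, rng):
        cfg = UpDownConfig(lambda_D=0.0)
        spikes, _ = generate_input(cfg, 5000.0, rng)
        onsets = up_onsets(cfg, 5000.0)
        for s in spikes:
            in_up = np.zeros(len(s), dtype=bool)
            for on in onsets:
                in_up |= (s >= on) & (s < on + cfg.T_U)
            assert in_up.all()

    def test_phase_shifts_uniform(self, rng):
        """Estimated per-neuron onset delays follow Uniform[0, sigma]."""
        cfg = UpDownConfig(d=100, sigma_shift=10.0, nu=0.0)
        duration = 200 * (cfg.T_U + cfg.T_D)
        spikes, _ = generate_input(cfg, duration, rng)
        onsets = up_onsets(cfg, duration)
        shifts = []
        for s in spikes:
            rel = [s[(s >= on) & (s < on + cfg.T_U + cfg.sigma_shift)] - on
                   for on in onsets]
            first = [r[0] for r in rel if r.size]
            shifts.append(min(first))
        stat = stats.kstest(shifts, "uniform",
                            args=(0, cfg.sigma_shift)).pvalue
        assert stat > 0.01

    def test_constant_rate_mode(self, rng):
        cfg = UpDownConfig(mode="constant_rate", lambda_U=40.0, d=50)
        spikes, _ = generate_input(cfg, 20000.0, rng)
        total = sum(len(s) for s in spikes)
        lam = 40.0 / 1000.0 * 20000.0 * 50
        assert total == pytest.approx(lam, abs=3 * math.sqrt(lam))


class TestDspBookkeeping:
    def test_blocking_window(self):
        params = SlnRuleParams()
        dsp = DspState()
        assert update_dsp(dsp, 5.0, params) is True
        assert update_dsp(dsp, 20.0, params) is False
        dsp2 = DspState()
        assert update_dsp(dsp2, 5.0, params) is True
        assert update_dsp(dsp2, 45.0, params) is True  # 45 > 5 + 35

    def test_at_most_one_dsp_per_up_phase(self):
        """T_burst=35 >= T_U=30 with T_D=50: never two DSPs in one phase."""
        lif, cfg = LifParams(), UpDownConfig()
        rule = replace(RULE_PRESETS["r13"], p_s_to_w=0.0, p_w_to_s=0.0)
        duration = 100 * 80.0
        res = run_lif(lif, cfg, rule, duration, init_d_s=30, seed=4)
        dsp_t = res.post_times[res.post_is_dsp.astype(bool)]
        assert np.all(np.diff(dsp_t) >= rule.T_burst - 1e-9)
        for on in up_onsets(cfg, duration):
            n = np.count_nonzero((dsp_t >= on) & (dsp_t < on + cfg.T_U))
            assert n <= 1


class TestTraceUpdates:
    def test_dsp_potentiation_applied_per_pre_spike(self):
        params = SlnRuleParams()
        dsp = DspState()
        syn = LifSynapseState(weight=1.0)
        update_trace(syn, ("pre", 3.0), dsp, params)
        update_trace(syn, ("pre", 7.0), dsp, params)
        update_dsp(dsp, 10.0, params)
        n = update_trace(syn, ("post", 10.0), dsp, params)
        assert n == 2
        assert syn.m == pytest.approx(1 + 0.95 * 1.0)

    def test_late_pre_spike_depresses_once(self):
        params = SlnRuleParams()
        dsp = DspState()
        syn = LifSynapseState(weight=40.0)
        update_dsp(dsp, 10.0, params)
        update_trace(syn, ("post", 10.0), dsp, params)
        update_trace(syn, ("pre", 20.0), dsp, params)
        assert syn.m == pytest.approx(-1.0)

    def test_all_to_all_depression_counts_every_pair(self):
        params = SlnRuleParams(pairing="all_to_all")
        dsp = DspState()
        syn = LifSynapseState(weight=40.0)
        for t in (5.0, 9.0):
            update_dsp(dsp, t, params)
            update_trace(syn, ("post", t), dsp, params)
        update_trace(syn, ("pre", 12.0), dsp, params)
        assert syn.m == pytest.approx(-1 + 0.95 * -1.0)

    def test_non_dsp_post_is_inert_in_dsp_mode(self):
        params = SlnRuleParams()
        dsp = DspState()
        syn = LifSynapseState(weight=1.0)
        update_trace(syn, ("pre", 8.0), dsp, params)
        update_dsp(dsp, 10.0, params)
        update_trace(syn, ("post", 10.0), dsp, params)
        m0 = syn.m
        update_dsp(dsp, 14.0, params)  # blocked, not a DSP
        n = update_trace(syn, ("post", 14.0), dsp, params)
        assert n == 0 and syn.m == m0

    def test_weight_rule_thresholds(self, rng):
        params = replace(RULE_PRESETS["r13"], p_s_to_w=1.0, p_w_to_s=1.0)
        syn = LifSynapseState(weight=40.0, m=-20.0)
        assert apply_weight_rule(syn, params, rng) == (40.0, params.w_w)
        syn = LifSynapseState(weight=40.0, m=0.0)  # inside [theta_D, theta_P]
        assert apply_weight_rule(syn, params, rng) is None

    def test_trace_surrogate_matches_moment_formulas(self, rng):
        """Static Bernoulli signal stream reproduces the attenuated-trace
        mean and variance limits."""
        r, gamma, n, chains = 1 / 3, 0.95, 4000, 12
        m = np.zeros(chains)
        tail = []
        for k in range(n):
            sign = np.where(rng.random(chains) < r, 1.0, -1.0)
            m = sign + gamma * m
            if k >= 500:
                tail.append(m.copy())
        tail = np.asarray(tail)
        ref = A.trace_moments(r, gamma)
        chain_means = tail.mean(axis=0)
        se = chain_means.std(ddof=1) / math.sqrt(chains)
        assert chain_means.mean() == pytest.approx(ref.mean_inf, abs=3 * se)
        chain_vars = tail.var(axis=0)
        se_v = chain_vars.std(ddof=1) / math.sqrt(chains)
        assert chain_vars.mean() == pytest.approx(ref.var_inf, abs=3 * se_v)


class TestRunLif:
    def test_frozen_weights_and_reproducibility(self, lif_defaults):
        lif, cfg, _ = lif_defaults
        rule = replace(RULE_PRESETS["r13"], p_s_to_w=0.0, p_w_to_s=0.0)
        a = run_lif(lif, cfg, rule, 4000.0, init_d_s=25, seed=11)
        b = run_lif(lif, cfg, rule, 4000.0, init_d_s=25, seed=11)
        assert a.n_events_total == 0
        assert np.array_equal(a.post_times, b.post_times)
        assert np.array_equal(a.final_weights, a.initial_weights)

    def test_trace_bounded_by_attenuation_fixpoint(self, lif_defaults):
        lif, cfg, _ = lif_defaults
        rule = replace(RULE_PRESETS["r13"], p_s_to_w=0.0, p_w_to_s=0.0)
        res = run_lif(lif, cfg, rule, 6000.0, init_d_s=40, seed=2,
                      trace_sample_ms=80.0)
        bound = 1.0 / (1.0 - rule.gamma)
        assert np.all(np.abs(res.trace_samples) <= bound + 1e-9)

    def test_spikes_per_up_tracks_inverse_latency(self, lif_defaults):
        """After convergence the spike count per UP phase is ~1/r_hat."""
        lif, cfg, _ = lif_defaults
        rule = RULE_PRESETS["r13"]
        dur = 300 * 80.0
        res = run_lif(lif, cfg, rule, dur, init_d_s=25, seed=8)
        st = latency_stats(res.post_times, cfg, dur, t_start=dur / 2)
        assert st.spikes_per_up == pytest.approx(1.0 / st.r_hat, rel=0.30)

    def test_constant_rate_has_no_latency(self, lif_defaults):
        lif, _, _ = lif_defaults
        cfg = UpDownConfig(mode="constant_rate")
        rule = replace(RULE_PRESETS["r12"], p_s_to_w=0.0, p_w_to_s=0.0)
        res = run_lif(lif, cfg, rule, 3000.0, init_d_s=25, seed=1)
        st = latency_stats(res.post_times, cfg, 3000.0)
        assert st.r_hat is None and st.spikes_per_up is None
        assert st.rate > 0

    def test_silent_neuron_watchdog(self, lif_defaults):
        lif, cfg, _ = lif_defaults
        rule = replace(RULE_PRESETS["r13"], p_s_to_w=0.0, p_w_to_s=0.0)
        with pytest.raises(DisconnectedNeuronError):
            # 3 strong synapses cannot reach threshold
            run_lif(lif, cfg, rule, 3000.0, init_d_s=3, seed=0,
                    abort_if_silent_ms=1000.0)

    def test_scale_windows_identity_at_default_up_length(self):
        rule = RULE_PRESETS["r13"]
        scaled = scale_windows(rule, 30.0)
        assert scaled == rule

    def test_kernel_agrees_with_event_free_reference(self):
        """Full simulator vs the step-by-step reference membrane on the same
        arrival stream (plasticity off, no noise)."""
        lif = LifParams()
        cfg = UpDownConfig(nu=0.0)
        rule = replace(RULE_PRESETS["r13"], p_s_to_w=0.0, p_w_to_s=0.0)
        res = run_lif(lif, cfg, rule, 2000.0, init_d_s=25, seed=6)
        arr = res.pre_times + lif.t_delay
        w = res.initial_weights[res.pre_ids]
        ref_spikes, _ = simulate_membrane(arr, w, lif, 2000.0)
        # near-threshold crossings may land one step apart (last-ulp exp
        # differences between the jitted and interpreted transcendentals)
        assert abs(len(res.post_times) - len(ref_spikes)) <= 1
        n = min(len(res.post_times), len(ref_spikes))
        assert np.median(np.abs(res.post_times[:n] - ref_spikes[:n])) <= 0.5
        assert res.post_times[0] == pytest.approx(ref_spikes[0], abs=0.2)
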