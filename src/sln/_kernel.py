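"""Time-stepped core loop of the conductance-based LIF simulator.

Written in a numba-njit-compatible subset of Python and jitted at import
when numba is available; the same function runs as plain Python otherwise.
All state is passed as flat arrays and scalars.

Per 0.1 ms step, in order: presynaptic plasticity events (at spike emission
times), conductance jumps (at arrival times, emission + delay), membrane
integration by exponential Euler with the step's conductance frozen, then
threshold / distinguished-spike / potentiation logic. The synaptic
conductance is decayed by the exact factor exp(-dt/tau_syn) once per step.
"""

import math

import numpy as np


def _core(n_steps, dt,
          C_m, E_L, g_L, E_e, tau_syn, V_th, V_r, tau_ref,
          pre_t, pre_id, arr_t, nrn_off, nrn_t, noise_t, w_n,
          gamma, T_burst, T_early, T_late, theta_D, theta_P,
          p_s_to_w, p_w_to_s, w_w,
          dist_kind, dist_p1, dist_p2, dist_p3,
          pairing_dsp, seed,
          weights, traces,
          post_t, post_dsp, ev_t, ev_syn, ev_old, ev_new,
          trace_sample_every, trace_samples, v_out):
    np.random.seed(seed)
    d = weights.shape[0]
    decay = math.exp(-dt / tau_syn)
    # charge-exact mean of the decaying conductance over one step; with
    # tau_syn comparable to dt, freezing the post-jump value instead would
    # overestimate the delivered charge by dt/(tau_syn*(1-decay))
    g_scale = tau_syn * (1.0 - decay) / dt
    v = E_L
    g_e = 0.0
    ref_until = -1.0
    burst_until = -1.0e18
    dsp_time = -1.0e18
    ip = 0
    ia = 0
    inz = 0
    n_post = 0
    n_ev = 0
    n_samp = 0
    npre = pre_t.shape[0]
    nnz = noise_t.shape[0]
    maxpost = post_t.shape[0]
    maxev = ev_t.shape[0]
    record_v = v_out.shape[0] > 0
    # ring buffer of recent postsynaptic spike times (all_to_all pairing)
    rp_cap = 64
    recent_posts = np.full(rp_cap, -1.0e18)
    rp_head = 0
    n_recent = 0

    for k in range(n_steps):
        t0 = k * dt
        t1 = t0 + dt

        # presynaptic spikes (emission times) in [t0, t1): depression check.
        # dsp pairing: one depression per pre spike inside the late window of
        # the last DSP; all_to_all: one per (pre, post) pair within T_late.
        while ip < npre and pre_t[ip] < t1:
            tau = pre_t[ip]
            j = pre_id[ip]
            if pairing_dsp == 1:
                n_dep = 1 if (tau > dsp_time and tau - dsp_time <= T_late) else 0
            else:
                n_dep = 0
                for q in range(n_recent):
                    tp = recent_posts[(rp_head - 1 - q) % rp_cap]
                    if tau - tp > T_late:
                        break
                    if tau > tp:
                        n_dep += 1
            for _ in range(n_dep):
                traces[j] = -1.0 + gamma * traces[j]
                m = traces[j]
                if m < theta_D:
                    if weights[j] > w_w and np.random.random() < p_s_to_w:
                        if n_ev < maxev:
                            ev_t[n_ev] = tau
                            ev_syn[n_ev] = j
                            ev_old[n_ev] = weights[j]
                            ev_new[n_ev] = w_w
                        n_ev += 1
                        weights[j] = w_w
                elif m > theta_P:
                    if weights[j] <= w_w and np.random.random() < p_w_to_s:
                        if dist_kind == 0:
                            nw = dist_p1
                        elif dist_kind == 1:
                            nw = np.random.normal(dist_p1, dist_p2)
                        else:
                            mu = dist_p1 if np.random.random() < 0.5 else dist_p2
                            nw = np.random.normal(mu, dist_p3)
                        if nw < 0.0:
                            nw = 0.0
                        if n_ev < maxev:
                            ev_t[n_ev] = tau
                            ev_syn[n_ev] = j
                            ev_old[n_ev] = weights[j]
                            ev_new[n_ev] = nw
                        n_ev += 1
                        weights[j] = nw
            ip += 1

        # conductance jumps at arrivals (emission + delay) and noise spikes
        while ia < npre and arr_t[ia] < t1:
            g_e += weights[pre_id[ia]]
            ia += 1
        while inz < nnz and noise_t[inz] < t1:
            g_e += w_n
            inz += 1

        # membrane update (clamped during refractory)
        if t0 >= ref_until:
            g_eff = g_e * g_scale
            gtot = g_L + g_eff
            vinf = (g_L * E_L + g_eff * E_e) / gtot
            v = vinf + (v - vinf) * math.exp(-gtot * dt / C_m)
        else:
            v = V_r
        g_e *= decay
        if record_v:
            v_out[k] = v

        # threshold crossing -> postsynaptic spike at t1
        if t0 >= ref_until and v >= V_th:
            tpost = t1
            is_dsp = 0
            if tpost >= burst_until:
                is_dsp = 1
                burst_until = tpost + T_burst
                dsp_time = tpost
            if n_post < maxpost:
                post_t[n_post] = tpost
                post_dsp[n_post] = is_dsp
            n_post += 1
            if pairing_dsp == 0 or is_dsp == 1:
                # potentiation: one trace update per presynaptic spike in
                # [tpost - T_early, tpost), weight rule after each
                for j in range(d):
                    a = nrn_off[j]
                    b = nrn_off[j + 1]
                    lo = np.searchsorted(nrn_t[a:b], tpost - T_early)
                    hi = np.searchsorted(nrn_t[a:b], tpost)
                    for _ in range(hi - lo):
                        traces[j] = 1.0 + gamma * traces[j]
                        m = traces[j]
                        if m > theta_P:
                            if weights[j] <= w_w and np.random.random() < p_w_to_s:
                                if dist_kind == 0:
                                    nw = dist_p1
                                elif dist_kind == 1:
                                    nw = np.random.normal(dist_p1, dist_p2)
                                else:
                                    mu = (dist_p1 if np.random.random() < 0.5
                                          else dist_p2)
                                    nw = np.random.normal(mu, dist_p3)
                                if nw < 0.0:
                                    nw = 0.0
                                if n_ev < maxev:
                                    ev_t[n_ev] = tpost
                                    ev_syn[n_ev] = j
                                    ev_old[n_ev] = weights[j]
                                    ev_new[n_ev] = nw
                                n_ev += 1
                                weights[j] = nw
                        elif m < theta_D:
                            if weights[j] > w_w and np.random.random() < p_s_to_w:
                                if n_ev < maxev:
                                    ev_t[n_ev] = tpost
                                    ev_syn[n_ev] = j
                                    ev_old[n_ev] = weights[j]
                                    ev_new[n_ev] = w_w
                                n_ev += 1
                                weights[j] = w_w
            recent_posts[rp_head] = tpost
            rp_head = (rp_head + 1) % rp_cap
            if n_recent < rp_cap:
                n_recent += 1
            v = V_r
            ref_until = tpost + tau_ref

        if trace_sample_every > 0 and (k + 1) % trace_sample_every == 0:
            if n_samp < trace_samples.shape[0]:
                for j in range(d):
                    trace_samples[n_samp, j] = traces[j]
                n_samp += 1

    return n_post, n_ev, n_samp


try:  # pragma: no cover - exercised implicitly wherever the kernel runs
    from numba import njit

    core = njit(cache=False)(_core)
    HAS_NUMBA = True
except Exception:  # pragma: no cover
    core = _core
    HAS_NUMBA = False
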