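"""Conductance-based leaky integrate-and-fire model with the SLN rule.

The membrane follows ``C_m dv/dt = -g_L (v - E_L) - g_e (v - E_e)`` with an
exponentially decaying excitatory conductance that jumps by the synaptic
weight at each arrival (emission time + delay). Input neurons fire as
inhomogeneous Poisson processes alternating between DOWN phases (rate
``lambda_D``) and UP phases (rate ``lambda_U``); an extra homogeneous
Poisson noise source of weight ``w_n`` at rate ``nu`` drives the membrane
but is not plastic and generates no learning signal.

Plasticity follows the spike latency normalization rule: the first
postsynaptic spike per burst window is the distinguished spike (DSP); it
triggers one potentiation update ``m <- 1 + gamma m`` per presynaptic spike
in the preceding ``T_early`` window, while presynaptic spikes in the
``T_late`` window after the DSP trigger depression updates
``m <- -1 + gamma m``. The probabilistic weight rule is applied after every
trace update. An ``all_to_all`` pairing mode treats every postsynaptic
spike as an anchor, for comparison.

Integration is exponential Euler on a 0.1 ms grid: exact for the
conductance decay, exact for the membrane ODE with the conductance frozen
over the step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel

__all__ = [
    "LifParams",
    "UpDownConfig",
    "SlnRuleParams",
    "DspState",
    "LifSynapseState",
    "LatencyStats",
    "LifResult",
    "MembraneState",
    "RULE_PRESETS",
    "scale_windows",
    "generate_input",
    "up_onsets",
    "step_membrane",
    "simulate_membrane",
    "update_dsp",
    "update_trace",
    "apply_weight_rule",
    "run_lif",
    "latency_stats",
    "strong_count_trajectory",
    "DisconnectedNeuronError",
]


class DisconnectedNeuronError(RuntimeError):
    """The target neuron stopped firing for the configured watchdog window."""


_STRONG_DISTS = ("point", "normal", "mixture")


@dataclass
class LifParams:
    """Membrane and synapse constants (conductance model defaults)."""

    C_m: float = 250.0        # pF
    E_L: float = -70.0        # mV
    g_L: float = 16.67        # nS
    E_e: float = 0.0          # mV
    tau_syn: float = 0.2      # ms
    t_delay: float = 1.0      # ms
    tau_ref: float = 2.5      # ms
    V_th: float = -55.0       # mV
    V_r: float = -60.0        # mV
    dt: float = 0.1           # ms

    def __post_init__(self) -> None:
        if min(self.tau_syn, self.tau_ref, self.dt) <= 0 or self.C_m <= 0:
            raise ValueError("time constants and C_m must be positive")
        if self.V_r > self.V_th:
            raise ValueError("V_r must not exceed V_th")
        if self.E_L >= self.E_e:
            raise ValueError("E_L must lie below E_e")


@dataclass
class UpDownConfig:
    """UP/DOWN inhomogeneous Poisson input (plus background noise)."""

    d: int = 100
    lambda_U: float = 40.0    # Hz
    lambda_D: float = 0.0     # Hz
    T_U: float = 30.0         # ms
    T_D: float = 50.0         # ms
    nu: float = 1000.0        # Hz
    w_n: float = 1.0          # nS
    sigma_shift: float = 0.0  # ms, per-neuron onset delay ~ Uniform[0, sigma]
    mode: str = "updown"      # or "constant_rate"

    def __post_init__(self) -> None:
        if min(self.lambda_U, self.lambda_D, self.nu) < 0:
            raise ValueError("rates must be >= 0")
        if min(self.T_U, self.T_D) <= 0:
            raise ValueError("phase durations must be positive")
        if self.sigma_shift < 0:
            raise ValueError("sigma_shift must be >= 0")
        if self.mode not in ("updown", "constant_rate"):
            raise ValueError("mode must be 'updown' or 'constant_rate'")


@dataclass
class SlnRuleParams:
    """Plasticity constants of the leaky model.

    ``strong_dist`` selects the strong-weight distribution used when a weak
    synapse potentiates: ``point`` (mass at ``w_s``), ``normal``
    (``Normal(w_s, strong_sd)``), or ``mixture`` (fair coin between
    ``Normal(strong_means[0], strong_sd)`` and
    ``Normal(strong_means[1], strong_sd)``), all truncated at 0.
    """

    gamma: float = 0.95
    T_burst: float = 35.0     # ms
    T_early: float = 35.0     # ms
    T_late: float = 35.0      # ms
    theta_D: float = -14.51
    theta_P: float = 1.48
    p_s_to_w: float = 0.05
    p_w_to_s: float = 0.05
    w_w: float = 1.0          # nS
    w_s: float = 40.0         # nS
    strong_dist: str = "point"
    strong_sd: float = 5.0
    strong_means: tuple[float, float] = (35.0, 45.0)
    pairing: str = "dsp"      # or "all_to_all"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        if min(self.T_burst, self.T_early, self.T_late) <= 0:
            raise ValueError("windows must be positive")
        if self.theta_D > self.theta_P:
            raise ValueError("theta_D must not exceed theta_P")
        for name in ("p_s_to_w", "p_w_to_s"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.strong_dist not in _STRONG_DISTS:
            raise ValueError(f"strong_dist must be one of {_STRONG_DISTS}")
        if self.pairing not in ("dsp", "all_to_all"):
            raise ValueError("pairing must be 'dsp' or 'all_to_all'")

    def _dist_code(self) -> tuple[int, float, float, float]:
        if self.strong_dist == "point":
            return 0, self.w_s, 0.0, 0.0
        if self.strong_dist == "normal":
            return 1, self.w_s, self.strong_sd, 0.0
        return 2, self.strong_means[0], self.strong_means[1], self.strong_sd

    def sample_strong(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw strong weights from the configured distribution."""
        if self.strong_dist == "point":
            w = np.full(size, self.w_s)
        elif self.strong_dist == "normal":
            w = rng.normal(self.w_s, self.strong_sd, size)
        else:
            mu = np.where(rng.random(size) < 0.5, self.strong_means[0],
                          self.strong_means[1])
            w = rng.normal(mu, self.strong_sd)
        return np.maximum(w, 0.0)


def scale_windows(rule: SlnRuleParams, T_U: float,
                  margin: float = 5.0) -> SlnRuleParams:
    """Adapt the DSP windows to an UP-phase length.

    Latency normalization requires exactly one DSP per phase and depression
    coverage of the phase remainder, without either window reaching into a
    neighboring phase: ``T_burst = T_late = T_U + margin`` while ``T_early``
    is left alone (it only needs to span the expected DSP latency
    ``r * T_U``, and must stay shorter than the DOWN phase to avoid counting
    the previous phase's spikes). For the default ``T_U = 30`` this
    reproduces the standard 35 ms windows.
    """
    return replace(rule, T_burst=T_U + margin, T_late=T_U + margin)


# Table-style presets: the two published parameter rows plus the mirrored
# r ~ 2/3 row used by the constant-rate rundown protocol (constructed as the
# reflection of the r=1/3 thresholds about the r=1/2 trace mean of 0).
RULE_PRESETS: dict[str, SlnRuleParams] = {
    "r13": SlnRuleParams(theta_D=-14.51, theta_P=1.48, p_s_to_w=0.05,
                         p_w_to_s=0.05),
    "r12": SlnRuleParams(theta_D=-8.42, theta_P=8.70, p_s_to_w=0.16,
                         p_w_to_s=0.05),
    "r23": SlnRuleParams(theta_D=-1.48, theta_P=14.51, p_s_to_w=0.05,
                         p_w_to_s=0.05),
}


# ---------------------------------------------------------------------------
# input generation


def up_onsets(cfg: UpDownConfig, duration: float) -> np.ndarray:
    """Unshifted UP-phase onset times within [0, duration); the schedule
    starts with a DOWN phase."""
    period = cfg.T_U + cfg.T_D
    n = max(0, math.ceil((duration - cfg.T_D) / period))
    onsets = cfg.T_D + period * np.arange(n)
    return onsets[onsets < duration]


def _poisson_segment(a: float, b: float, rate_hz: float,
                     rng: np.random.Generator) -> np.ndarray:
    if b <= a or rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz / 1000.0 * (b - a))
    return rng.uniform(a, b, n)


def generate_input(cfg: UpDownConfig, duration: float,
                   rng: np.random.Generator
                   ) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-neuron spike-time arrays plus the background-noise spike train.

    Each neuron's rate function is the alternating UP/DOWN schedule delayed
    by its own ``Uniform[0, sigma_shift]`` phase shift; sampling is exact
    piecewise-constant Poisson (counts then uniform placement). In
    ``constant_rate`` mode every neuron fires homogeneously at ``lambda_U``.
    """
    spikes: list[np.ndarray] = []
    if cfg.mode == "constant_rate":
        for _ in range(cfg.d):
            spikes.append(np.sort(_poisson_segment(0.0, duration,
                                                   cfg.lambda_U, rng)))
    else:
        onsets = up_onsets(cfg, duration + cfg.sigma_shift + cfg.T_U)
        for _ in range(cfg.d):
            s = rng.uniform(0.0, cfg.sigma_shift) if cfg.sigma_shift > 0 else 0.0
            parts = []
            prev_end = 0.0
            for on in onsets:
                a, b = on + s, on + s + cfg.T_U
                a0, b0 = max(a, 0.0), min(b, duration)
                if cfg.lambda_D > 0 and a0 > prev_end:
                    parts.append(_poisson_segment(prev_end, min(a0, duration),
                                                  cfg.lambda_D, rng))
                if b0 > a0:
                    parts.append(_poisson_segment(a0, b0, cfg.lambda_U, rng))
                prev_end = b0
                if a >= duration:
                    break
            if cfg.lambda_D > 0 and prev_end < duration:
                parts.append(_poisson_segment(prev_end, duration,
                                              cfg.lambda_D, rng))
            spikes.append(np.sort(np.concatenate(parts))
                          if parts else np.empty(0))
    noise = np.sort(_poisson_segment(0.0, duration, cfg.nu, rng))
    return spikes, noise


# ---------------------------------------------------------------------------
# single-step membrane (reference implementation; also the fine-grid oracle)


@dataclass
class MembraneState:
    v: float
    g_e: float = 0.0
    t: float = 0.0
    ref_until: float = -1.0


def step_membrane(state: MembraneState, arriving_weights: float,
                  p: LifParams, dt: float | None = None
                  ) -> tuple[MembraneState, bool]:
    """Advance the membrane by one step of length ``dt`` (default p.dt).

    ``arriving_weights`` is the summed weight of spikes arriving in this
    step; the conductance jumps before integration and decays by the exact
    exponential factor afterwards. Returns the new state and a spike flag.
    """
    dt = p.dt if dt is None else dt
    g_e = state.g_e + arriving_weights
    if state.t >= state.ref_until:
        # charge-exact step-average of the decaying conductance
        g_eff = g_e * p.tau_syn * (1.0 - math.exp(-dt / p.tau_syn)) / dt
        gtot = p.g_L + g_eff
        vinf = (p.g_L * p.E_L + g_eff * p.E_e) / gtot
        v = vinf + (state.v - vinf) * math.exp(-gtot * dt / p.C_m)
    else:
        v = p.V_r
    g_next = g_e * math.exp(-dt / p.tau_syn)
    t1 = state.t + dt
    spiked = state.t >= state.ref_until and v >= p.V_th
    if spiked:
        return MembraneState(p.V_r, g_next, t1, t1 + p.tau_ref), True
    return MembraneState(v, g_next, t1, state.ref_until), False


def simulate_membrane(arrival_times: np.ndarray, arrival_weights: np.ndarray,
                      p: LifParams, duration: float, dt: float | None = None,
                      record_v: bool = False
                      ) -> tuple[np.ndarray, np.ndarray | None]:
    """Pure-Python membrane-only simulation (no plasticity).

    Used as the independent finer-grid integration oracle: run it at
    dt = 0.01 ms to check the 0.1 ms production grid.
    """
    dt = p.dt if dt is None else dt
    n_steps = int(round(duration / dt))
    order = np.argsort(arrival_times, kind="stable")
    at = np.asarray(arrival_times)[order]
    aw = np.asarray(arrival_weights)[order]
    state = MembraneState(v=p.E_L)
    spikes = []
    vtrace = np.empty(n_steps) if record_v else None
    i = 0
    for k in range(n_steps):
        t1 = (k + 1) * dt
        w = 0.0
        while i < len(at) and at[i] < t1:
            w += aw[i]
            i += 1
        state, spiked = step_membrane(state, w, p, dt)
        if record_v:
            vtrace[k] = state.v
        if spiked:
            spikes.append(state.t)
    return np.asarray(spikes), vtrace


# ---------------------------------------------------------------------------
# DSP bookkeeping and per-synapse trace updates (event-level reference)


@dataclass
class DspState:
    """Timers realizing the burst-blocking and late-window indicators."""

    last_dsp_time: float | None = None
    burst_active_until: float = -math.inf
    late_active_until: float = -math.inf
    last_post_time: float | None = None
    recent_post_times: list[float] = field(default_factory=list)


def update_dsp(dsp: DspState, post_spike_time: float,
               params: SlnRuleParams) -> bool:
    """Classify a postsynaptic spike; spikes must arrive in time order.

    A spike is a DSP iff no DSP occurred within the preceding ``T_burst``
    (half-open window: a spike exactly ``T_burst`` after a DSP is again
    distinguished). A DSP re-arms both timers.
    """
    is_dsp = post_spike_time >= dsp.burst_active_until
    if is_dsp:
        dsp.last_dsp_time = post_spike_time
        dsp.burst_active_until = post_spike_time + params.T_burst
        dsp.late_active_until = post_spike_time + params.T_late
    dsp.last_post_time = post_spike_time
    dsp.recent_post_times.append(post_spike_time)
    return is_dsp


@dataclass
class LifSynapseState:
    """Event-level view of one plastic synapse (reference implementation)."""

    weight: float
    m: float = 0.0
    recent_pre: list[float] = field(default_factory=list)


def update_trace(syn: LifSynapseState, event: tuple[str, float],
                 dsp: DspState, params: SlnRuleParams) -> int:
    """Apply one pre- or post-synaptic event to the synapse's trace.

    ``event`` is ``("pre", t)`` or ``("post", t)``; post events must already
    have been classified via :func:`update_dsp`. Returns the number of
    signed trace updates applied (negative count for depression).

    In ``dsp`` pairing a presynaptic spike in the ``(t_DSP, t_DSP + T_late]``
    window depresses once, and a DSP potentiates once per presynaptic spike
    in ``[t_post - T_early, t_post)``. In ``all_to_all`` pairing every
    (pre, post) spike pair within the windows contributes one update, so a
    pre spike following k postsynaptic spikes within ``T_late`` depresses k
    times.
    """
    kind, t = event
    if kind == "pre":
        syn.recent_pre.append(t)
        if params.pairing == "dsp":
            anchors = ([] if dsp.last_dsp_time is None
                       else [dsp.last_dsp_time])
        else:
            anchors = dsp.recent_post_times
        n = sum(1 for tp in anchors if 0.0 < t - tp <= params.T_late)
        for _ in range(n):
            syn.m = -1.0 + params.gamma * syn.m
        return -n
    # postsynaptic event
    if params.pairing == "dsp" and dsp.last_dsp_time != t:
        return 0
    n = sum(1 for tp in syn.recent_pre if t - params.T_early <= tp < t)
    for _ in range(n):
        syn.m = 1.0 + params.gamma * syn.m
    syn.recent_pre = [tp for tp in syn.recent_pre if tp >= t - params.T_early]
    return n


def apply_weight_rule(syn: LifSynapseState, params: SlnRuleParams,
                      rng: np.random.Generator
                      ) -> tuple[float, float] | None:
    """Probabilistic weight update from the current trace (binary levels or
    a strong-weight distribution). Returns (old, new) on change."""
    if params.theta_D > params.theta_P:
        raise ValueError("theta_D must not exceed theta_P")
    old = syn.weight
    if syn.m < params.theta_D and old > params.w_w:
        if rng.random() < params.p_s_to_w:
            syn.weight = params.w_w
            return old, syn.weight
    elif syn.m > params.theta_P and old <= params.w_w:
        if rng.random() < params.p_w_to_s:
            syn.weight = float(params.sample_strong(1, rng)[0])
            return old, syn.weight
    return None


# ---------------------------------------------------------------------------
# full simulation


@dataclass
class LatencyStats:
    """First-spike latency summary over UP phases (analysis side: uses the
    known phase schedule). ``r_hat`` is the mean first-spike latency divided
    by the effective phase length ``T_U + sigma_shift``, conditioned on a
    spike occurring within the phase; undefined (None) for constant-rate
    input."""

    dsp_latencies: np.ndarray
    r_hat: float | None
    spikes_per_up: float | None
    rate: float
    n_phases: int = 0
    n_phases_with_spike: int = 0


@dataclass
class LifResult:
    """Spike trains, weight events and terminal state of a LIF run."""

    post_times: np.ndarray
    post_is_dsp: np.ndarray
    pre_times: np.ndarray
    pre_ids: np.ndarray
    noise_times: np.ndarray
    event_times: np.ndarray
    event_synapses: np.ndarray
    event_old: np.ndarray
    event_new: np.ndarray
    initial_weights: np.ndarray
    final_weights: np.ndarray
    final_traces: np.ndarray
    trace_samples: np.ndarray
    trace_sample_times: np.ndarray
    v_trace: np.ndarray | None
    duration: float
    n_events_total: int


def latency_stats(post_times: np.ndarray, cfg: UpDownConfig, duration: float,
                  t_start: float = 0.0) -> LatencyStats:
    """First-postsynaptic-spike latencies per UP phase from the schedule."""
    post_times = np.asarray(post_times)
    rate_window = max(duration - t_start, 1e-9)
    rate = 1000.0 * np.count_nonzero(post_times >= t_start) / rate_window
    if cfg.mode == "constant_rate":
        return LatencyStats(np.empty(0), None, None, rate)
    t_eff = cfg.T_U + cfg.sigma_shift
    onsets = up_onsets(cfg, duration)
    onsets = onsets[(onsets >= t_start) & (onsets + t_eff <= duration)]
    lat = []
    counts = []
    for on in onsets:
        lo = np.searchsorted(post_times, on)
        hi = np.searchsorted(post_times, on + t_eff)
        counts.append(hi - lo)
        if hi > lo:
            lat.append(post_times[lo] - on)
    lat = np.asarray(lat)
    r_hat = float(lat.mean() / t_eff) if lat.size else None
    return LatencyStats(
        dsp_latencies=lat,
        r_hat=r_hat,
        spikes_per_up=float(np.mean(counts)) if counts else None,
        rate=rate,
        n_phases=len(onsets),
        n_phases_with_spike=int(lat.size),
    )


def strong_count_trajectory(result: LifResult, w_w: float
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct d_s(t) (strong-synapse count) from the weight events."""
    counts = [int(np.count_nonzero(result.initial_weights > w_w))]
    times = [0.0]
    for t, old, new in zip(result.event_times, result.event_old,
                           result.event_new):
        delta = int(new > w_w) - int(old > w_w)
        times.append(float(t))
        counts.append(counts[-1] + delta)
    return np.asarray(times), np.asarray(counts)


def run_lif(lif: LifParams, cfg: UpDownConfig, rule: SlnRuleParams,
            duration: float, init_weights: np.ndarray | None = None,
            init_d_s: int | None = None, seed: int | None = 0,
            trace_sample_ms: float = 0.0, record_v: bool = False,
            abort_if_silent_ms: float | None = None) -> LifResult:
    """Simulate the leaky model with the SLN rule for ``duration`` ms.

    Initial weights come either from ``init_weights`` directly or from
    ``init_d_s`` strong synapses (random subset, strong values drawn from
    the rule's strong-weight distribution) with the rest at ``w_w``. The
    master seed feeds independent substreams for initialization, plastic
    input, noise, and the plasticity Bernoulli trials, so the input
    realization is reproducible independently of the plasticity draws.

    If ``abort_if_silent_ms`` is set and the final stretch of that length
    contains no postsynaptic spike, a :class:`DisconnectedNeuronError` is
    raised (input weight rundown has made the neuron unresponsive).
    """
    ss = np.random.SeedSequence(seed)
    init_ss, input_ss, noise_ss, plast_ss = ss.spawn(4)
    rng_init = np.random.default_rng(init_ss)
    rng_input = np.random.default_rng(input_ss)
    rng_noise = np.random.default_rng(noise_ss)
    kernel_seed = int(plast_ss.generate_state(1)[0] % np.uint32(2 ** 31 - 1))

    if init_weights is None:
        if init_d_s is None:
            raise ValueError("give either init_weights or init_d_s")
        weights = np.full(cfg.d, rule.w_w, dtype=float)
        strong = rng_init.choice(cfg.d, size=init_d_s, replace=False)
        weights[strong] = rule.sample_strong(init_d_s, rng_init)
    else:
        weights = np.asarray(init_weights, dtype=float).copy()
        if len(weights) != cfg.d:
            raise ValueError("init_weights length must equal cfg.d")
    initial_weights = weights.copy()

    spikes, noise_t = generate_input(cfg, duration, rng_input)
    # noise uses its own substream so the plastic input realization is
    # unchanged when nu varies
    if cfg.nu > 0:
        noise_t = np.sort(_poisson_segment(0.0, duration, cfg.nu, rng_noise))
    lengths = np.array([len(s) for s in spikes], dtype=np.int64)
    nrn_off = np.zeros(cfg.d + 1, dtype=np.int64)
    np.cumsum(lengths, out=nrn_off[1:])
    nrn_t = (np.concatenate(spikes) if nrn_off[-1] > 0 else np.empty(0))
    pre_id_flat = np.repeat(np.arange(cfg.d, dtype=np.int64), lengths)
    order = np.argsort(nrn_t, kind="stable")
    pre_t = np.ascontiguousarray(nrn_t[order])
    pre_id = np.ascontiguousarray(pre_id_flat[order])
    arr_t = pre_t + lif.t_delay

    n_steps = int(round(duration / lif.dt))
    maxpost = int(duration / max(lif.tau_ref, lif.dt)) + 16
    period = cfg.T_U + cfg.T_D
    maxev = int(8 * cfg.d * max(duration / period, 1.0)) + 10000
    post_t = np.empty(maxpost)
    post_dsp = np.zeros(maxpost, dtype=np.uint8)
    ev_t = np.empty(maxev)
    ev_syn = np.empty(maxev, dtype=np.int64)
    ev_old = np.empty(maxev)
    ev_new = np.empty(maxev)
    sample_every = int(round(trace_sample_ms / lif.dt)) if trace_sample_ms > 0 else 0
    n_samp_max = n_steps // sample_every if sample_every > 0 else 0
    trace_samples = np.zeros((n_samp_max, cfg.d))
    v_out = np.empty(n_steps if record_v else 0)
    traces = np.zeros(cfg.d)

    dist_kind, p1, p2, p3 = rule._dist_code()
    n_post, n_ev, n_samp = _kernel.core(
        n_steps, lif.dt, lif.C_m, lif.E_L, lif.g_L, lif.E_e, lif.tau_syn,
        lif.V_th, lif.V_r, lif.tau_ref,
        pre_t, pre_id, arr_t, nrn_off, nrn_t, noise_t, cfg.w_n,
        rule.gamma, rule.T_burst, rule.T_early, rule.T_late,
        rule.theta_D, rule.theta_P, rule.p_s_to_w, rule.p_w_to_s, rule.w_w,
        dist_kind, p1, p2, p3,
        1 if rule.pairing == "dsp" else 0, kernel_seed,
        weights, traces,
        post_t, post_dsp, ev_t, ev_syn, ev_old, ev_new,
        sample_every, trace_samples, v_out)

    n_post_stored = min(n_post, maxpost)
    n_ev_stored = min(n_ev, maxev)
    result = LifResult(
        post_times=post_t[:n_post_stored].copy(),
        post_is_dsp=post_dsp[:n_post_stored].copy(),
        pre_times=pre_t,
        pre_ids=pre_id,
        noise_times=noise_t,
        event_times=ev_t[:n_ev_stored].copy(),
        event_synapses=ev_syn[:n_ev_stored].copy(),
        event_old=ev_old[:n_ev_stored].copy(),
        event_new=ev_new[:n_ev_stored].copy(),
        initial_weights=initial_weights,
        final_weights=weights,
        final_traces=traces,
        trace_samples=trace_samples[:n_samp],
        trace_sample_times=(np.arange(1, n_samp + 1) * sample_every * lif.dt
                            if sample_every > 0 else np.empty(0)),
        v_trace=v_out if record_v else None,
        duration=duration,
        n_events_total=n_ev,
    )
    if abort_if_silent_ms is not None:
        cut = duration - abort_if_silent_ms
        if not np.any(result.post_times >= cut):
            raise DisconnectedNeuronError(
                f"no postsynaptic spike in the final {abort_if_silent_ms:.0f} "
                f"ms (total input weight {weights.sum():.1f} nS); the neuron "
                "appears disconnected")
    return result
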