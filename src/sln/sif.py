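"""Event-level simulator of the integrate-and-fire model without leak.

Presynaptic activity arrives in volleys: each of ``d`` input neurons fires
exactly once per volley at a uniformly random time, and the spike is
transmitted with probability ``p_r``. The membrane simply accumulates the
transmitted weights, so the postsynaptic neuron fires at the arrival whose
cumulative transmitted weight first reaches the threshold ``theta_v``; since
the potential resets only between volleys, it fires at most once per volley
and only the spike order within the volley matters.

Learning signals are spike-pair orders: when the postsynaptic neuron fires,
every transmitting synapse whose spike arrived no later than the
threshold-crossing arrival receives a potentiation signal (1) and every
later transmitting synapse a depression signal (0). Each synapse keeps the
last ``M`` signals; every ``L``-th signal the sliding fraction of
potentiation signals is compared against the thresholds ``theta_D`` /
``theta_P`` and the weight changes probabilistically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .analytics import prob_fire, sample_lognormal_strong_weights

__all__ = [
    "VolleyConfig",
    "SifNeuronParams",
    "SifPlasticityParams",
    "SynapsePopulation",
    "VolleyOutcome",
    "SimResult",
    "DisconnectedNeuronError",
    "sample_volley",
    "assign_signals",
    "update_trace_and_weights",
    "run_sif",
    "signal_frequency_mc",
]

_ORDER_MODELS = ("uniform", "gaussian_rank")
_WEIGHT_SCHEMES = ("binary", "heterogeneous_lognormal", "additive",
                   "multiplicative")


class DisconnectedNeuronError(RuntimeError):
    """Total input weight can no longer bring the neuron to threshold."""


@dataclass
class VolleyConfig:
    """Volley-input parameters (model-without-leak defaults)."""

    d: int = 100
    T_U: float = 1.0
    T_D: float = 1.0
    p_r: float = 1.0
    order_model: str = "uniform"
    sigma_Z: float = 0.0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if not 0.0 < self.p_r <= 1.0:
            raise ValueError("p_r must lie in (0, 1]")
        if self.T_U <= 0:
            raise ValueError("T_U must be positive")
        if self.sigma_Z < 0:
            raise ValueError("sigma_Z must be >= 0")
        if self.order_model not in _ORDER_MODELS:
            raise ValueError(f"order_model must be one of {_ORDER_MODELS}")


@dataclass
class SifNeuronParams:
    """Threshold neuron without leak. tau_ref is stored but inert: the
    membrane resets between volleys and at most one postsynaptic spike can
    occur per volley by construction."""

    theta_v: float = 10.0
    V_r: float = 0.0
    tau_ref: float = 1.0

    def __post_init__(self) -> None:
        if self.theta_v <= 0:
            raise ValueError("theta_v must be positive")


@dataclass
class SifPlasticityParams:
    """All plasticity constants of the model without leak.

    ``L`` defaults to ``M`` (deterministic synapses); for probabilistic
    synapses :func:`run_sif` recomputes it each cycle.
    """

    M: int = 39
    L: int | None = None
    theta_D: float = 0.26
    theta_P: float = 0.72
    p_s_to_w: float = 0.2
    p_w_to_s: float = 0.05
    weight_scheme: str = "binary"
    w_w: float = 0.0
    w_s: float = 1.0
    omega: float = 1.0
    c_p: float = 1.0
    c_d: float = 0.2
    zeta: float = 0.15
    mu_ln: float = 1.74
    sigma_ln: float = 0.1002

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_D <= self.theta_P <= 1.0:
            raise ValueError("need 0 <= theta_D <= theta_P <= 1")
        for name in ("p_s_to_w", "p_w_to_s"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.L is not None and self.L < self.M:
            raise ValueError("L must be >= M")
        if min(self.omega, self.c_p, self.c_d) < 0:
            raise ValueError("omega, c_p, c_d must be >= 0")
        if self.weight_scheme not in _WEIGHT_SCHEMES:
            raise ValueError(f"weight_scheme must be one of {_WEIGHT_SCHEMES}")

    @property
    def cadence(self) -> int:
        return self.M if self.L is None else self.L


class SynapsePopulation:
    """Weights, signal buffers and update counters for ``d`` synapses.

    The buffer holds the last ``<= M`` binary learning signals per synapse
    (1 = potentiation) as a ring; ``signal_count`` counts trace updates since
    the synapse's last weight update.
    """

    def __init__(self, weights: np.ndarray, M: int, w_w: float = 0.0):
        self.weights = np.asarray(weights, dtype=float).copy()
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        self.d = len(self.weights)
        self.M = int(M)
        self.w_w = float(w_w)
        self.buffer = np.zeros((self.d, self.M), dtype=np.uint8)
        self.buf_len = np.zeros(self.d, dtype=np.int64)
        self.buf_pos = np.zeros(self.d, dtype=np.int64)
        self.signal_count = np.zeros(self.d, dtype=np.int64)

    @classmethod
    def binary(cls, d: int, d_s: int, params: SifPlasticityParams,
               rng: np.random.Generator | None = None) -> "SynapsePopulation":
        """Population with ``d_s`` strong synapses (random subset when an rng
        is given, otherwise the first ``d_s``)."""
        weights = np.full(d, params.w_w, dtype=float)
        if rng is None:
            strong = np.arange(d_s)
        else:
            strong = rng.choice(d, size=d_s, replace=False)
        weights[strong] = params.w_s
        return cls(weights, params.M, w_w=params.w_w)

    @classmethod
    def heterogeneous(cls, d: int, d_s: int, params: SifPlasticityParams,
                      rng: np.random.Generator) -> "SynapsePopulation":
        """Population with lognormal strong weights and weak weight w_w = 0."""
        weights = np.full(d, params.w_w, dtype=float)
        strong = rng.choice(d, size=d_s, replace=False)
        weights[strong] = sample_lognormal_strong_weights(
            params.mu_ln, params.sigma_ln, d_s, rng)
        return cls(weights, params.M, w_w=params.w_w)

    @property
    def n_strong(self) -> int:
        return int(np.count_nonzero(self.weights > self.w_w))

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def traces(self) -> np.ndarray:
        """Current memory trace per synapse: fraction of potentiation signals
        in the buffer (NaN while the buffer is empty)."""
        with np.errstate(invalid="ignore"):
            m = self.buffer.sum(axis=1) / np.maximum(self.buf_len, 1)
        m = np.where(self.buf_len > 0, m, np.nan)
        return m


@dataclass(frozen=True)
class VolleyOutcome:
    """Result of a single volley.

    ``arrival_order`` lists the transmitting synapses in arrival order;
    ``post_rank`` is the 0-based position in that order at which the
    cumulative transmitted weight first reached threshold (None if the
    neuron did not fire).
    """

    transmitted: np.ndarray
    arrival_order: np.ndarray
    post_spiked: bool
    post_rank: int | None


@dataclass
class SimResult:
    """Trajectory and terminal state of a model-without-leak run."""

    update_index: np.ndarray
    volley_index: np.ndarray
    total_weight: np.ndarray
    n_strong: np.ndarray
    final_weights: np.ndarray
    final_traces: np.ndarray
    n_volleys: int


# ---------------------------------------------------------------------------
# volley mechanics


def sample_volley(cfg: VolleyConfig, pop: SynapsePopulation,
                  nrn: SifNeuronParams, rng: np.random.Generator) -> VolleyOutcome:
    """Draw transmissions and the arrival order for one volley.

    Under the ``uniform`` order model the transmitting synapses arrive in a
    uniformly random order (uniform spike times induce a uniform
    permutation); under ``gaussian_rank`` synapse ``i`` (1-based) draws
    ``Z_i ~ Normal(i/d, sigma_Z)`` and arrivals are ordered by ``Z``.
    Numerically tied ``Z`` values are broken by a uniform sub-order. Weak
    synapses transmit (and occupy order slots) even when their weight is 0.
    """
    transmitted = rng.random(cfg.d) < cfg.p_r
    idx = np.flatnonzero(transmitted)
    if cfg.order_model == "uniform":
        order = rng.permutation(idx)
    else:
        z = (idx + 1) / cfg.d
        if cfg.sigma_Z > 0:
            z = z + cfg.sigma_Z * rng.standard_normal(idx.size)
        # lexsort: primary key z, uniform secondary key breaks exact ties
        order = idx[np.lexsort((rng.random(idx.size), z))]
    cum = np.cumsum(pop.weights[order])
    crossed = cum >= nrn.theta_v
    if crossed.any():
        rank = int(np.argmax(crossed))
        return VolleyOutcome(transmitted, order, True, rank)
    return VolleyOutcome(transmitted, order, False, None)


def assign_signals(out: VolleyOutcome,
                   pop: SynapsePopulation) -> tuple[np.ndarray, np.ndarray]:
    """Learning signals implied by a volley outcome.

    Returns ``(synapses, signals)``: with a postsynaptic spike every
    transmitting synapse receives exactly one signal -- 1 if its arrival is
    at or before the threshold-crossing arrival, 0 after; without one, no
    synapse receives any signal.
    """
    if not out.post_spiked:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.astype(np.uint8)
    n = out.arrival_order.size
    signals = (np.arange(n) <= out.post_rank).astype(np.uint8)
    return out.arrival_order.astype(np.int64), signals


def _apply_weight_rule(pop: SynapsePopulation, due: np.ndarray, m: np.ndarray,
                       params: SifPlasticityParams,
                       rng: np.random.Generator) -> list[tuple[int, float, float]]:
    """Probabilistic weight update for synapses whose cadence elapsed."""
    events: list[tuple[int, float, float]] = []
    dep = (m < params.theta_D) & (rng.random(due.size) < params.p_s_to_w)
    pot = (m > params.theta_P) & (rng.random(due.size) < params.p_w_to_s)
    w = pop.weights
    scheme = params.weight_scheme
    for j, is_dep, is_pot in zip(due, dep, pot):
        old = w[j]
        new = old
        if scheme in ("binary", "heterogeneous_lognormal"):
            strong = old > params.w_w
            if is_dep and strong:
                new = params.w_w
            elif is_pot and not strong:
                if scheme == "binary":
                    new = params.w_s
                else:
                    new = float(sample_lognormal_strong_weights(
                        params.mu_ln, params.sigma_ln, 1, rng)[0])
        elif scheme == "additive":
            if is_dep:
                new = max(0.0, old - params.omega)
            elif is_pot:
                new = old + params.omega
        else:  # multiplicative
            if is_dep:
                kappa = rng.normal(0.0, params.zeta) if params.zeta > 0 else 0.0
                new = max(0.0, old + (-params.c_d + kappa) * old)
            elif is_pot:
                kappa = rng.normal(0.0, params.zeta) if params.zeta > 0 else 0.0
                new = max(0.0, old + (params.c_p + kappa) * old)
        if new != old:
            w[j] = new
            events.append((int(j), float(old), float(new)))
    return events


def update_trace_and_weights(pop: SynapsePopulation, synapses: np.ndarray,
                             signals: np.ndarray, params: SifPlasticityParams,
                             rng: np.random.Generator,
                             L: int | None = None
                             ) -> list[tuple[int, float, float]]:
    """Append signals to the buffers and fire due weight updates.

    Each signaled synapse appends to its ring buffer and increments its
    signal count; a synapse whose count reaches ``L`` (default
    ``params.cadence``) has its count reset and the weight rule applied to
    its trace. Since ``L >= M``, the first evaluated trace always averages a
    full buffer. Returns the weight-change events ``(synapse, old, new)``.
    """
    if params.theta_D > params.theta_P:
        raise ValueError("theta_D must not exceed theta_P")
    cadence = params.cadence if L is None else int(L)
    if synapses.size == 0:
        return []
    pop.buffer[synapses, pop.buf_pos[synapses]] = signals
    pop.buf_pos[synapses] = (pop.buf_pos[synapses] + 1) % pop.M
    pop.buf_len[synapses] = np.minimum(pop.buf_len[synapses] + 1, pop.M)
    pop.signal_count[synapses] += 1

    due = synapses[pop.signal_count[synapses] >= cadence]
    if due.size == 0:
        return []
    m = pop.buffer[due].sum(axis=1) / np.minimum(pop.buf_len[due], pop.M)
    pop.signal_count[due] = 0
    return _apply_weight_rule(pop, due, m, params, rng)


def run_sif(cfg: VolleyConfig, nrn: SifNeuronParams,
            params: SifPlasticityParams, n_weight_updates: int,
            init_d_s: int | None = None, seed: int | None = 0,
            pop: SynapsePopulation | None = None) -> SimResult:
    """Simulate the model without leak for ``n_weight_updates`` update cycles.

    A cycle is ``L`` volleys; for deterministic synapses (``p_r = 1``)
    ``L = M`` and every synapse's weight rule fires exactly at cycle
    boundaries, while for probabilistic synapses ``L`` is recomputed at the
    start of each cycle as ``ceil(2 M / (p_r Pr[X >= theta_v]))`` with the
    current strong count and individual synapses update whenever their own
    signal count reaches it. The trajectory records the total input weight
    (and the strong count) at every cycle boundary.

    Raises :class:`DisconnectedNeuronError` when the summed weights can no
    longer reach ``theta_v`` (the neuron would never fire again and the
    dynamics would freeze).

    The master ``seed`` feeds three independent substreams: initial strong
    placement, volley input (transmission + order), and the weight-update
    Bernoulli trials.
    """
    ss = np.random.SeedSequence(seed)
    rng_init, rng_input, rng_plast = (np.random.default_rng(c)
                                      for c in ss.spawn(3))
    if pop is None:
        if init_d_s is None:
            raise ValueError("give either pop or init_d_s")
        if params.weight_scheme == "heterogeneous_lognormal":
            pop = SynapsePopulation.heterogeneous(cfg.d, init_d_s, params,
                                                  rng_init)
        else:
            pop = SynapsePopulation.binary(cfg.d, init_d_s, params, rng_init)

    upd_idx, volley_idx, totals, strongs = [], [], [], []
    volley = 0
    for cycle in range(n_weight_updates):
        if pop.total_weight < nrn.theta_v:
            raise DisconnectedNeuronError(
                f"total input weight {pop.total_weight:.3f} < theta_v="
                f"{nrn.theta_v} after {volley} volleys; the neuron can no "
                "longer fire and no further learning signal can arrive")
        if cfg.p_r >= 1.0:
            L = params.cadence
        else:
            pf = prob_fire(pop.n_strong, math.ceil(nrn.theta_v / params.w_s),
                           cfg.p_r) if params.weight_scheme == "binary" else \
                _prob_fire_weights(pop.weights, nrn.theta_v, cfg.p_r)
            if pf <= 0.0:
                raise DisconnectedNeuronError(
                    f"firing probability is 0 at volley {volley} "
                    f"(n_strong={pop.n_strong}); cannot set the update cadence")
            L = max(params.M, math.ceil(2 * params.M / (cfg.p_r * pf)))
        for _ in range(L):
            out = sample_volley(cfg, pop, nrn, rng_input)
            syn, sig = assign_signals(out, pop)
            update_trace_and_weights(pop, syn, sig, params, rng_plast, L=L)
            volley += 1
        upd_idx.append(cycle + 1)
        volley_idx.append(volley)
        totals.append(pop.total_weight)
        strongs.append(pop.n_strong)

    return SimResult(
        update_index=np.asarray(upd_idx),
        volley_index=np.asarray(volley_idx),
        total_weight=np.asarray(totals),
        n_strong=np.asarray(strongs),
        final_weights=pop.weights.copy(),
        final_traces=pop.traces(),
        n_volleys=volley,
    )


def _prob_fire_weights(weights: np.ndarray, theta_v: float,
                       p_r: float, n_mc: int = 2000,
                       seed: int = 12345) -> float:
    """Monte-Carlo firing probability for non-binary weights."""
    rng = np.random.default_rng(seed)
    transmit = rng.random((n_mc, len(weights))) < p_r
    return float(np.mean(transmit @ weights >= theta_v))


# ---------------------------------------------------------------------------
# vectorized Monte-Carlo signal frequencies (analysis oracle)


def signal_frequency_mc(d_s: int, d: int, theta_v: float, p_r: float,
                        n_volleys: int, seed: int | None = 0,
                        chunk: int = 20000) -> dict[str, float]:
    """Empirical per-synapse potentiation-signal frequencies over many volleys.

    Binary weights (strong 1, weak 0), uniform order. Returns pooled
    frequencies and signal counts for strong and weak synapses plus
    delta-method standard errors. Signals are correlated within a volley,
    so the frequency is a ratio of per-volley totals and its SE comes from
    the per-volley moments of ``pot_v - p * sig_v`` (a naive binomial count
    would understate the error).
    """
    rng = np.random.default_rng(seed)
    weights = np.zeros(d)
    weights[:d_s] = 1.0
    # per-volley moment accumulators: [sum pot, sum sig, sum pot^2,
    # sum sig^2, sum pot*sig] for strong and weak pools
    acc = {"s": np.zeros(5), "w": np.zeros(5)}
    done = 0
    while done < n_volleys:
        n = min(chunk, n_volleys - done)
        done += n
        transmitted = rng.random((n, d)) < p_r
        order = np.argsort(rng.random((n, d)), axis=1)
        w_ord = np.where(np.take_along_axis(transmitted, order, axis=1),
                         weights[order], 0.0)
        cum = np.cumsum(w_ord, axis=1)
        spiked = cum[:, -1] >= theta_v
        crossing = np.argmax(cum >= theta_v, axis=1)
        rank = np.empty_like(order)
        np.put_along_axis(rank, order, np.arange(d)[None, :].repeat(n, 0),
                          axis=1)
        has_signal = transmitted & spiked[:, None]
        pot = has_signal & (rank <= crossing[:, None])
        for key, sl in (("s", slice(None, d_s)), ("w", slice(d_s, None))):
            pv = pot[:, sl].sum(axis=1).astype(float)
            sv = has_signal[:, sl].sum(axis=1).astype(float)
            acc[key] += (pv.sum(), sv.sum(), (pv * pv).sum(),
                         (sv * sv).sum(), (pv * sv).sum())

    def _ratio_and_se(a: np.ndarray) -> tuple[float, float]:
        sp, ss, spp, sss, sps = a
        if ss == 0:
            return math.nan, math.nan
        p = sp / ss
        # delta method: Var(p) ~ Var(pot_v - p sig_v) / (n * mean(sig_v)^2)
        var_u = (spp - 2 * p * sps + p * p * sss) / n_volleys \
            - ((sp - p * ss) / n_volleys) ** 2
        se = math.sqrt(max(var_u, 0.0) / n_volleys) / (ss / n_volleys)
        return float(p), float(se)

    f_s, se_s = _ratio_and_se(acc["s"])
    f_w, se_w = _ratio_and_se(acc["w"])
    return {
        "freq_strong": f_s,
        "freq_weak": f_w,
        "se_strong": se_s,
        "se_weak": se_w,
        "n_signals_strong": int(acc["s"][1]),
        "n_signals_weak": int(acc["w"][1]),
    }
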