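"""Closed-form analysis of the spike latency normalization (SLN) rule.

This module collects everything about the volley-driven model that can be
written down exactly: the probability that a synapse receives a potentiation
rather than a depression signal as a function of the total input weight, the
expected per-update weight drift, the stable state it induces, rules for
choosing the plasticity constants around that stable state, a bound on the
expected convergence time, order statistics for the jittered-rank input
model, and the moments of the geometrically attenuated memory trace used by
the leaky model.

Throughout, the postsynaptic neuron fires in a volley iff the number of
transmitted strong inputs ``X ~ Binomial(d_s, p_r)`` reaches the threshold
``theta_v``; all quantities condition on that event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DriftCurve",
    "TuningInputs",
    "TraceMoments",
    "p_early",
    "prob_fire",
    "expected_changes",
    "drift_curve",
    "stable_state",
    "choose_parameters",
    "convergence_bound",
    "order_probability",
    "trace_moments",
    "lognormal_strong_weight_mean",
    "sample_lognormal_strong_weights",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class DriftCurve:
    """Expected weight changes per update cycle on a grid of strong counts.

    ``drift = e_potentiate - e_depress`` is the expected change of the total
    input weight (in units of synapses, for binary weights) after one
    application of the weight-update rule.
    """

    d_s_grid: np.ndarray
    e_depress: np.ndarray
    e_potentiate: np.ndarray

    @property
    def drift(self) -> np.ndarray:
        return self.e_potentiate - self.e_depress


@dataclass(frozen=True)
class TuningInputs:
    """Constants for choosing plasticity parameters around a target state.

    epsilon   -- half-width of the threshold band around the signal
                 probabilities at the stable state (thresholds).
    delta     -- target bound on the expected fraction of synapses that
                 change weight per update at the stable state (sets M).
    epsilon_1 -- relative band around d_s* inside which the expected number
                 of weight changes per update is bounded by epsilon_1 * d_s*.
    c_prime   -- safety constant for the depression-probability cap.
    d_s_star  -- the target stable number of strong synapses.
    """

    epsilon: float
    delta: float
    epsilon_1: float
    c_prime: float = 2.0
    d_s_star: int = 20

    def __post_init__(self) -> None:
        for name in ("epsilon", "delta", "epsilon_1"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.c_prime <= 0:
            raise ValueError("c_prime must be positive")


@dataclass(frozen=True)
class TraceMoments:
    """Mean and variance of the attenuated trace after ``l`` signals."""

    mean_l: float
    var_l: float
    mean_inf: float
    var_inf: float


@dataclass(frozen=True)
class ChosenParameters:
    """Plasticity-parameter fragment produced by :func:`choose_parameters`."""

    M: int
    theta_D: float
    theta_P: float
    p_s_to_w: float
    p_w_to_s: float


# ---------------------------------------------------------------------------
# signal probabilities


def prob_fire(d_s: int, theta_v: int, p_r: float) -> float:
    """Probability that the target neuron fires in a volley: Pr[X >= theta_v]."""
    if d_s < theta_v:
        return 0.0
    return float(stats.binom.sf(theta_v - 1, d_s, p_r))


def p_early(d_s: int, theta_v: int, p_r: float, strong: bool = True,
            conditioned: bool = True) -> float:
    """Probability of a potentiation signal, conditioned on a postsynaptic spike.

    For a strong synapse the potentiation signal requires its spike to be among
    the first ``theta_v`` of the ``i`` transmitted strong spikes (probability
    ``theta_v / i`` under a uniform order); a weak synapse must precede the
    ``theta_v``-th strong spike among ``i + 1`` possible slots, giving
    ``theta_v / (i + 1)``. Averaging over the strong transmitter count ``X``
    and conditioning on firing:

        p_early(d_s)  = E[theta_v / X       | X >= theta_v]
        p'_early(d_s) = E[theta_v / (X + 1) | X >= theta_v]

    With ``conditioned=True`` (default) the strong case uses the exact
    distribution of the strong count given that the tracked synapse itself
    transmitted, ``X = 1 + Binomial(d_s - 1, p_r)``, which is what the
    per-synapse signal frequency measures; ``conditioned=False`` evaluates
    the unconditional ``X ~ Binomial(d_s, p_r)`` form instead. The two
    coincide for deterministic synapses (``p_r = 1``) and differ by
    ``O(1/d_s)`` otherwise. The weak case is unaffected (a weak synapse does
    not alter the strong count).

    Returns NaN in the degenerate case ``Pr[X >= theta_v] = 0`` (the neuron
    can never fire, so no learning signal is ever emitted).
    """
    if theta_v < 1:
        raise ValueError("theta_v must be >= 1")
    if d_s < 0:
        raise ValueError("d_s must be >= 0")
    i = np.arange(theta_v, d_s + 1)
    if strong and conditioned:
        if d_s < 1:
            return math.nan
        norm = float(stats.binom.sf(theta_v - 2, d_s - 1, p_r))
        if norm == 0.0:
            return math.nan
        terms = (theta_v / i) * stats.binom.pmf(i - 1, d_s - 1, p_r)
        return float(terms.sum() / norm)
    norm = prob_fire(d_s, theta_v, p_r)
    if norm == 0.0:
        return math.nan
    denom = i if strong else i + 1
    terms = (theta_v / denom) * stats.binom.pmf(i, d_s, p_r)
    return float(terms.sum() / norm)


def _count_below(threshold_times_m: float) -> int:
    """Largest integer strictly below ``threshold_times_m``."""
    return math.ceil(threshold_times_m) - 1


def _tail_probs(d_s: int, m: int, theta_d: float, theta_p: float,
                theta_v: int, p_r: float) -> tuple[float, float]:
    """Pr[trace < theta_D] and Pr[trace > theta_P] for one synapse.

    The trace is the fraction of potentiation signals among the last M
    signals, so the potentiation count is Binomial(M, p) with p the
    appropriate signal probability.
    """
    pe = p_early(d_s, theta_v, p_r, strong=True)
    pw = p_early(d_s, theta_v, p_r, strong=False)
    if math.isnan(pe):
        return math.nan, math.nan
    p_dep = float(stats.binom.cdf(_count_below(theta_d * m), m, pe))
    p_pot = float(stats.binom.sf(math.floor(theta_p * m), m, pw))
    return p_dep, p_pot


def expected_changes(d_s: int, d: int, params, theta_v: int,
                     p_r: float) -> tuple[float, float]:
    """Expected numbers of depression / potentiation events per update cycle.

    Returns ``(E[Delta_s->w](d_s), E[Delta_w->s](d_s))``: the expected number
    of strong synapses turning weak and weak synapses turning strong in one
    application of the weight rule. ``params`` needs fields ``M``,
    ``theta_D``, ``theta_P``, ``p_s_to_w``, ``p_w_to_s``.
    """
    if params.theta_D > params.theta_P:
        raise ValueError("theta_D must not exceed theta_P")
    p_dep, p_pot = _tail_probs(d_s, params.M, params.theta_D, params.theta_P,
                               theta_v, p_r)
    e_dep = p_dep * d_s * params.p_s_to_w
    e_pot = p_pot * (d - d_s) * params.p_w_to_s
    return e_dep, e_pot


def drift_curve(d: int, params, theta_v: int, p_r: float) -> DriftCurve:
    """Evaluate the expected drift on every feasible strong count.

    The grid starts at the smallest ``d_s`` for which the neuron can fire
    (``Pr[X >= theta_v] > 0``); below it no signal is ever emitted and the
    weight dynamics are frozen rather than attracted.
    """
    lo = next(ds for ds in range(d + 1) if prob_fire(ds, theta_v, p_r) > 0.0)
    grid = np.arange(lo, d + 1)
    dep = np.empty(len(grid))
    pot = np.empty(len(grid))
    for k, ds in enumerate(grid):
        dep[k], pot[k] = expected_changes(int(ds), d, params, theta_v, p_r)
    return DriftCurve(d_s_grid=grid, e_depress=dep, e_potentiate=pot)


def stable_state(d: int, params, theta_v: int, p_r: float) -> tuple[int, np.ndarray]:
    """Stable total input weight: the argmin of the absolute expected drift.

    Evaluated exhaustively over the feasible integer grid. Returns the
    smallest minimizer together with the full tie set.
    """
    curve = drift_curve(d, params, theta_v, p_r)
    absdrift = np.abs(curve.drift)
    ties = curve.d_s_grid[absdrift == absdrift.min()]
    return int(ties[0]), ties


# ---------------------------------------------------------------------------
# parameter choosers and convergence bound


def choose_parameters(t: TuningInputs, theta_v: int, d: int,
                      p_r: float) -> ChosenParameters:
    """Pick thresholds, memory size and update probabilities for a target d_s*.

    Thresholds bracket the signal probabilities at the stable state,

        theta_D = (1 - eps) * p_early(d_s*),
        theta_P = (1 + eps) * p'_early(d_s*),

    and the memory size M = ceil(3 log(1/delta) / (eps^2 p'_early(d_s*)))
    (natural logarithm) makes the expected fraction of synapses changing
    weight at the stable state at most delta.

    The update probabilities bound the expected number of weight changes per
    update by eps_1 * d_s* just outside the band [(1-2 eps_1) d_s*,
    (1+2 eps_1) d_s*]: the depression probability is the smaller of the
    undershoot cap c' (d_s* - theta_v)/d and eps_1 d_s* divided by the
    expected depression count at (1+2 eps_1) d_s* taken with unit
    probability; the potentiation probability divides by the unit-probability
    potentiation count at (1-2 eps_1) d_s*.
    """
    eps, eps1 = t.epsilon, t.epsilon_1
    pe = p_early(t.d_s_star, theta_v, p_r, strong=True)
    pw = p_early(t.d_s_star, theta_v, p_r, strong=False)
    if math.isnan(pe):
        raise ValueError("d_s_star cannot drive the neuron to threshold")
    theta_d = (1.0 - eps) * pe
    theta_p = (1.0 + eps) * pw
    m = math.ceil(3.0 * math.log(1.0 / t.delta) / (eps ** 2 * pw))

    ds_hi = int(round((1.0 + 2.0 * eps1) * t.d_s_star))
    ds_lo = int(round((1.0 - 2.0 * eps1) * t.d_s_star))
    p_dep_hi, _ = _tail_probs(ds_hi, m, theta_d, theta_p, theta_v, p_r)
    _, p_pot_lo = _tail_probs(ds_lo, m, theta_d, theta_p, theta_v, p_r)

    cap = t.c_prime * (t.d_s_star - theta_v) / d
    dep_count = p_dep_hi * ds_hi            # E[Delta_s->w(ds_hi)] at p_s->w = 1
    pot_count = p_pot_lo * (d - ds_lo)      # E[Delta_w->s(ds_lo)] at p_w->s = 1
    p_s_to_w = cap if dep_count == 0 or math.isnan(dep_count) else min(
        cap, eps1 * t.d_s_star / dep_count)
    p_w_to_s = 1.0 if pot_count == 0 else eps1 * t.d_s_star / pot_count
    return ChosenParameters(
        M=m,
        theta_D=theta_d,
        theta_P=theta_p,
        p_s_to_w=float(min(1.0, max(0.0, p_s_to_w))),
        p_w_to_s=float(min(1.0, max(0.0, p_w_to_s))),
    )


def convergence_bound(d_s_init: int, d_s_star: int, epsilon: float,
                      p_s_to_w: float) -> float:
    """Upper bound on the expected number of weight updates to reach the band.

    For a start above the band, ``d_s_init > (1 + 2 eps) d_s*``, the expected
    number of weight updates until the strong count first drops below
    ``(1 + 2 eps) d_s*`` is at most

        1 / ((1 - 2 eps) p_s->w) * (1/d_s* + log(d_s_init - (1+2 eps) d_s*))

    with the natural logarithm.
    """
    if not 0.0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    if not 0.0 < p_s_to_w <= 1.0:
        raise ValueError("p_s_to_w must lie in (0, 1]")
    slack = d_s_init - (1.0 + 2.0 * epsilon) * d_s_star
    if slack <= 0:
        raise ValueError(
            f"d_s_init={d_s_init} must exceed (1+2*eps)*d_s_star="
            f"{(1.0 + 2.0 * epsilon) * d_s_star:.2f}")
    return (1.0 / ((1.0 - 2.0 * epsilon) * p_s_to_w)
            * (1.0 / d_s_star + math.log(slack)))


# ---------------------------------------------------------------------------
# ordered input and trace moments


def order_probability(i: int, j: int, d: int, sigma_Z: float) -> float:
    """Probability that input neuron ``j`` spikes before input neuron ``i``.

    In the jittered-rank input model neuron ``k`` draws
    ``Z_k ~ Normal(k/d, sigma_Z)`` and the volley order is the order of the
    ``Z`` values, so ``Pr[Z_j < Z_i] = Phi((i - j) / (d * sqrt(2) * sigma_Z))``.
    ``sigma_Z = 0`` degenerates to the fixed-order indicator.
    """
    if i == j:
        raise ValueError("i and j must differ")
    if sigma_Z < 0:
        raise ValueError("sigma_Z must be >= 0")
    if sigma_Z == 0.0:
        return 1.0 if j < i else 0.0
    return float(stats.norm.cdf((i - j) / (d * math.sqrt(2.0) * sigma_Z)))


def trace_moments(r: float, gamma: float, l: int | float = math.inf) -> TraceMoments:
    """Moments of the attenuated memory trace driven by Bernoulli(r) signals.

    After ``l`` independent signals, each +1 with probability ``r`` and -1
    otherwise, attenuated by ``gamma`` per signal:

        E[m]   = (2r - 1) (1 - gamma^l) / (1 - gamma)   -> (2r-1)/(1-gamma)
        Var[m] = 4 r (1-r) (1 - gamma^2l) / (1 - gamma^2) -> 4r(1-r)/(1-gamma^2)
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    if not 0.0 <= gamma < 1.0:
        raise ValueError("gamma must lie in [0, 1)")
    mean_inf = (2.0 * r - 1.0) / (1.0 - gamma)
    var_inf = 4.0 * r * (1.0 - r) / (1.0 - gamma ** 2)
    if math.isinf(l):
        return TraceMoments(mean_inf, var_inf, mean_inf, var_inf)
    if l < 0:
        raise ValueError("l must be >= 0")
    mean_l = (2.0 * r - 1.0) * (1.0 - gamma ** l) / (1.0 - gamma)
    var_l = 4.0 * r * (1.0 - r) * (1.0 - gamma ** (2 * l)) / (1.0 - gamma ** 2)
    return TraceMoments(mean_l, var_l, mean_inf, var_inf)


def lognormal_strong_weight_mean(mu: float, sigma: float, base: str = "e") -> float:
    """Mean of the heterogeneous strong-weight distribution exp(Normal(mu, sigma^2)).

    ``base='e'`` (default) returns exp(mu + sigma^2/2), the mean of a base-e
    lognormal with sigma the standard deviation of the Gaussian exponent;
    with mu=1.74, sigma=0.1002 this is ~5.726. ``base='10'`` evaluates
    10**(mu + sigma^2/2) for comparison with the alternative reading.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    exponent = mu + sigma ** 2 / 2.0
    if base == "e":
        return math.exp(exponent)
    if base == "10":
        return 10.0 ** exponent
    raise ValueError("base must be 'e' or '10'")


def sample_lognormal_strong_weights(mu: float, sigma: float, size: int,
                                    rng: np.random.Generator) -> np.ndarray:
    """Draw strong weights w = exp(Normal(mu, sigma^2))."""
    return np.exp(rng.normal(mu, sigma, size=size))
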