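"""Seeded, scaled-down reproductions of the published figure protocols.

Each experiment generates all of its input internally, runs the relevant
simulator, evaluates the protocol's property assertions, and returns an
:class:`ExperimentReport` whose aggregates can be recomputed from the stored
per-trial values. Default trial counts and durations are reduced relative
to the original study; ``full=True`` restores the original scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from . import lif as lif_mod
from .lif import (LifParams, RULE_PRESETS, SlnRuleParams, UpDownConfig,
                  latency_stats, run_lif)
from .sif import (SifNeuronParams, SifPlasticityParams, SynapsePopulation,
                  VolleyConfig, run_sif)

__all__ = [
    "ExperimentSpec",
    "ExperimentReport",
    "EXPERIMENT_NAMES",
    "run_experiment",
    "sweep",
    "bimodality_valley_ratio",
]

EXPERIMENT_NAMES = (
    "fig2_convergence",
    "fig3_order",
    "fig4_stability",
    "fig5_up_length",
    "fig6_multimodal",
    "fig7_robustness",
    "fig8_dsp_vs_all",
    "fig8_constant_rate",
)

SWEEP_PARAMETERS = ("T_U", "T_D", "sigma_shift", "d", "nu", "C_m")


@dataclass
class ExperimentSpec:
    """Named protocol with config overrides and a master seed."""

    name: str
    overrides: dict = field(default_factory=dict)
    n_trials: int | None = None
    seed: int = 0
    full: bool = False

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENT_NAMES:
            raise ValueError(f"unknown experiment {self.name!r}; "
                             f"choose from {EXPERIMENT_NAMES}")
        if self.n_trials is not None and self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class ExperimentReport:
    """Per-trial records, re-derivable aggregates and assertion outcomes."""

    name: str
    seed: int
    trials: list[dict]
    aggregates: dict
    assertions: list[dict]

    @property
    def passed(self) -> bool:
        return all(a["passed"] for a in self.assertions)

    def to_dict(self) -> dict:
        return asdict(self)


def _trial_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2 ** 31 - 1)) for s in state]


def _agg(values: list[float]) -> dict:
    arr = np.asarray(values, dtype=float)
    return {"mean": float(arr.mean()), "sd": float(arr.std(ddof=1))
            if len(arr) > 1 else 0.0, "n": len(arr)}


def bimodality_valley_ratio(weights: np.ndarray, bins: int = 20,
                            lo: float = 0.0, hi: float = 10.0
                            ) -> tuple[float, int]:
    """Valley-to-peak ratio of a fixed-bin histogram.

    Finds the two tallest local maxima of the histogram; the ratio is the
    minimum bin count between them divided by the smaller of the two peaks.
    Returns ``(ratio, n_local_maxima)``; a distribution is called bimodal
    when at least two local maxima exist and the ratio is <= 0.5.
    """
    h, _ = np.histogram(weights, bins=bins, range=(lo, hi))
    peaks = [k for k in range(bins)
             if h[k] > 0
             and (k == 0 or h[k] >= h[k - 1])
             and (k == bins - 1 or h[k] > h[k + 1])]
    if len(peaks) < 2:
        return 1.0, len(peaks)
    top2 = sorted(sorted(peaks, key=lambda k: h[k], reverse=True)[:2])
    valley = h[top2[0] + 1:top2[1]].min() if top2[1] - top2[0] > 1 else h[top2[0]]
    return float(valley / min(h[top2[0]], h[top2[1]])), len(peaks)


# ---------------------------------------------------------------------------
# protocol implementations


def _fig2_convergence(spec: ExperimentSpec):
    n_trials = spec.n_trials or (50 if spec.full else 5)
    n_updates = spec.overrides.get("n_updates", 200)
    inits = spec.overrides.get("inits", (20, 30, 80))
    cfg, nrn, params = VolleyConfig(), SifNeuronParams(), SifPlasticityParams()
    trials = []
    for init in inits:
        for s in _trial_seeds(spec.seed + init, n_trials):
            res = run_sif(cfg, nrn, params, n_updates, init_d_s=init, seed=s)
            trials.append({"init_d_s": init, "seed": s,
                           "terminal_d_s": int(res.n_strong[-1])})
    agg = {str(i): _agg([t["terminal_d_s"] for t in trials
                         if t["init_d_s"] == i]) for i in inits}
    means = [agg[str(i)]["mean"] for i in inits]
    sds = [max(agg[str(i)]["sd"], 1.0) for i in inits]
    ok = max(means) - min(means) <= 3.0 * max(sds)
    assertions = [{"name": "common_terminal_band", "passed": bool(ok),
                   "detail": {"means": means, "sds": sds}}]
    return trials, agg, assertions


def _fig3_order(spec: ExperimentSpec):
    n_trials = spec.n_trials or (250 if spec.full else 6)
    n_updates = spec.overrides.get("n_updates", 250 if spec.full else 50)
    sigmas = spec.overrides.get("sigmas", (0.0, 0.5, 2.0, 8.0))
    nrn, params = SifNeuronParams(), SifPlasticityParams()
    d = 100
    p_strong = 4 * nrn.theta_v / d
    trials = []
    for order_model, sigma in [("uniform", None)] + [("gaussian_rank", s)
                                                     for s in sigmas]:
        cfg = VolleyConfig(d=d, order_model=order_model,
                           sigma_Z=0.0 if sigma is None else sigma)
        offset = 7919 if sigma is None else int(100 * sigma)
        for s in _trial_seeds(spec.seed + offset, n_trials):
            rng = np.random.default_rng(s)
            w = (rng.random(d) < p_strong).astype(float)
            pop = SynapsePopulation(w, params.M, w_w=params.w_w)
            if pop.total_weight < nrn.theta_v:  # re-draw degenerate start
                w[:int(nrn.theta_v) + 2] = 1.0
                pop = SynapsePopulation(w, params.M, w_w=params.w_w)
            res = run_sif(cfg, nrn, params, n_updates, seed=s, pop=pop)
            strong_idx = np.flatnonzero(res.final_weights > params.w_w)
            trials.append({
                "order_model": order_model, "sigma_Z": sigma, "seed": s,
                "terminal_d_s": int(res.n_strong[-1]),
                "mean_strong_index": float(strong_idx.mean() + 1)
                if strong_idx.size else math.nan,
            })
    def _sel(sig):
        return [t for t in trials if t["sigma_Z"] == sig]
    agg = {f"sigma={k}": _agg([t["terminal_d_s"] for t in _sel(k)])
           for k in sigmas}
    agg["uniform"] = _agg([t["terminal_d_s"] for t in trials
                           if t["order_model"] == "uniform"])
    agg["mean_index"] = {f"sigma={k}": _agg([t["mean_strong_index"]
                                             for t in _sel(k)])
                         for k in sigmas}
    idx0 = agg["mean_index"]["sigma=0.0"]["mean"]
    idx_hi = agg["mean_index"][f"sigma={sigmas[-1]}"]["mean"]
    ds_2 = agg["sigma=2.0"]["mean"] if 2.0 in sigmas else None
    ds_u = agg["uniform"]["mean"]
    assertions = [
        {"name": "early_neurons_preferred_at_small_sigma",
         "passed": bool(idx0 < idx_hi),
         "detail": {"mean_index_sigma0": idx0, "mean_index_large": idx_hi}},
    ]
    if ds_2 is not None:
        tol = 3.0 * max(agg["sigma=2.0"]["sd"], agg["uniform"]["sd"], 1.0)
        assertions.append(
            {"name": "stable_state_matches_uniform_at_sigma2",
             "passed": bool(abs(ds_2 - ds_u) <= tol),
             "detail": {"d_s_sigma2": ds_2, "d_s_uniform": ds_u, "tol": tol}})
    return trials, agg, assertions


def _stability_rule(dist: str) -> SlnRuleParams:
    return replace(RULE_PRESETS["r13"], theta_D=-16.0, theta_P=5.0,
                   strong_dist=dist)


def _fig4_stability(spec: ExperimentSpec):
    n_trials = spec.n_trials or 5
    duration = spec.overrides.get("duration_ms", 50000.0 if spec.full
                                  else 10000.0)
    lif, cfg = LifParams(), UpDownConfig()
    trials = []
    for dist in ("normal", "mixture"):
        rule = _stability_rule(dist)
        for s in _trial_seeds(spec.seed + (0 if dist == "normal" else 7),
                              n_trials):
            res = run_lif(lif, cfg, rule, duration, init_d_s=24, seed=s)
            trials.append({"dist": dist, "seed": s,
                           "n_weight_changes": int(res.n_events_total)})
    agg = {dist: _agg([t["n_weight_changes"] for t in trials
                       if t["dist"] == dist]) for dist in ("normal", "mixture")}
    ok = all(t["n_weight_changes"] == 0 for t in trials)
    assertions = [{"name": "zero_weight_changes", "passed": bool(ok),
                   "detail": {"changes": [t["n_weight_changes"]
                                          for t in trials]}}]
    return trials, agg, assertions


def _fig5_protocol(t_u: float, n_phases: int, seed: int,
                   rule: SlnRuleParams) -> dict:
    lif = LifParams()
    cfg = UpDownConfig(T_U=t_u, T_D=1000.0)
    rule = replace(rule, T_burst=1000.0)
    duration = n_phases * (t_u + cfg.T_D)
    res = run_lif(lif, cfg, rule, duration, init_d_s=25, seed=seed)
    stats = latency_stats(res.post_times, cfg, duration,
                          t_start=duration / 2)
    return {"T_U": t_u, "seed": seed,
            "final_d_s": int(np.count_nonzero(res.final_weights > rule.w_w)),
            "r_hat": stats.r_hat, "spikes_per_up": stats.spikes_per_up}


def _fig5_up_length(spec: ExperimentSpec):
    n_trials = spec.n_trials or (20 if spec.full else 3)
    grid = spec.overrides.get(
        "T_U_grid",
        (20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0, 60.0, 80.0, 100.0, 500.0,
         1000.0) if spec.full else (20.0, 30.0, 50.0, 500.0, 1000.0))
    n_phases = spec.overrides.get("n_phases", 400 if spec.full else 150)
    rule = RULE_PRESETS[spec.overrides.get("preset", "r13")]
    trials = []
    for t_u in grid:
        for s in _trial_seeds(spec.seed + int(t_u), n_trials):
            trials.append(_fig5_protocol(t_u, n_phases, s, rule))
    agg = {f"T_U={t_u:g}": {
        "d_s": _agg([t["final_d_s"] for t in trials if t["T_U"] == t_u]),
        "r_hat": _agg([t["r_hat"] for t in trials
                       if t["T_U"] == t_u and t["r_hat"] is not None]),
    } for t_u in grid}
    assertions = []
    long_grid = [t for t in grid if t >= 500.0]
    if len(long_grid) >= 2:
        d1 = agg[f"T_U={long_grid[0]:g}"]["d_s"]["mean"]
        d2 = agg[f"T_U={long_grid[-1]:g}"]["d_s"]["mean"]
        rel = abs(d1 - d2) / max((d1 + d2) / 2, 1e-9)
        assertions.append({"name": "long_up_weight_normalization",
                           "passed": bool(rel < 0.15),
                           "detail": {"d_s": [d1, d2], "rel_diff": rel}})
    short_grid = [t for t in grid if t <= 50.0]
    if len(short_grid) >= 2:
        rhats = [agg[f"T_U={t:g}"]["r_hat"]["mean"] for t in short_grid]
        spread = max(rhats) - min(rhats)
        assertions.append({"name": "short_up_latency_normalization",
                           "passed": bool(spread < 0.05),
                           "detail": {"r_hats": rhats, "spread": spread}})
    return trials, agg, assertions


def _fig6_multimodal(spec: ExperimentSpec):
    n_trials = spec.n_trials or (100 if spec.full else 5)
    n_converge = spec.overrides.get("n_converge", 100 if spec.full else 60)
    n_extra = spec.overrides.get("n_extra", 250 if spec.full else 120)
    nrn = SifNeuronParams(theta_v=100.0)
    cfg = VolleyConfig()
    trials = []
    pooled: dict[str, list[np.ndarray]] = {"additive": [], "multiplicative": []}
    for scheme in ("additive", "multiplicative"):
        params = SifPlasticityParams(weight_scheme=scheme)
        for s in _trial_seeds(spec.seed + len(scheme), n_trials):
            pop = SynapsePopulation(np.full(cfg.d, 10.0), params.M,
                                    w_w=params.w_w)
            res = run_sif(cfg, nrn, params, n_converge + n_extra, seed=s,
                          pop=pop)
            pooled[scheme].append(res.final_weights)
            trials.append({"scheme": scheme, "seed": s,
                           "final_total_weight": float(res.total_weight[-1]),
                           "max_weight": float(res.final_weights.max())})
    agg, assertions = {}, []
    for scheme in ("additive", "multiplicative"):
        w = np.concatenate(pooled[scheme])
        ratio, n_peaks = bimodality_valley_ratio(w)
        bimodal = n_peaks >= 2 and ratio <= 0.5
        agg[scheme] = {"valley_to_peak": ratio, "n_peaks": n_peaks,
                       "frac_below_10": float(np.mean(w < 10.0)),
                       "total_weight": _agg([t["final_total_weight"]
                                             for t in trials
                                             if t["scheme"] == scheme])}
        expected = scheme == "additive"
        assertions.append({"name": f"{scheme}_{'bi' if expected else 'uni'}modal",
                           "passed": bool(bimodal == expected),
                           "detail": {"ratio": ratio, "n_peaks": n_peaks}})
        assertions.append({"name": f"{scheme}_weights_below_start",
                           "passed": bool(np.quantile(w, 0.99) < 10.0),
                           "detail": {"q99": float(np.quantile(w, 0.99))}})
    return trials, agg, assertions


def _fig7_trial(lif: LifParams, cfg: UpDownConfig, rule: SlnRuleParams,
                n_burn: int, n_measure: int, init_d_s: int, seed: int) -> dict:
    rule = lif_mod.scale_windows(rule, cfg.T_U)
    period = cfg.T_U + cfg.T_D
    duration = (n_burn + n_measure) * period
    res = run_lif(lif, cfg, rule, duration, init_d_s=init_d_s, seed=seed)
    stats = latency_stats(res.post_times, cfg, duration,
                          t_start=n_burn * period)
    return {"seed": seed, "r_hat": stats.r_hat, "rate": stats.rate,
            "spikes_per_up": stats.spikes_per_up,
            "final_d_s": int(np.count_nonzero(res.final_weights > rule.w_w))}


def _fig7_robustness(spec: ExperimentSpec):
    n_trials = spec.n_trials or (40 if spec.full else 3)
    n_burn = spec.overrides.get("n_burn", 200 if spec.full else 100)
    n_measure = spec.overrides.get("n_measure", 200 if spec.full else 100)
    grid = spec.overrides.get("T_U_grid", (30.0, 50.0, 80.0))
    trials = []
    for preset, init in (("r13", 25), ("r12", 17)):
        rule = RULE_PRESETS[preset]
        for t_u in grid:
            cfg = UpDownConfig(T_U=t_u)
            for s in _trial_seeds(spec.seed + int(t_u), n_trials):
                row = _fig7_trial(LifParams(), cfg, rule, n_burn, n_measure,
                                  init, s)
                row.update({"preset": preset, "T_U": t_u})
                trials.append(row)
    agg = {}
    assertions = []
    for preset, target in (("r13", 1 / 3), ("r12", 1 / 2)):
        agg[preset] = {f"T_U={t_u:g}": _agg(
            [t["r_hat"] for t in trials
             if t["preset"] == preset and t["T_U"] == t_u
             and t["r_hat"] is not None]) for t_u in grid}
        rhats = [agg[preset][f"T_U={t:g}"]["mean"] for t in grid]
        assertions.append({
            "name": f"{preset}_r_hat_flat",
            "passed": bool(all(abs(r - target) <= 0.07 for r in rhats)),
            "detail": {"target": target, "r_hats": rhats}})
    return trials, agg, assertions


def _fig8_dsp_vs_all(spec: ExperimentSpec):
    n_trials = spec.n_trials or (10 if spec.full else 3)
    duration = spec.overrides.get("duration_ms", 50000.0 if spec.full
                                  else 10000.0)
    d_s = spec.overrides.get("d_s", 60)
    lif, cfg = LifParams(), UpDownConfig()
    trials = []
    for pairing in ("dsp", "all_to_all"):
        rule = replace(RULE_PRESETS["r13"], p_s_to_w=0.0, p_w_to_s=0.0,
                       pairing=pairing)
        for s in _trial_seeds(spec.seed + len(pairing), n_trials):
            res = run_lif(lif, cfg, rule, duration, init_d_s=d_s, seed=s,
                          trace_sample_ms=cfg.T_U + cfg.T_D)
            samples = res.trace_samples[res.trace_samples.shape[0] // 2:]
            trials.append({"pairing": pairing, "seed": s,
                           "trace_var": float(samples.var()),
                           "trace_mean": float(samples.mean())})
    agg = {p: _agg([t["trace_var"] for t in trials if t["pairing"] == p])
           for p in ("dsp", "all_to_all")}
    ok = agg["dsp"]["mean"] < agg["all_to_all"]["mean"]
    assertions = [{"name": "dsp_trace_variance_smaller", "passed": bool(ok),
                   "detail": {k: v["mean"] for k, v in agg.items()}}]
    return trials, agg, assertions


def _fig8_constant_rate(spec: ExperimentSpec):
    n_trials = spec.n_trials or (50 if spec.full else 3)
    duration = spec.overrides.get("duration_ms", 30000.0)
    init_d_s = spec.overrides.get("init_d_s", 20)
    lif = LifParams()
    cfg = UpDownConfig(mode="constant_rate", lambda_U=40.0)
    trials = []
    for preset in ("r13", "r23"):
        rule = RULE_PRESETS[preset]
        for s in _trial_seeds(spec.seed + len(preset) + ord(preset[1]),
                              n_trials):
            res = run_lif(lif, cfg, rule, duration, init_d_s=init_d_s, seed=s)
            late = np.count_nonzero(res.post_times >= 0.75 * duration)
            trials.append({
                "preset": preset, "seed": s,
                "final_d_s": int(np.count_nonzero(res.final_weights
                                                  > rule.w_w)),
                "final_total_weight": float(res.final_weights.sum()),
                "initial_total_weight": float(res.initial_weights.sum()),
                "late_rate_hz": 1000.0 * late / (0.25 * duration),
            })
    agg = {p: {"final_d_s": _agg([t["final_d_s"] for t in trials
                                  if t["preset"] == p]),
               "final_total_weight": _agg([t["final_total_weight"]
                                           for t in trials
                                           if t["preset"] == p])}
           for p in ("r13", "r23")}
    d = cfg.d
    up_ok = agg["r13"]["final_d_s"]["mean"] > 0.8 * d
    down = [t for t in trials if t["preset"] == "r23"]
    down_ok = all(t["final_total_weight"] < 0.5 * t["initial_total_weight"]
                  for t in down)
    assertions = [
        {"name": "r13_potentiates_toward_d", "passed": bool(up_ok),
         "detail": {"mean_final_d_s": agg["r13"]["final_d_s"]["mean"],
                    "d": d}},
        {"name": "r23_weight_rundown", "passed": bool(down_ok),
         "detail": {"final_total": [t["final_total_weight"] for t in down],
                    "late_rate_hz": [t["late_rate_hz"] for t in down]}},
    ]
    return trials, agg, assertions


_PROTOCOLS = {
    "fig2_convergence": _fig2_convergence,
    "fig3_order": _fig3_order,
    "fig4_stability": _fig4_stability,
    "fig5_up_length": _fig5_up_length,
    "fig6_multimodal": _fig6_multimodal,
    "fig7_robustness": _fig7_robustness,
    "fig8_dsp_vs_all": _fig8_dsp_vs_all,
    "fig8_constant_rate": _fig8_constant_rate,
}


def run_experiment(spec: ExperimentSpec) -> ExperimentReport:
    """Execute a named protocol and evaluate its property assertions."""
    trials, agg, assertions = _PROTOCOLS[spec.name](spec)
    return ExperimentReport(name=spec.name, seed=spec.seed, trials=trials,
                            aggregates=agg, assertions=assertions)


def sweep(parameter: str, values: list, base: ExperimentSpec) -> list[dict]:
    """Single-parameter robustness sweep (burn-in then measurement phases).

    ``parameter`` is one of T_U, T_D, sigma_shift, d, nu (input config) or
    C_m (membrane). Each value is run for ``n_trials`` trials of the
    burn-in + measurement protocol; the returned rows carry the mean r_hat,
    output rate, spikes per UP phase and terminal strong count.
    """
    if parameter not in SWEEP_PARAMETERS:
        raise ValueError(f"unsupported sweep parameter {parameter!r}; "
                         f"choose from {SWEEP_PARAMETERS}")
    n_trials = base.n_trials or (10 if base.full else 3)
    n_burn = base.overrides.get("n_burn", 200 if base.full else 100)
    n_measure = base.overrides.get("n_measure", 200 if base.full else 100)
    preset = base.overrides.get("preset", "r13")
    rule = RULE_PRESETS[preset]
    for key, value in base.overrides.get("rule", {}).items():
        rule = replace(rule, **{key: value})
    init = base.overrides.get("init_d_s", 25)
    rows = []
    for v in values:
        lif = LifParams(C_m=v) if parameter == "C_m" else LifParams()
        cfg_kwargs = {} if parameter == "C_m" else {parameter: v}
        cfg = UpDownConfig(**cfg_kwargs)
        per = [
            _fig7_trial(lif, cfg, rule, n_burn, n_measure, init, s)
            for s in _trial_seeds(base.seed + sum(map(ord, parameter))
                                  + int(v), n_trials)
        ]
        rhats = [t["r_hat"] for t in per if t["r_hat"] is not None]
        rows.append({
            "parameter": parameter, "value": v, "n_trials": n_trials,
            "r_hat": _agg(rhats) if rhats else None,
            "rate": _agg([t["rate"] for t in per]),
            "spikes_per_up": _agg([t["spikes_per_up"] for t in per
                                   if t["spikes_per_up"] is not None]),
            "final_d_s": _agg([t["final_d_s"] for t in per]),
        })
    return rows
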