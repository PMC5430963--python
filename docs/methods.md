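# Methods

This note records the modeling conventions, numerical choices and known
limitations behind `sln`. It states nothing the test suite or the
experiment protocols do not themselves compute.

## Models

**Volley model (no leak).** `d` input neurons each fire exactly once per
volley at a uniformly random time in `[0, T_U]`; a spike is transmitted
with probability `p_r` (deterministic synapses: `p_r = 1`). The membrane
has no leak and resets between volleys, so only the *order* of arrivals
matters: the postsynaptic neuron fires at the arrival whose cumulative
transmitted weight first reaches `theta_v`, at most once per volley.
`tau_ref` is stored for completeness but cannot influence the dynamics.
Under the alternative `gaussian_rank` order model, input `i` (1-based)
draws `Z_i ~ Normal(i/d, sigma_Z)` and arrivals are sorted by `Z`;
`sigma_Z = 0` gives the fixed order `1..d` and large `sigma_Z` approaches
the uniform order (numerically tied `Z` are broken by a uniform
sub-order). Weak synapses with `w_w = 0` still transmit and occupy order
slots; they contribute nothing to the threshold sum.

**Learning signals and trace.** Given a postsynaptic spike, every
transmitting synapse receives exactly one binary signal: 1 if its arrival
is at or before the threshold-crossing arrival, else 0. Without a
postsynaptic spike no signal is emitted. Each synapse buffers its last `M`
signals; the trace is their mean, an unbiased estimate of the
potentiation-signal probability. The signal probabilities are evaluated in
`analytics.p_early`:

- the weak-synapse form averages `theta_v/(X+1)` over
  `X ~ Binomial(d_s, p_r)` conditioned on firing, exactly;
- the strong-synapse form conditions on the tracked synapse itself
  transmitting, so the strong transmitter count is
  `X = 1 + Binomial(d_s − 1, p_r)`. This *conditioned* form is what the
  per-synapse signal frequency measures (the unconditional variant,
  available via `conditioned=False`, coincides with it at `p_r = 1` and
  deviates by `O(1/d_s)` otherwise; at `d_s = 40`, `p_r = 0.5` the
  difference is 0.013, large against Monte-Carlo error).

**Weight rule.** After every `L`-th trace update of a synapse
(`L = M` for deterministic synapses; for probabilistic synapses `L` is
recomputed every cycle as `ceil(2M/(p_r Pr[X ≥ theta_v]))` from the
current strong count), the weight changes with probability `p_s→w` if
`m < theta_D` (depression) or `p_w→s` if `m > theta_P` (potentiation) —
strict inequalities, also used in the analytic tail expressions. Schemes:
binary (levels `w_w`/`w_s`), heterogeneous (strong weights redrawn from
`exp(Normal(mu, sigma^2))`), additive (`±omega`), and multiplicative
(`Δw = (−c_d + κ)w` or `(c_p + κ)w` with `κ ~ Normal(0, zeta)`), all
clipped at zero.

**Analytic layer.** Expected per-cycle change counts are
`E[Δ_s→w] = Pr[Binomial(M, p_early) < theta_D·M] · d_s · p_s→w` and
symmetrically for potentiation with `p'_early`, `d − d_s` and
`> theta_P·M`; the binomial count is the *memory size* `M` (the trace is a
fraction of `M` signals). The stable state is the exhaustive integer
argmin of the absolute expected drift over the `d_s` range where the
neuron can fire at all (`Pr[X ≥ theta_v] > 0`); below that range no signal
is ever generated, the dynamics are frozen rather than attracted, and
including it would trivially return `d_s = 0`. Ties are reported and
broken toward the smallest `d_s`.

The parameter chooser brackets the signal probabilities at a target
`d_s*`: `theta_D = (1−ε)p_early(d_s*)`, `theta_P = (1+ε)p'_early(d_s*)`,
`M = ceil(3 ln(1/δ) / (ε² p'_early(d_s*)))` (natural logarithm here and in
the convergence bound — the standard base in concentration bounds; a
different base rescales `M` and the bound by a constant). The update
probabilities bound the expected number of weight changes per update by
`ε₁ d_s*` just outside the band `(1 ± 2ε₁) d_s*`: the depression
probability is `min(c′(d_s* − theta_v)/d, ε₁ d_s* / D)` where `D` is the
expected depression count at `(1+2ε₁)d_s*` taken with unit probability,
and the potentiation probability divides `ε₁ d_s*` by the unit-probability
potentiation count at `(1−2ε₁)d_s*`. Each probability is normalized by its
*own* change count — the only self-consistent pairing, since the counts
contain the probabilities being solved for. With `ε = 0.5, δ = 0.2,
ε₁ = 0.25, c′ = 2` at `d_s* = 20` this chooser reproduces the default
parameter table (`theta_D ≈ 0.25/0.26`, `theta_P ≈ 0.71/0.72`,
`p_s→w = 0.2` from the `c′` cap, `p_w→s ≈ 0.056/0.05`), which is the
strongest available consistency check.

The heterogeneous strong-weight distribution is base-e lognormal with
`sigma` the standard deviation of the Gaussian exponent: mean
`exp(mu + sigma²/2) ≈ 5.726` at `mu = 1.74, sigma = 0.1002`. A base-10
variant is exposed for comparison but is not the default (it does not
reproduce 5.726).

**Leaky model.** Conductance-based LIF
(`C_m dv/dt = −g_L(v−E_L) − g_e(v−E_e)`; the sign convention is the
standard excitatory one — `g_e(v−E_e)` with `E_e > v` *depolarizes*), with
exponential synaptic conductance (`tau_syn`), delivery delay `t_delay`,
threshold/reset/refractory. Input neurons are independent inhomogeneous
Poisson processes alternating `lambda_D` (DOWN, duration `T_D`) and
`lambda_U` (UP, duration `T_U`), the schedule starting with a DOWN phase;
each neuron's rate function may be delayed by its own
`Uniform[0, sigma_shift]` draw. A homogeneous Poisson noise source (rate
`nu`, weight `w_n`) drives the membrane but is not plastic and never
generates learning signals.

DSPs are defined purely by the local burst timer (a postsynaptic spike is
distinguished iff no DSP occurred in the preceding `T_burst`; the blocking
window is half-open, so a spike exactly `T_burst` later is again
distinguished). The simulator never consults the hidden phase schedule;
the latency statistics do (analysis side only), with the effective phase
window `T_U + sigma_shift` when input shifts are active and conditioning
on a spike occurring within the phase. `r_hat` is reported as absent, not
zero, for constant-rate input.

Window conventions: potentiation counts presynaptic spikes in
`[t_post − T_early, t_post)` (half-open; one `m ← 1 + γm` application per
spike, weight rule after each), depression applies `m ← −1 + γm` for a pre
spike in `(t_DSP, t_DSP + T_late]` — a spike simultaneous with the DSP
counts as early, never both. Spike-pair bookkeeping uses *emission* times;
conductance uses arrival times (emission + delay). This reproduces the
known mild potentiation bias of the delay: inputs emitted during the last
`t_delay` before the postsynaptic spike are counted as "early". In
`all_to_all` pairing every (pre, post) pair within the windows contributes
one signed update — a pre spike following k recent postsynaptic spikes
depresses k times — which is what makes its trace range and variance grow
with the postsynaptic rate, the effect the DSP restriction removes.

**Integration.** Exponential Euler on a fixed 0.1 ms grid. The
conductance decays by the exact factor `exp(−dt/tau_syn)` with weight
jumps at arrivals; the membrane step freezes the *charge-exact step
average* `g_eff = g_e · tau_syn(1 − e^(−dt/tau_syn))/dt` and advances `v`
exactly for the resulting linear ODE. Freezing the post-jump value
instead would deliver `dt/(tau_syn(1 − e^(−dt/tau_syn))) = 1.27×` the true
charge per spike at these constants (`tau_syn = 0.2 ms` is comparable to
`dt`), firing the neuron ~15% too early and visibly shifting the stable
state; the charge-exact form agrees with a 0.01 ms reference integration
(shipped as `simulate_membrane`, the test oracle) to a fraction of a step.
Event ordering within a step: presynaptic plasticity events, conductance
jumps, membrane update, threshold/DSP/potentiation logic. Trace updates of
equal sign commute, so ties among pre spikes are order-irrelevant.

**Windows for other UP lengths.** The default windows
(`T_burst = T_early = T_late = 35 ms`) are tied to `T_U = 30`. Latency
normalization requires one DSP per phase and depression coverage of the
phase remainder without either window reaching a neighboring phase, so the
robustness protocols scale `T_burst = T_late = T_U + 5` while keeping
`T_early = 35` (`T_early` must only span the expected DSP latency
`r·T_U < 35` and must stay shorter than the DOWN phase — scaling it with
`T_U` would count the previous phase's spikes as potentiation). At
`T_U = 30` this is the identity (`lif.scale_windows`). The long-UP
protocols instead fix `T_burst = T_D = 1000 ms` with 35 ms learning
windows, the regime where the rule normalizes the absolute latency.

**Parameter presets.** `RULE_PRESETS` carries the two published threshold
rows (`r = 1/3`: `theta_D = −14.51, theta_P = 1.48, p = 0.05/0.05`;
`r = 1/2`: `−8.42, 8.70, 0.16/0.05`) plus an `r ≈ 2/3` row used by the
constant-rate rundown protocol. No such row is published; it is
constructed here as the mirror image of the `r = 1/3` row about the
`r = 1/2` trace mean of zero (`theta_D = −1.48, theta_P = 14.51,
p = 0.05/0.05`). The stationary trace moments `(2r−1)/(1−γ)` and
`4r(1−r)/(1−γ²)` justify the reflection.

**Randomness.** Every run takes one master seed feeding named independent
substreams (initial strong placement, plastic input, background noise,
weight-update Bernoulli trials), so an input realization can be held fixed
while plasticity draws vary, and all experiments are bit-reproducible from
`(name, overrides, seed)`.

## Synthetic data: what it emulates, what it does not

All inputs are generated internally: volley orders and Bernoulli
transmission for the no-leak model, piecewise-constant-rate Poisson trains
plus homogeneous noise for the leaky model. The generator's defaults *are*
the study conditions (parameter tables above). It emulates abrupt
UP/DOWN-state population activity with independent inputs and stationary
phase statistics; it does not emulate correlated inputs, rate ramps,
inhibition, neuromodulation, conduction-delay heterogeneity or any
recorded dataset. Passing tests therefore demonstrate the internal
consistency of rule, analysis and simulators under the model's own
assumptions — not performance on biological recordings.

## Protocol scale-downs

The experiment layer runs the figure protocols at reduced scale by
default (5–20 trials instead of 40–250; shorter measurement windows), with
`--full` restoring the original counts. Specific scaled sizes: volley
convergence 120 update cycles; UP-length grid
`{20, 30, 50, 500, 1000} ms` at 150–200 phases; stability 10 s instead of
50 s; robustness 100 + 100 phases (the acceptance battery uses the full
200 + 200 × 10 trials). Multimodality of terminal weight distributions is
decided by a fixed documented rule — the valley-to-peak ratio on a 20-bin
histogram over `[0, 10]`, bimodal iff a second local maximum exists and
the ratio is ≤ 0.5 — rather than an unnamed statistical test. The
stability protocol keeps the plasticity rule armed at
`p_s→w = p_w→s = 0.05` (the published protocol states only the
thresholds), so "zero weight changes" is a statement about the trace
staying inside `[theta_D, theta_P]`, not a vacuous `p = 0` identity.

## Known limitations

- **Stable-state offset of the leaky model.** Under charge-exact
  integration the `r = 1/3` preset converges to `d_s ≈ 29` at the default
  input (total ~1.2 µS), whereas the original study's protocols imply a
  stable point near 24–25. The equilibrium latency fraction is fixed by
  the trace-threshold balance (≈ 0.31 here, measured `r_hat` 0.29–0.32),
  so a few-percent difference in effective synaptic charge between
  integrators moves `d_s*` by several synapses. Consequently the
  stability protocol pinned at `d_s = 24` sits slightly below this
  package's stable state and shows rare potentiation flips
  (~0.65 per 10 s at `p = 0.05`); run at the package's own stable state
  (`d_s = 29`) the same protocol yields essentially zero changes
  (1 event in 30 × 10 s trials).
- **Short-UP latency spread.** With fixed 35 ms windows and
  `T_burst = 1000` the measured `r_hat` declines mildly with `T_U`
  (0.332/0.300/0.269 at 20/30/50 ms): the synaptic-delay potentiation
  bias scales as `1/T_U` and the depression window only partially covers
  a 50 ms phase. The normalization *trend* is robust; exact flatness is
  not.
- The voltage-gated DSP variant (blocking tied to a low-potential state)
  and multi-neuron or recurrent extensions are out of scope, as are
  inhibitory synapses.
- The no-leak analytic layer treats non-integer `(1 ± 2ε₁)d_s*` by
  rounding to the nearest integer strong count.
- Trace values are bounded by the attenuation fixpoint `1/(1−γ)` per
  signed application; compound per-phase updates keep the bound but make
  the stationary trace slightly heavier-tailed than the independent
  Bernoulli model used for calibration.
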