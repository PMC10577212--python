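# Methods

This note documents the models, algorithms and design choices behind
`fscode`, in the spirit of a methods appendix: what is computed, under what
assumptions, and where the genuinely open decisions were made.

## 1. Event representation

Raw sensor events — `(t, x, y, p)` for vision with polarity `p = ±1`,
`(t, channel)` for audio — are accumulated into dense count tensors at a
temporal resolution `Δt`: shape `(2, H, W, T)` for vision (polarity split
into two channels) or `(F, T)` for audio. Bin `k` (0-based) covers the
half-open interval `[kΔt, (k+1)Δt)`; an event at exactly `t = TΔt` falls
outside the window and is dropped. These are standard histogram conventions;
nothing in the downstream model depends on them beyond consistency.

Spatial downsampling (vision) is a block **sum** of counts, zero-padding the
bottom/right edge when the factor does not divide the frame. Summing, rather
than subsampling or averaging, preserves the total event count that the
input representation is defined on. Whether real pipelines pool or subsample
is tool-specific; block-sum is this package's choice.

The input file format is plain CSV (`t,x,y,p` or `t,channel`, one event per
row) — auditable, diff-able, and free of binary decoder dependencies. Native
sensor formats (AEDAT, .dat) are out of scope.

## 2. Neuron model and discretization

The CUBA-LIF neuron is discretized with per-step decays
`α = β = exp(−Δt/τ)` (membrane and synaptic constants are tied, `τ_m = τ_s`;
the API stores one `τ`). One step per layer runs in a fixed normative order:

1. `U[n+1] = α·U[n]·(1 − s[n]) + (1 − α)·I[n]`
2. `s[n+1] = Θ(U[n+1] − θ)`
3. `I[n+1] = β·I[n] + W·s_prev[n+1] + V·s_self[n+1]`

The `(1 − s[n])` factor is an instantaneous reset to the resting potential
0; there is no refractory period. The ordering resolves the apparent
same-step recurrent dependency: a spike emitted at `n+1` enters the current
at `n+1` and first affects the membrane at `n+3`, so no algebraic loop
exists. The first layer receives the raw integer **counts** (not binarized
spikes) as its drive — the input is a count tensor by construction.

Supported layers: fully connected (optionally with a full recurrent matrix
`V`, self-connections included — nothing in the update rule excludes the
diagonal), 2-D convolution (valid padding, square kernels, stride), and
spatial max pooling. Pooling is **stateless**: the max of a `{0,1}` block is
a logical OR, applied per step; pool units carry no `τ/θ` and are not
counted as neurons. Giving pooling its own LIF state would require dynamics
that have no defining equations here, so the stateless reading is adopted
deliberately.

Time is 1-based in all recorded trajectories (`n = 1..T`; index 0 holds the
zero initial state). Internal arrays are indexed the same way to avoid
off-by-one translation.

## 3. Readout

Output spike trains are encoded per step as `n·Δt` (spike) or the sentinel
`t_inf = (T+1)Δt` (silence); the first-spike time is the minimum of the
codes, and the FS prediction is the argmin over class neurons. When **every**
output neuron is silent, the prediction falls back to the largest
max-over-time membrane potential — a neuron close to threshold is the one
most likely to have fired first. Ties at the same first step are broken by
the higher membrane potential at that step, then by the lower neuron index;
the potential-based tie-break mirrors the fallback's logic. The FR readout
is the argmax of the firing rate `f_i = (1/T)Σ_n s_i[n]`, ties broken by
`U_max`, then index.

## 4. Objectives

**FS loss** — softmax cross-entropy over negative first-spike times plus a
silent-target penalty:

```
L_FS = −Σ_i y_i log softmax(−α₀·t_F)_i + λ_t Σ_{i: t_F,i > T} y_i (exp(β₀·t_F,i) − 1)
```

Times enter the exponentials in **steps** (`t/Δt`), not seconds. The printed
scales this package defaults to (`α₀ = 0.1`, `β₀ = 0.02`) only make sense in
step units: with windows of 50–250 steps the exponents stay O(1), whereas
second-valued times at millisecond resolution would flatten the softmax and
make the penalty astronomically steep. Only the sentinel `T+1` can exceed
`T`, so "silent" is implemented as `t_F = T+1` exactly. Softmax is computed
with max-subtraction (shift invariance makes this exact, not approximate).

**FR loss** — cross-entropy over `softmax(α₁·f)`; no inactivity penalty is
needed because rate training rarely silences neurons.

**Spike-count constraint** (optional) — `L_s = λ_s·|N_s − Ñ_s|`, where `N_s`
is the mean spike count per neuron over hidden + output layers. Its
(sub)gradient is a constant `λ_s·sign(N_s − Ñ_s)/(#neurons·B)` added to
every neuron-step spike error during the backward pass.

## 5. Backward pass

Gradients flow through three custom rules, composed with plain reverse-time
accumulation.

**Time-to-spike assignment.** For an *active* output neuron with first spike
at step `m*`, the time error lands on the surrounding spikes through a
negative Gaussian window `∂t/∂s[n] = g(m* − n)`,
`g(x) = −A/(√(2π)σ)·exp(−x²/2σ²)`, truncated at `|n − m*| ≤ 3σ`. The width
rule is `σ = ⌊T/D⌋`, `W = min{6σ+1, T}`. For an *inactive* neuron the error
is assigned to every step (each step receiving the truncated windowed sum
over all source steps) — this is what keeps silent target neurons trainable
and silent non-target neurons suppressed. The sign flip encodes "earlier
time ⇔ larger spike value". Truncation at 3σ for the inactive sum keeps the
cost `O(T·W)`; the untruncated tail it discards is below 0.3 % of the
window mass.

Degenerate window: `D > T` gives `σ = 0`, `W = 1` — the delta limit. To
avoid a division by zero while preserving that limit, the single-tap weight
uses the `σ = 1` peak value `−A/√(2π)`; for any `D ≤ T`, `σ ≥ 1` holds
automatically and no guard is needed. The amplitude defaults to `A = 2T`.
`σ` and `W` are recomputed from the *current* window length every call, so
an empty-sequence extension automatically widens the window base.

**Surrogate derivative.** `f'(U) = 1/(1 + ρ|U − θ|)²` (fast sigmoid),
`ρ = 5` by default.

**Reverse accumulation.** Per layer, stepping `n = T..1`:

```
∂L/∂I[n] = (1−α)·∂L/∂U[n+1] + β·∂L/∂I[n+1]
∂L/∂s[n] = external + Vᵀ·∂L/∂I[n]            (same step, recurrent)
∂L/∂U[n] = ∂L/∂s[n]·f'(U[n]) + α·(1−s[n])·∂L/∂U[n+1]
∂L/∂W    = Σ_n ∂L/∂I[n] ⊗ s_prev[n] ,  ∂L/∂V = Σ_n ∂L/∂I[n] ⊗ s_self[n]
```

with spike errors crossing layers through `Wᵀ` at the same step. The reset
factor `(1 − s[n])` is treated as a **constant** during differentiation — no
gradient flows into the reset's own spike. This matches common
surrogate-gradient practice and the structure of the update equations, but
it is a modelling decision, not a theorem. Max-pool backward routes each
block's error to its argmax input, first index on ties. For FR training the
output spike error is simply `∂L/∂f_i · (1/T)` at every step; no Gaussian is
involved.

The production backward pass is vectorized; the test suite checks it against
an independent per-neuron, per-step loop implementation of the same
semantics (50 random networks, < 1e-6 relative error) and checks the loss
gradients against central finite differences.

## 6. Training

`SpikingClassifier` follows the scikit-learn estimator contract. Defaults
(the package's standard audio-task configuration): `Δt = 10 ms`,
`τ₁ = 50 ms`, `θ₁ = 0.5` for feature-extraction layers; decision layers use
`τ₂ = μ·τ₁` (default `μ = 4`) and `θ₂ = 1.0`; `α₀ = 0.1`, `β₀ = 0.02`,
`λ_t = 0.01`, `α₁ = 20`, `A = 2T`, `D = 16`, `ρ = 5`, Adam with
`η = 10⁻³`, batch 32, weight decay `10⁻⁴` (L2 folded into the gradient;
`β₁/β₂/ε = 0.9/0.999/10⁻⁸`), Xavier-uniform init. In a convolutional net
the conv/pool layers are "feature extraction" and all FC layers "decision";
in a pure FC net only the output layer is the decision layer.

In FS mode the training window is extended by `T_E` zero bins (default 10)
so output spikes delayed past the stimulus remain observable; `σ` and `W`
are derived from the extended length. Evaluation uses the window as given.
A run is fully determined by `random_state` (init and batch order); loss
divergence aborts with a diagnostic rather than continuing on NaNs.

Metrics: `N_s` (mean spikes per neuron, hidden + output — input bins are
counts, not spikes, and pool units are not neurons); the accuracy-vs-window
curve, computed from a single forward pass because LIF dynamics are causal
(the `T'`-truncated simulation is exactly the prefix of the full one, with
the readout sentinel `(T'+1)Δt`); and the time delays `t_d(p%)` — the
smallest `T'·Δt` whose accuracy reaches `p%` of the curve's peak (an
all-zero curve reports the full window length).

## 7. Synthetic data

The generator emulates the qualitative split between repetitive visual and
non-repetitive auditory event streams:

* **repetitive** — a fixed per-class pixel template replayed every `period`
  bins (gesture-like periodicity);
* **nonrepetitive** — each class traces a chirp-like channel sweep exactly
  once per trial. The default motifs (slow up-sweep; fast up-then-down
  chirp; up-hold-up staircase; slower-tempo replays for further classes)
  share their starting channels and overall channel occupancy, so the
  class label is carried by *when* channels fire rather than which ones —
  the property that makes first-spike timing informative at all.
  `pattern_channels` overrides the motifs with explicit per-class
  channel-per-bin trajectories (e.g. disjoint constant channels for a
  linearly separable control).

Event counts on active cells are Poisson with mean `signal_rate` per bin
(default 3.0 — a strongly driven cochlea channel at 10 ms bins), timing is
blurred with Gaussian jitter (default 1 bin s.d.), and every cell receives
Poisson background at `noise_rate` (default 0.3 events/bin/channel, i.e.
roughly two background events per signal event over a 20-channel trial —
enough that single-bin evidence is unreliable and decisions require
temporal integration). Generation is fully deterministic given the seed;
the standard study task is 3 classes × 100 trials, `F = 20`, `T = 50`,
split 80/20.

What this generator does **not** emulate: sensor non-idealities (hot
pixels, refractory effects, per-channel gain), realistic cochlear
filter-bank correlations, class-conditional event-rate differences, or any
spatial structure in the audio case. Passing tests on this data shows the
training machinery works and that timing information is exploitable; it
does not certify accuracy on real DVS/cochlea recordings.

## 8. Scaled-down behavioural studies

The test suite reproduces three qualitative findings at desk scale
(minutes on one CPU), using the standard study task:

* **Learnability** — FS and FR training both exceed 90 % held-out accuracy
  within 50 epochs (seed 0) on the 3-class task.
* **Non-target suppression** — after matched 80-epoch budgets, the FS
  model's non-target output neurons emit fewer total spikes than the FR
  model's on held-out data in ≥ 4 of 5 seeds. 80 epochs (rather than the
  learnability study's 50) lets every seed converge for both losses; the
  comparison is between trained models, not between half-converged runs.
* **Delay trend** — `t_d(50%)` grows with the decision time constant
  (`μ ∈ {1, 4, 12}`). The accuracy curves are measured on a 300-trial
  evaluation set freshly generated from the same distribution (seed 1): a
  60-trial split quantizes accuracy in steps of 1/60, which is larger than
  the effect being measured. The trend statistic is the Spearman rank
  correlation of the per-μ mean delays across 5 seeds (pooled correlation
  is also positive).

Training-run counts and sizes were chosen so the full suite stays within a
few minutes; all randomness is seed-pinned, so reruns are bit-identical.

## 9. Known limitations

* Dense NumPy simulation: fine for ≤ ~10⁵ neuron-steps per trial, not for
  large convolutional nets or long windows.
* The FS pseudo-gradient is heuristic; there is no convergence guarantee,
  and a minority of seeds converge noticeably more slowly than others on
  the study task.
* Adaptive (AdLIF) neurons, trainable time constants, batch-norm and
  dropout are not implemented.
* The delta-window scaling at `σ = 0` (`−A/√(2π)` per step) is one of
  several defensible normalizations of the degenerate case.
* `t_d(50%)` on few-class tasks sits close to chance level of the accuracy
  curve and is intrinsically noisy; `t_d(90%)` is the more stable summary
  at this scale.
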