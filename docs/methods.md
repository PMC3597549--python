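# Model and methods

`chainstream` simulates perceptual organisation in auditory streaming as
two coupled processes: a probabilistic, event-driven discovery of
repeating tone patterns ("chains"), and a stochastic winner-take-all
competition among the discovered patterns. This note records the exact
equations, the parameter values and units, the numerical scheme, and the
design decisions taken where the published description of the model
leaves the implementation open — together with what the synthetic
stimuli do and do not exercise.

## Stimuli

The canonical input is the ABA− train: A tones fixed at 400 Hz, B tones
`Δf ∈ {4, 10, 16, 22}` semitones higher, onset-to-onset interval
`Δt ∈ {100, 150, 200, 250}` ms, cycle length `4·Δt` (A, B, A, silence),
total duration 240 s, tone duration 75 ms. The model is onset-based:
tone duration is carried on the `Event` type but plays no role in
assembly or dynamics. Time is real-valued milliseconds; partial trailing
cycles are truncated at whole events. Arbitrary repetitive sequences can
be supplied as `(onset, frequency, duration)` triples or CSV.

Feature distance is measured in semitones, `d = |12·log2(f2/f1)|`.

## Chain assembly

Each input event spawns a singleton open chain. For every later event,
each open chain draws two independent Bernoulli branches:

* **include** with `p⁺ = exp(−β₁ d²/g − β₂ n)`,
* **skip** with `p⁻ = 1 − exp(−β₃ d/g − β₄ max(0, Δn))`,
  forced to zero if the event's feature matches one the chain already
  contains (a chain cannot skip the event type it includes),

where `d` is the feature distance from the chain's last event, `g` the
time gap in seconds, `n` the number of competing chains predicting the
candidate event, and `Δn` the candidate's predictedness minus the
predictedness of the chain's last event. Both branches surviving splits
the chain; both failing deletes it. Open chains are capped at 6 nodes
and a time span of `8·Δt` (twice the longest expected period).

When inclusion makes the first and last events match in feature, a
closed loop is spawned (period = last onset − first onset, the final arc
returned to the first event) while the open copy keeps growing. For a
*loop-closing* inclusion, `n` excludes competing chains equivalent to
the loop being completed: an established chain's own predictions do not
explain away its own rediscovery.

A closed chain is on probation for one full cycle: every prediction must
be matched by an input event (matching is an exclusive elliptical region,
`(Δt/w_t)² + (Δd/w_f)² < 1`, with widths 30 ms and 0.5 ST), and every
event it does not predict must survive a skip draw. Survivors that
duplicate a competing chain (mutually matching predictions over a
two-cycle horizon) are discarded and counted as a *rediscovery* of the
original; novel survivors enter the competition with probability
`p_c = 0.2`. Any closed chain with an unmatched prediction is deleted,
competing or not.

Assembly parameters: `β₁ = 0.00015`, `β₂ = 1`, `β₃ = 0.0055`, `β₄ = 8`,
`w_t = 30` ms, `w_f = 0.5` ST, `p_c = 0.2`.

### Reconstruction choices in the assembly stage

The published equations for `p⁺`/`p⁻` are not fully legible, so the
argument scalings were fixed by requiring the published coefficient
values to reproduce the published behaviour across the stimulus grid:

* the inclusion penalty uses the distance-weighted rate `d²/g`; a plain
  rate `d/g` with `β₁ = 0.00015` would make inclusion essentially free
  even at 22 ST / 100 ms, abolishing the segregated-first bias there;
* the skip bonus uses the plain rate `d/g`;
* the predictedness contrast is one-sided (`max(0, Δn)`): skipping is
  eased when the *candidate* is better explained elsewhere than the
  chain's own tail, never the reverse. A symmetric `|Δn|` lets an
  established stream chain free its own duplicates' skip draws,
  producing a runaway rediscovery loop (rediscoveries outpacing
  successes) that lets every newly admitted chain instantly unseat the
  incumbent — inconsistent with the minutes-long first phases at the
  small-Δf/long-Δt corner.

## Competition dynamics

Each competing chain `j` carries eight state variables. Excitation and
inhibition obey

    τ_ei dE_j/dt = −E_j + σ( w_s S_j/(R+κ) + w_x X_j/(R+κ) − w_ie I_j
                             + w_se E_j (1 − A_j) + w_n U_j )
    τ_ei dI_j/dt = −I_j + σ( w_c Σ_k C_jk/(R+κ) + w_a A_j − w_ei E_j )

with `σ` the standard logistic sigmoid, keeping both variables in
(0, 1). The event-driven rates are leaky integrators,
`τ dx/dt = −x + Σᵢ δ(t − tᵢ)`, so each occurrence bumps the variable by
`1/τ` and its long-run mean equals the occurrence rate in s⁻¹:

* `S_j` — successful predictions (on an ABA− train with a 500 ms cycle
  the A-stream, B-stream and integrated chains average 4, 2 and 6 s⁻¹);
* `C_jk` — collisions with chain `k` (both chains predicting the same
  event), each increment weighted by the *rival's* excitation at the
  collision instant, so the inhibition a collision delivers is
  proportional to how excited the other chain currently is;
* `R` — the overall input event rate, shared by all chains and
  integrated from stimulus onset; it divides the success, rediscovery
  and collision drives (`κ = 0.1` prevents division by zero) and makes
  the competition operate on rate *ratios*, normalising behaviour across
  presentation rates;
* `X_j` — rediscoveries of chain `j`.

Adaptation follows the saturating law `τ_a dA/dt = E(1 − 2A) − A`
(equilibrium `E/(1+2E) ≤ 1/3`) and throttles the self-excitation term.
Noise is an Ornstein–Uhlenbeck process per chain,
`dU = −U dt/τ_u + σ_u √(2 dt/τ_u) ξ`, independent across chains, with
stationary standard deviation `σ_u`; it feeds the excitatory population
only.

Parameters: `τ_ei = 50` ms, `τ_S = τ_C = 1` s, `τ_u = 500` ms,
`τ_A = τ_R = τ_X = 5` s; `w_ie = 8.1`, `w_ei = 1`, `w_se = 3.2`,
`w_s = 3.8`, `w_c = 3`, `w_n = 3.4`, `w_a = 0.1`, `w_x = 7`, `κ = 0.1`;
`σ_u = 0.3`.

### Reconstruction choices in the dynamics

* **Sign of the `w_ei` term.** The chain's own excitation enters its
  inhibitory population with a *negative* sign, keeping local inhibition
  away from saturation while the chain is dominant. With the opposite
  sign every chain self-cancels (fixed-point analysis with the published
  weights puts the dominant excitation near 0.25, removes the segregated
  attractor entirely and drives switching on the adaptation timescale),
  which contradicts the deep two-attractor structure, the
  suppressed-but-positive excitations, and the noise-free stability the
  model is described as having.
* **Shared R.** The input event rate is a stimulus property. Zeroing it
  per chain at admission would hand newcomers a ~35× transient drive
  (divisor `R + κ ≈ κ`) and let them unseat any incumbent instantly.
* **Adaptation cap.** With adaptation tracking excitation fully, a
  freshly admitted (unadapted) chain out-self-excites a long-dominant
  integrated chain by more than the integrated chain's success
  advantage, again producing admission-time usurpation. The saturating
  law caps that advantage below the success gap.
* **Noise amplitude.** The published noise equation specifies a
  unit-variance Gaussian increment but not the diffusion scale; `σ_u`
  is therefore a model parameter. It was calibrated once so that the
  balanced condition (16 ST / 200 ms) yields a mean perceptual phase
  duration near the reported ~24 s, and then frozen; it was not adjusted
  per condition.

Integration is forward Euler at 1 ms (τ_ei/50), with exact exponential
decay of the rate variables between impulses and √dt scaling of the OU
increment. Impulses are applied at event onsets. All state variables of
a chain start at zero when it enters the competition.

## Readout and analysis

Excitations are low-pass filtered (first-order, 500 ms — suppresses the
per-event ripple without masking multi-second phases) before comparison.
A sample is *integrated* if the filtered excitation of the integrated
chain (the one predicting both frequency classes) exceeds that of every
single-class chain, *segregated* if any single-class chain beats it (or
no integrated chain competes), and *none* when nothing competes — so the
first report always starts strictly after stimulus onset. Maximal
constant-label runs form phases; runs shorter than 300 ms are discarded
and absorbed into their neighbours, mirroring the human button-press
pipeline (toggleable).

Condition summaries follow the behavioural conventions: the first
classified phase is analysed separately (choice and duration, labels
pooled); subsequent-phase segregation is time-weighted; runs with no
subsequent phases are imputed from the same run's other conditions at
grid level; the segregation-probability time course is the across-run
mean of the segregated indicator smoothed by a centred 2-s moving
average; log phase durations (ms) are tested with Shapiro–Wilk.
Statistical machinery beyond that (ANOVA families etc.) is deliberately
not re-implemented — phase tables are exported as CSV for any standard
statistics environment.

## Simulated experiment

The default protocol is 15 independent 4-minute runs per condition on
the 4×4 `Δf × Δt` grid (a 6×6 grid is configurable but its extra levels
are not defined here). A root seed deterministically spawns
per-(condition, run) seeds, and each run splits its seed into separate
assembly and noise streams, so either stage's stochasticity can be
frozen in isolation. One 240-s run at 1-ms resolution takes ~1-2 s on a
single CPU (the inner Euler loop is JIT-compiled); the full default grid
completes in a few minutes.

## What the synthetic stimuli do and do not show

The generator produces exactly the idealised isochronous pure-tone
trains the model was designed around: perfectly periodic onsets, exact
frequencies, no jitter, no intensity or location cues, no attentional
modulation. Passing the test suite therefore demonstrates the internal
consistency of the discovery-plus-competition account (first-percept
biases across the grid, discovery latencies, multistable switching
statistics, attractor structure, rate normalisation) — not that the
model fits any particular listener, whose data are noisier and who may
report organisations outside the forced integrated/segregated choice.

## Known limitations

* Only periodic, loop-shaped predictors are discovered; no soft
  weakening of failing chains (they are deleted outright), no
  multi-feature distances, and no carry-over between stimulus blocks.
* The reconstruction reproduces segregation dominance at the balanced
  condition but overshoots the reported single-run figure (~85-90% vs
  74%), and the mean stream-discovery delay at the small-Δf/long-Δt
  corner runs ~25-30 s against the reported 39 s: early lucky
  admissions in the opening seconds drag the mean down.
* The adaptation depth compatible with stable first phases is too small
  to impose a visible refractory period, so ablating adaptation changes
  the phase-duration distribution little: both intact and ablated
  distributions are heavy-tailed (log-normal-like, Shapiro–Wilk W on log
  durations ≈ 0.97), rather than showing a gamma-to-exponential
  reversion.
* With fifteen 4-minute runs at a ~20-25 s mean phase duration the
  pooled phase count is necessarily in the hundreds; a pooled count of
  ~50 would require a ~60 s mean phase, so those two reported statistics
  cannot be reproduced simultaneously.
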