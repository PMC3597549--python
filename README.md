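# chainstream

A two-stage computational model of auditory streaming — how listeners
hear an alternating tone sequence either as one integrated pattern or as
separate streams, and why that perception keeps flipping.

The model addresses the classic ABA− paradigm: a low tone A at 400 Hz, a
tone B `Δf` semitones higher, A again, then a silent slot, repeating
every `4·Δt` ms for four minutes. Listeners report either an
*integrated* gallop (ABA−ABA−…) or a *segregated* pair of streams
(A−A−A−… and B−−−B−−−…), with spontaneous switches between the two.

**Stage 1 — chain discovery.** Every tone onset is an *event*. Events
are probabilistically linked into *chains*: open chains grow by
including or skipping each incoming event, and close into immutable
predicting loops when their first and last events match. With distance
`d` (semitones), gap `g` (s), `n` the number of competing chains
predicting the event and `dn` the predictedness contrast,

    p_include = exp(-β₁ d²/g − β₂ n)
    p_skip    = 1 − exp(-β₃ d/g − β₄ max(0, dn))   (0 for an already-included event type)

A closed loop must survive one probation cycle (every prediction matched,
every other event successfully skipped) and a Bernoulli(p_c) draw before
it *competes*; re-discovered duplicates of a competing chain are
discarded but counted as rediscoveries. Mis-predicting chains are
deleted.

**Stage 2 — competition.** Each competing chain `j` carries excitation
`E`, inhibition `I`, adaptation `A`, Ornstein–Uhlenbeck noise `U`, and
leaky-integrated rates of successes `S`, collisions `C`, input events
`R` (shared) and rediscoveries `X`:

    τ dE_j/dt = −E_j + σ( w_s S_j/(R+κ) + w_x X_j/(R+κ) − w_ie I_j
                          + w_se E_j (1−A_j) + w_n U_j )
    τ dI_j/dt = −I_j + σ( w_c Σ_k C_jk /(R+κ) + w_a A_j − w_ei E_j )

Collisions (two chains predicting the same event) are the only channel
of inter-chain inhibition, weighted by the rival's current excitation —
so the chains of the momentarily dominant organisation suppress the
rest, forming two attractors whose noisy, adaptation-biased rivalry
reproduces multistable switching. A readout compares low-pass filtered
excitations and reports *integrated*, *segregated*, or *none*; phases
shorter than 300 ms are discarded, as in human button-press data.

## Worked example

```python
from chainstream import StimulusSpec, run_single
from chainstream.analysis import phases_frame

run = run_single(StimulusSpec(delta_f=16, delta_t=200, duration=240), seed=1)
for e in run.chain_log:
    if e["kind"] == "admitted":
        print(f'{e["role"]:11s} joined the competition at {e["time_ms"]/1000:5.1f} s')
print(phases_frame([run]).head(6).to_string(index=False))
```

prints (seed 1):

```
integrated  joined the competition at   2.4 s
A           joined the competition at   2.6 s
B           joined the competition at   3.6 s
 run_id  delta_f  delta_t  phase_index      label  start_ms   end_ms  duration_ms
      0       16      200            0 integrated    2400.0   6340.0       3940.0
      0       16      200            1 segregated    6340.0  36020.0      29680.0
      0       16      200            2 integrated   36020.0  37640.0       1620.0
      0       16      200            3 segregated   37640.0  76330.0      38690.0
      0       16      200            4 integrated   76330.0  81060.0       4730.0
      0       16      200            5 segregated   81060.0 103230.0      22170.0
```

All three canonical chains (the integrated loop and the two stream
loops) are discovered within seconds at this balanced condition, and
perception then alternates irregularly on a tens-of-seconds timescale:
this run reports segregation 91% of the classified time across 12
phases with a mean phase duration of 19.8 s.

The same machinery is exposed on the command line:

```
chainstream simulate  --delta-f 16 --delta-t 200 --duration 240 --seed 1
chainstream condition --delta-f 4  --delta-t 250 --n-runs 15 --seed 0
chainstream grid      --n-runs 15 --seed 0 --out results/grid
```

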