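import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from chainstream import (AssemblyParams, ChainAssembler, DynamicsParams,
                         Event, EventSequence, StimulusSpec, generate_aba_train)


@pytest.fixture
def aparams():
    return AssemblyParams()


@pytest.fixture
def dparams():
    return DynamicsParams()


@pytest.fixture
def neutral_spec():
    """The balanced stimulus condition: 16 ST separation, 200 ms SOA."""
    return StimulusSpec(delta_f=16, delta_t=200, duration=240)


@pytest.fixture
def abac_sequence():
    """A, B, A, C at 100 ms spacing — the worked chain-building example."""
    f_a, f_b, f_c = 400.0, 400.0 * 2 ** (16 / 12), 250.0
    events = [Event(0, f_a), Event(100, f_b), Event(200, f_a), Event(300, f_c)]
    return EventSequence(events, 500.0)


def run_forced_assembly(sequence, params=None, finalize_at=None):
    """Assembler with every non-zero branch draw forced to succeed."""
    params = params or AssemblyParams(max_open_span=1600.0)
    asm = ChainAssembler(params, np.random.default_rng(0), branch_mode="force")
    for e in sequence:
        asm.process_event(e)
    if finalize_at is not None:
        asm.finalize(finalize_at)
    return asm


def attractor_probe(n_trials=20, rng_seed=99, duration_s=40.0):
    """Final organisation from random excitation states, noise off.

    The canonical chains are installed with their success, collision and
    input rates primed at the stimulus steady state and the rediscovery
    drive sustained at the rates the assembly produces on the neutral
    train; excitation, inhibition and adaptation start at random values.
    Returns the list of final configurations ("int"/"seg") and the final
    filtered-excitation drifts (stationarity measure).
    """
    import itertools
    from chainstream import CompetitionDynamics, DynamicsParams
    from chainstream.assembly import canonical_chains

    train = generate_aba_train(StimulusSpec(16, 200, duration_s))
    rng = np.random.default_rng(rng_seed)
    s_rates = {"A": 2.5, "B": 1.25, "ABA": 3.75}
    x_rates = {"A": 1.3, "B": 0.01, "ABA": 0.25}
    coll = {("A", "ABA"): 2.5, ("ABA", "A"): 2.5,
            ("B", "ABA"): 1.25, ("ABA", "B"): 1.25}
    ap = AssemblyParams()
    w_t = ap.match_width_time
    finals, drifts = [], []
    for trial in range(n_trials):
        chains = canonical_chains(16, 200)
        eng = CompetitionDynamics(DynamicsParams(noise_on=False),
                                  np.random.default_rng(trial),
                                  duration_ms=train.total_duration)
        for c in chains.values():
            eng.add_chain(c)
        e0 = {k: rng.uniform(0, 1) for k in chains}
        for k, c in chains.items():
            eng.set_state(c, E=e0[k], I=rng.uniform(0.2, 0.7), A=e0[k] / 3,
                          S=s_rates[k], X=x_rates[k], R=3.75)
        for (j, k), r in coll.items():
            eng._C[eng.chains.index(chains[j]),
                   eng.chains.index(chains[k])] = r * e0[k]
        xacc = {k: 0.0 for k in chains}
        t_prev = 0.0
        for e in train.events:
            eng.advance_to(e.onset)
            for k, c in chains.items():
                xacc[k] += x_rates[k] * (e.onset - t_prev) / 1000.0
                while xacc[k] >= 1.0:
                    eng.register_rediscovery(c, e.onset)
                    xacc[k] -= 1.0
            t_prev = e.onset
            matchers = []
            for c in chains.values():
                c.generate_until(e.onset + w_t)
                if c.try_match(e, ap):
                    matchers.append(c)
            import itertools as _it
            for x, y in _it.combinations(matchers, 2):
                eng.register_collision(x, y, e.onset)
            for c in matchers:
                eng.register_success(c, e.onset)
            eng.register_input_event(e.onset)
            for c in chains.values():
                c.drop_resolved(e.onset, w_t)
        eng.finalize()
        last = {k: float(np.nanmean(eng.trace_E[c.id][-300:]))
                for k, c in chains.items()}
        finals.append("seg" if max(last["A"], last["B"]) > last["ABA"]
                      else "int")
        drifts.append(max(abs(eng.trace_F[c.id][-1] - eng.trace_F[c.id][-200])
                          for c in chains.values()))
    return finals, drifts
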