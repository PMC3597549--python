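import itertools
import math

import numpy as np
import pytest

from chainstream import (AssemblyParams, DynamicsParams, StimulusSpec,
                        adaptation_step, generate_aba_train, ou_step,
                        run_installed, run_single, sigmoid)
from chainstream.assembly import canonical_chains
from chainstream.dynamics import CompetitionDynamics
from chainstream.readout import NONE, classify_traces, extract_phases


def integrate_rate_averages(delta_t, duration_s=70.0, skip_s=10.0):
    """Time-averaged S for the three canonical chains on an ABA- train.

    Integrates the leaky success traces exactly between events.
    """
    ap = AssemblyParams()
    dp = DynamicsParams(noise_on=False)
    train = generate_aba_train(StimulusSpec(16, delta_t, duration_s))
    chains = canonical_chains(16, delta_t)
    order = ["A", "B", "ABA"]
    objs = [chains[k] for k in order]
    tau = dp.tau_success
    S = {k: 0.0 for k in order}
    integral = {k: 0.0 for k in order}
    r_int = 0.0
    R = 0.0
    tau_r = dp.tau_rate
    t_prev = 0.0
    w_t = ap.match_width_time
    for e in train.events:
        gap = e.onset - t_prev
        for k in order:
            if e.onset > skip_s * 1000:
                lo = max(t_prev, skip_s * 1000)
                integral[k] += S[k] * math.exp(-(lo - t_prev) / tau) \
                    * tau * (1 - math.exp(-(e.onset - lo) / tau))
            S[k] *= math.exp(-gap / tau)
        if e.onset > skip_s * 1000:
            lo = max(t_prev, skip_s * 1000)
            r_int += R * math.exp(-(lo - t_prev) / tau_r) \
                * tau_r * (1 - math.exp(-(e.onset - lo) / tau_r))
        R *= math.exp(-gap / tau_r)
        R += 1000.0 / tau_r
        for k, c in zip(order, objs):
            c.generate_until(e.onset + w_t)
            if c.try_match(e, ap):
                S[k] += 1000.0 / tau
            c.drop_resolved(e.onset, w_t)
        t_prev = e.onset
    horizon = (t_prev - skip_s * 1000)
    means = {k: integral[k] / horizon for k in order}
    means["R"] = r_int / horizon
    return means


class TestRateSteadyStates:
    def test_success_rates_on_500ms_cycle(self):
        """A, B and integrated chains average 4, 2 and 6 successes/s."""
        means = integrate_rate_averages(delta_t=125)
        assert means["A"] == pytest.approx(4.0, rel=0.02)
        assert means["B"] == pytest.approx(2.0, rel=0.02)
        assert means["ABA"] == pytest.approx(6.0, rel=0.02)

    def test_input_event_rate_at_200ms(self):
        means = integrate_rate_averages(delta_t=200)
        assert means["R"] == pytest.approx(3.75, rel=0.02)

    def test_rate_doubles_with_presentation_rate(self):
        slow = integrate_rate_averages(delta_t=200)
        fast = integrate_rate_averages(delta_t=100)
        assert fast["R"] == pytest.approx(2 * slow["R"], rel=0.03)
        # success-to-rate ratios are rate invariant
        assert fast["A"] / fast["R"] == pytest.approx(slow["A"] / slow["R"],
                                                      rel=0.03)


class TestNoiseProcess:
    def test_zero_diffusion_decays_exponentially(self):
        u = 1.0
        for _ in range(500):
            u = ou_step(u, 1.0, 500.0, 0.0, 0.0)
        assert u == pytest.approx(math.exp(-1.0), rel=0.01)

    def test_autocorrelation_time_and_stationary_sd(self):
        rng = np.random.default_rng(42)
        n, dt, tau, sigma = 200_000, 1.0, 500.0, 0.3
        xi = rng.standard_normal(n)
        u = np.empty(n)
        u[0] = 0.0
        for i in range(1, n):
            u[i] = ou_step(u[i - 1], dt, tau, sigma, xi[i])
        u = u[5000:]
        assert np.std(u) == pytest.approx(sigma, rel=0.05)
        lag = 500
        rho = np.corrcoef(u[:-lag], u[lag:])[0, 1]
        assert rho == pytest.approx(math.exp(-1.0), abs=0.05)

    def test_chains_noise_paths_decorrelated(self, neutral_spec):
        run = run_single(neutral_spec, seed=2, keep_traces=True)
        # proxy: residual fast fluctuations of two different chains' E
        ids = list(run.traces_E)
        a, b = run.traces_E[ids[0]], run.traces_E[ids[1]]
        m = np.isfinite(a) & np.isfinite(b)
        da, db = np.diff(a[m]), np.diff(b[m])
        rho = np.corrcoef(da, db)[0, 1]
        assert abs(rho) < 0.35  # anticorrelation from competition only


class TestAdaptation:
    def test_decays_when_excitation_low(self):
        a = 0.3
        for _ in range(30_000):
            a = adaptation_step(a, 0.0, 1.0, 5000.0)
        assert a < 0.01

    def test_saturates_when_excitation_high(self):
        a = 0.0
        for _ in range(60_000):
            a = adaptation_step(a, 1.0, 1.0, 5000.0)
        assert a == pytest.approx(1.0 / 3.0, rel=0.02)

    def test_less_excited_chain_adapts_more_slowly(self):
        hi = lo = 0.0
        for _ in range(3000):
            hi = adaptation_step(hi, 0.9, 1.0, 5000.0)
            lo = adaptation_step(lo, 0.3, 1.0, 5000.0)
        assert lo < hi


class TestBoundsAndStructure:
    def test_state_variable_bounds_full_run(self, neutral_spec):
        run = run_single(StimulusSpec(16, 200, 60), seed=3, keep_traces=True)
        for tr in run.traces_E.values():
            vals = tr[np.isfinite(tr)]
            assert np.all(vals >= 0.0) and np.all(vals <= 1.0)

    def test_rate_variables_nonnegative(self):
        train = generate_aba_train(StimulusSpec(16, 200, 30))
        chains = list(canonical_chains(16, 200).values())
        eng = run_installed(train, chains, seed=4)
        for c in chains:
            st = eng.state_of(c)
            assert st.S >= 0 and st.R >= 0 and st.X >= 0
            assert all(v >= 0 for v in st.C.values())
            assert 0.0 <= st.E <= 1.0 and 0.0 <= st.I <= 1.0

    def test_suppressed_chains_keep_positive_excitation(self):
        train = generate_aba_train(StimulusSpec(16, 200, 60))
        chains = canonical_chains(16, 200)
        eng = run_installed(train, list(chains.values()),
                            DynamicsParams(noise_on=False), seed=5)
        for c in chains.values():
            tail = eng.trace_E[c.id][3000:]
            tail = tail[np.isfinite(tail)]
            assert tail.min() > 0.0

    def test_excitation_inherits_event_oscillations(self):
        """E carries per-event fine structure from the leaky rate drives."""
        train = generate_aba_train(StimulusSpec(16, 200, 40))
        chains = canonical_chains(16, 200)
        eng = run_installed(train, list(chains.values()),
                            DynamicsParams(noise_on=False), seed=6)
        dominant = max(chains.values(),
                       key=lambda c: np.nanmean(eng.trace_E[c.id][2000:]))
        tr = eng.trace_E[dominant.id][2000:3000]
        smooth = np.convolve(tr, np.ones(50) / 50, mode="same")
        ripple = np.std((tr - smooth)[100:-100])
        assert ripple > 1e-4

    def test_collision_structure_of_canonical_chains(self):
        """A and B streams never collide; every other pair does."""
        train = generate_aba_train(StimulusSpec(16, 200, 20))
        chains = canonical_chains(16, 200)
        eng = run_installed(train, list(chains.values()), seed=7)
        a, b, aba = chains["A"], chains["B"], chains["ABA"]
        assert eng.state_of(a).C[b.id] == 0.0
        assert eng.state_of(b).C[a.id] == 0.0
        assert eng.state_of(a).C[aba.id] > 0.0
        assert eng.state_of(b).C[aba.id] > 0.0
        assert eng.state_of(aba).C[a.id] > 0.0


class TestAttractorLandscape:
    def _final_config(self, eng, chains):
        e = {k: eng.trace_E[c.id] for k, c in chains.items()}
        last = {k: np.nanmean(v[-300:]) for k, v in e.items()}
        seg = max(last["A"], last["B"]) > last["ABA"]
        return "seg" if seg else "int", last

    def test_noise_off_converges_to_two_organisations(self):
        """Random excitation states settle into one of two organisations."""
        from conftest import attractor_probe
        finals, drifts = attractor_probe(n_trials=20, rng_seed=99)
        assert set(finals) == {"seg", "int"}  # both attractors reachable
        assert max(drifts) < 0.1              # trajectories are stationary

    def test_noise_off_never_switches_after_settling(self):
        train = generate_aba_train(StimulusSpec(16, 200, 120))
        chains = canonical_chains(16, 200)
        eng = run_installed(train, list(chains.values()),
                            DynamicsParams(noise_on=False), seed=8)
        labels = classify_traces(eng.trace_F, {chains["ABA"].id})
        settled = labels[2000:]  # after 20 s
        assert len(set(settled.tolist())) == 1

    def test_noise_on_switches(self):
        train = generate_aba_train(StimulusSpec(16, 200, 240))
        chains = canonical_chains(16, 200)
        eng = run_installed(train, list(chains.values()),
                            DynamicsParams(), seed=9)
        labels = classify_traces(eng.trace_F, {chains["ABA"].id})
        phases = [p for p in extract_phases(eng.sample_times, labels)
                  if p.label != NONE]
        assert len(phases) >= 3  # alternation at irregular intervals

    def test_rate_normalisation_across_delta_t(self):
        """Same pattern at two rates: comparable dominance proportions."""
        props = {}
        for dt in (100.0, 200.0):
            seg_time = tot = 0.0
            for seed in range(3):
                train = generate_aba_train(StimulusSpec(16, dt, 120))
                chains = canonical_chains(16, dt)
                eng = run_installed(train, list(chains.values()),
                                    DynamicsParams(), seed=seed)
                labels = classify_traces(eng.trace_F, {chains["ABA"].id})
                seg_time += np.sum(labels == "segregated")
                tot += np.sum(labels != NONE)
            props[dt] = seg_time / tot
        assert abs(props[100.0] - props[200.0]) < 0.35


def test_sigmoid_range_and_midpoint():
    assert sigmoid(0.0) == 0.5
    assert 0.0 <= sigmoid(-50.0) < 1e-20
    assert sigmoid(-sigmoid(50.0)) <= sigmoid(50.0) <= 1.0
    assert sigmoid(3.0) + sigmoid(-3.0) == pytest.approx(1.0)
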