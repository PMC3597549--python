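"""Full simulations: single trials, repeated conditions, grid sweeps.

A single trial wires the three stages together in event-time order: the
stimulus generator produces an ABA− train, the chain assembler processes
each tone onset (feeding success/collision/input/rediscovery impulses to
the dynamics engine as chains are discovered and admitted), the engine
integrates the competition between onsets, and the readout converts the
filtered excitation traces into a phase sequence.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .analysis import RunResult, phases_frame, summarize_condition
from .assembly import AssemblyParams, ChainAssembler, ClosedChain, match_feature
from .dynamics import CompetitionDynamics, DynamicsParams
from .readout import NONE, classify_traces, extract_phases
from .stimulus import EventSequence, StimulusSpec, generate_aba_train

__all__ = [
    "ExperimentConfig",
    "run_single",
    "run_condition",
    "run_grid",
    "run_installed",
    "DEFAULT_GRID",
]

#: The experiment's stimulus grid: Δf in semitones × Δt in ms.
DEFAULT_GRID: list[tuple[float, float]] = [
    (df, dt) for df in (4.0, 10.0, 16.0, 22.0) for dt in (100.0, 150.0, 200.0, 250.0)
]


@dataclass
class ExperimentConfig:
    grid: list = field(default_factory=lambda: list(DEFAULT_GRID))
    duration_s: float = 240.0
    n_runs: int = 15
    root_seed: int = 0
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    min_phase_ms: float = 300.0
    record_dt: float = 10.0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def _chain_role(chain: ClosedChain, params: AssemblyParams,
                base_frequency: float) -> str:
    classes = chain.feature_classes(params)
    if len(classes) >= 2:
        return "integrated"
    return "A" if match_feature(classes[0], base_frequency, params) else "B"


def run_single(spec: StimulusSpec | EventSequence,
               seed: int,
               assembly_params: Optional[AssemblyParams] = None,
               dynamics_params: Optional[DynamicsParams] = None,
               min_phase_ms: float = 300.0,
               record_dt: float = 10.0,
               keep_traces: bool = False,
               base_frequency: Optional[float] = None) -> RunResult:
    """Simulate one trial and return its phase sequence and logs.

    Deterministic for a given ``seed``: the root seed spawns independent
    sub-streams for the assembly draws and for the dynamical noise.
    """
    if isinstance(spec, EventSequence):
        train = spec
        delta_f, delta_t = float("nan"), float("nan")
        base = base_frequency if base_frequency is not None else (
            min(e.frequency for e in train.events) if train.events else 0.0)
        span_cap = None
    else:
        train = generate_aba_train(spec)
        delta_f, delta_t = spec.delta_f, spec.delta_t
        base = spec.base_frequency
        span_cap = 8.0 * spec.delta_t  # twice the longest expected period

    aparams = assembly_params if assembly_params is not None else AssemblyParams()
    if aparams.max_open_span is None and span_cap is not None:
        aparams = replace(aparams, max_open_span=span_cap)
    dparams = dynamics_params if dynamics_params is not None else DynamicsParams()

    ss_assembly, ss_noise = np.random.SeedSequence(seed).spawn(2)
    rng_assembly = np.random.default_rng(ss_assembly)
    rng_noise = np.random.default_rng(ss_noise)

    engine = CompetitionDynamics(dparams, rng_noise,
                                 duration_ms=train.total_duration,
                                 record_dt=record_dt)
    assembler = ChainAssembler(aparams, rng_assembly, listener=engine)

    for e in train.events:
        engine.advance_to(e.onset)
        assembler.process_event(e)
    engine.finalize()
    assembler.finalize(train.total_duration)

    chain_log = []
    roles = {}
    for entry in assembler.log:
        entry = dict(entry)
        cid = entry["chain_id"]
        freqs = entry.pop("frequencies", None)
        if cid not in roles:
            roles[cid] = _role_from_log(entry, freqs, aparams, base)
        entry["role"] = roles[cid]
        chain_log.append(entry)

    integrated_ids = {c.id for c in engine.history
                      if c.is_integrated(aparams)}
    if engine.history:
        labels = classify_traces(engine.trace_F, integrated_ids)
    else:
        labels = np.full(engine.n_samples, NONE, dtype=object)
    phases = extract_phases(engine.sample_times, labels, min_phase_ms)

    return RunResult(
        delta_f=delta_f, delta_t=delta_t, seed=seed,
        duration_ms=train.total_duration,
        phases=phases, times=engine.sample_times, labels=labels,
        chain_log=chain_log,
        traces_E=engine.trace_E if keep_traces else None,
        traces_F=engine.trace_F if keep_traces else None)


def _role_from_log(entry, freqs, params, base) -> str:
    if entry.get("n_features", 1) >= 2:
        return "integrated"
    if freqs:
        return "A" if match_feature(freqs[0], base, params) else "B"
    return "A" if "400" in str(entry.get("label", "")) else "B"


def condition_seed(root_seed: int, delta_f: float, delta_t: float, run: int) -> int:
    """Deterministic per-(condition, run) child seed below 2**31."""
    ss = np.random.SeedSequence(
        [int(root_seed), int(round(delta_f * 1000)), int(round(delta_t * 1000)), int(run)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_condition(delta_f: float, delta_t: float, *, n_runs: int = 15,
                  root_seed: int = 0, duration_s: float = 240.0,
                  assembly_params: Optional[AssemblyParams] = None,
                  dynamics_params: Optional[DynamicsParams] = None,
                  min_phase_ms: float = 300.0, record_dt: float = 10.0,
                  keep_traces: bool = False) -> list[RunResult]:
    """Repeat one stimulus condition ``n_runs`` times with distinct seeds."""
    spec = StimulusSpec(delta_f=delta_f, delta_t=delta_t, duration=duration_s)
    return [
        run_single(spec,
                   seed=condition_seed(root_seed, delta_f, delta_t, r),
                   assembly_params=assembly_params,
                   dynamics_params=dynamics_params,
                   min_phase_ms=min_phase_ms, record_dt=record_dt,
                   keep_traces=keep_traces)
        for r in range(n_runs)
    ]


def run_grid(config: ExperimentConfig) -> dict:
    """Run every condition of the grid; optionally write result files.

    Returns ``{(delta_f, delta_t): (runs, ConditionSummary)}`` and, when
    ``config.out_dir`` is set, writes per-condition phase tables (CSV),
    summaries (JSON) and a manifest with seeds and parameters.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    results = {}
    manifest = {
        "root_seed": config.root_seed,
        "duration_s": config.duration_s,
        "n_runs": config.n_runs,
        "assembly": asdict(config.assembly),
        "dynamics": asdict(config.dynamics),
        "conditions": [],
    }
    for delta_f, delta_t in config.grid:
        entry = {"delta_f": delta_f, "delta_t": delta_t,
                 "seeds": [condition_seed(config.root_seed, delta_f, delta_t, r)
                           for r in range(config.n_runs)]}
        try:
            runs = run_condition(
                delta_f, delta_t, n_runs=config.n_runs,
                root_seed=config.root_seed, duration_s=config.duration_s,
                assembly_params=config.assembly, dynamics_params=config.dynamics,
                min_phase_ms=config.min_phase_ms, record_dt=config.record_dt)
            summary = summarize_condition(runs)
            results[(delta_f, delta_t)] = (runs, summary)
            entry["status"] = "ok"
            if out:
                tag = f"df{delta_f:g}_dt{delta_t:g}"
                phases_frame(runs).to_csv(out / f"phases_{tag}.csv", index=False)
                with open(out / f"summary_{tag}.json", "w") as fh:
                    json.dump(summary.to_dict(), fh, indent=1)
        except Exception as exc:  # pragma: no cover - defensive
            entry["status"] = f"failed: {exc!r}"
        manifest["conditions"].append(entry)
    if out:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return results


def run_installed(train: EventSequence | StimulusSpec,
                  chains: Sequence[ClosedChain],
                  dynamics_params: Optional[DynamicsParams] = None,
                  assembly_params: Optional[AssemblyParams] = None,
                  seed: int = 0, record_dt: float = 10.0,
                  initial_states: Optional[dict] = None) -> CompetitionDynamics:
    """Run the competition with a fixed, pre-installed chain inventory.

    No assembly takes place: the supplied closed chains receive success,
    collision and input-rate impulses from the train and the dynamics are
    integrated.  Used to probe the attractor landscape (e.g. from random
    initial conditions with the noise switched off) and steady-state
    rates.  ``initial_states`` maps chain id -> dict of state overrides.
    """
    if isinstance(train, StimulusSpec):
        train = generate_aba_train(train)
    aparams = assembly_params or AssemblyParams()
    dparams = dynamics_params or DynamicsParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    engine = CompetitionDynamics(dparams, rng, duration_ms=train.total_duration,
                                 record_dt=record_dt)
    for c in chains:
        engine.add_chain(c)
    if initial_states:
        for c in chains:
            if c.id in initial_states:
                engine.set_state(c, **initial_states[c.id])
    w_t = aparams.match_width_time
    for e in train.events:
        engine.advance_to(e.onset)
        matchers = []
        for c in chains:
            c.generate_until(e.onset + w_t)
            if c.try_match(e, aparams):
                matchers.append(c)
        for a, b in itertools.combinations(matchers, 2):
            engine.register_collision(a, b, e.onset)
        for c in matchers:
            engine.register_success(c, e.onset)
        engine.register_input_event(e.onset)
        for c in chains:
            c.drop_resolved(e.onset, w_t)
    engine.finalize()
    return engine
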