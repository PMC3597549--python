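"""Event-driven discovery of repeating patterns ("chains").

Every input event starts a new *open* chain (a growing linear sequence of
events).  At each subsequent event an open chain probabilistically splits
into an include-branch (the event is appended) and a skip-branch (the
event is left out); if both branches fail the chain is deleted.  When the
first and last events of an open chain match in feature, a *closed* chain
(an immutable predicting loop) is spawned while the open copy is retained.
A closed chain must survive one probation cycle — every prediction matched
by an input event, every non-predicted event successfully skipped — after
which it enters the dynamical competition with probability ``p_compete``.
Closed chains whose predictions go unmatched are deleted; re-formed
duplicates of a competing chain are discarded and counted as
*rediscoveries* of the original.

Link probabilities
------------------
With ``d`` the feature distance (semitones) between the chain's last event
and the candidate, ``g`` the time gap in seconds, ``n`` the number of
competing chains predicting the candidate and ``dn`` how much better
predicted the candidate is than the chain's last event::

    p_include = exp(-beta_include_rate * (d**2 / g) - beta_include_npred * n)
    p_skip    = 0                       if the candidate matches an event
                                        already included in the chain
              = 1 - exp(-beta_skip_rate * (d / g)
                        - beta_skip_ndiff * max(0, dn))   otherwise

Inclusion is penalised by abrupt feature change (a distance-weighted
rate of change ``d**2/g``) and by the event being explained by other
chains; skipping is favoured by the plain rate of change ``d/g`` and by a
predictedness contrast: an event already claimed by more chains than the
chain's own tail is easy to leave out.  Because the penalty counts *other* chains,
a closing inclusion — one that would complete a loop — ignores
predictions made by chains equivalent to the loop being completed, so
an established chain cannot explain away its own rediscovery.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .stimulus import Event, semitone_distance

__all__ = [
    "AssemblyParams",
    "OpenChain",
    "ClosedChain",
    "PredictionLedger",
    "ChainAssembler",
    "match",
    "match_time",
    "match_feature",
    "p_include",
    "p_skip",
    "chains_equivalent",
    "canonical_chains",
]


@dataclass
class AssemblyParams:
    """Chain-building parameters (defaults are the published set)."""

    beta_include_rate: float = 0.00015  # per (ST^2/s) distance-weighted rate
    beta_include_npred: float = 1.0     # per predicting chain
    beta_skip_rate: float = 0.0055      # per (ST/s) of feature rate-of-change
    beta_skip_ndiff: float = 8.0        # per unit predictedness contrast
    match_width_time: float = 30.0      # ms
    match_width_feature: float = 0.5    # semitones
    p_compete: float = 0.2
    max_open_length: int = 6            # nodes; combinatorial cap
    max_open_span: Optional[float] = None  # ms; None = uncapped

    def __post_init__(self) -> None:
        for name in ("beta_include_rate", "beta_include_npred",
                     "beta_skip_rate", "beta_skip_ndiff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.match_width_time <= 0 or self.match_width_feature <= 0:
            raise ValueError("matching widths must be > 0")
        if not 0.0 <= self.p_compete <= 1.0:
            raise ValueError("p_compete must be in [0, 1]")


# ---------------------------------------------------------------------------
# matching

def match_time(t1: float, t2: float, params: AssemblyParams) -> bool:
    """Same-time decision, ignoring feature (strict boundary)."""
    return abs(t1 - t2) < params.match_width_time


def match_feature(f1: float, f2: float, params: AssemblyParams) -> bool:
    """Same-type decision, ignoring timing (strict boundary)."""
    return semitone_distance(f1, f2) < params.match_width_feature


def match(e1, e2, params: AssemblyParams) -> bool:
    """Full elliptical matching region in time-feature space.

    ``e1``/``e2`` may be events or predictions; anything with ``onset``/
    ``time`` and ``frequency`` attributes, or ``(time, frequency)`` pairs.
    The boundary is exclusive (strict inequality).
    """
    t1, f1 = _time_freq(e1)
    t2, f2 = _time_freq(e2)
    dt = (t1 - t2) / params.match_width_time
    df = semitone_distance(f1, f2) / params.match_width_feature
    return dt * dt + df * df < 1.0


def _time_freq(e) -> tuple[float, float]:
    if hasattr(e, "onset"):
        return e.onset, e.frequency
    if hasattr(e, "time"):
        return e.time, e.frequency
    t, f = e
    return t, f


# ---------------------------------------------------------------------------
# link probabilities


def p_include(prev: Event, nxt: Event, n_pred_next: int, params: AssemblyParams) -> float:
    """Probability that an open chain ending at ``prev`` absorbs ``nxt``."""
    gap_s = (nxt.onset - prev.onset) / 1000.0
    if gap_s <= 0:
        raise ValueError("next event must be later than the chain tail")
    d = semitone_distance(prev.frequency, nxt.frequency)
    rate = d * d / gap_s  # distance-weighted rate of change
    return math.exp(-params.beta_include_rate * rate
                    - params.beta_include_npred * n_pred_next)


def p_skip(prev: Event, nxt: Event, delta_n_pred: int,
           included_frequencies: Sequence[float], params: AssemblyParams) -> float:
    """Probability that a chain ending at ``prev`` skips over ``nxt``.

    Zero whenever ``nxt`` matches (in feature) an event the chain has
    already included: a chain cannot skip the same event it contains.
    """
    gap_s = (nxt.onset - prev.onset) / 1000.0
    if gap_s <= 0:
        raise ValueError("next event must be later than the chain tail")
    for f in included_frequencies:
        if match_feature(f, nxt.frequency, params):
            return 0.0
    d = semitone_distance(prev.frequency, nxt.frequency)
    contrast = max(0, delta_n_pred)
    return 1.0 - math.exp(-params.beta_skip_rate * d / gap_s
                          - params.beta_skip_ndiff * contrast)


# ---------------------------------------------------------------------------
# chain types

@dataclass
class OpenChain:
    """A growing linear sequence of absorbed events."""

    nodes: list[Event]
    creation_time: float
    tail_n_pred: int = 0  # predictedness of the tail event when absorbed

    @property
    def first(self) -> Event:
        return self.nodes[0]

    @property
    def tail(self) -> Event:
        return self.nodes[-1]

    @property
    def span(self) -> float:
        return self.tail.onset - self.first.onset

    def included_frequencies(self) -> list[float]:
        return [e.frequency for e in self.nodes]


class ClosedChain:
    """An immutable predicting loop.

    ``cycle`` is a list of ``(offset_ms, frequency)`` templates relative to
    the loop origin; predictions are emitted indefinitely at
    ``origin + k * period + offset``.
    """

    _ids = itertools.count()

    def __init__(self, cycle: Sequence[tuple[float, float]], period: float,
                 origin: float, closed_at: float, label: str = ""):
        if period <= 0:
            raise ValueError("period must be > 0")
        if not cycle:
            raise ValueError("cycle must be non-empty")
        self.id = next(self._ids)
        self.cycle = [(float(o), float(f)) for o, f in cycle]
        self.period = float(period)
        self.origin = float(origin)
        self.closed_at = float(closed_at)
        self.label = label
        self.competitive = False
        self.alive = True
        self.in_probation = True
        self.probation_end = self.closed_at + self.period
        self.admitted_at: Optional[float] = None
        self.died_at: Optional[float] = None
        self.rediscoveries = 0
        # pending predictions: [time, freq, matched]
        self._pending: list[list] = []
        self._k = 0  # index into the infinite prediction stream
        self._skip_to(self.closed_at)

    # -- prediction stream -------------------------------------------------
    def _pred_at(self, k: int) -> tuple[float, float]:
        m = len(self.cycle)
        off, f = self.cycle[k % m]
        return self.origin + (k // m) * self.period + off, f

    def _skip_to(self, t: float) -> None:
        while self._pred_at(self._k)[0] <= t:
            self._k += 1

    def generate_until(self, t: float) -> None:
        """Extend the pending list with predictions at times <= ``t``."""
        while True:
            pt, pf = self._pred_at(self._k)
            if pt > t:
                break
            self._pending.append([pt, pf, False])
            self._k += 1

    def predictions_between(self, t0: float, t1: float) -> list[tuple[float, float]]:
        """Prediction stream restricted to ``(t0, t1]`` (bookkeeping-free)."""
        out = []
        m = len(self.cycle)
        k = 0
        while True:
            off, f = self.cycle[k % m]
            pt = self.origin + (k // m) * self.period + off
            if pt > t1:
                break
            if pt > t0:
                out.append((pt, f))
            k += 1
        return out

    # -- bookkeeping --------------------------------------------------------
    def overdue(self, t: float, w_t: float) -> list[list]:
        return [p for p in self._pending if not p[2] and p[0] < t - w_t]

    def try_match(self, e: Event, params: AssemblyParams) -> bool:
        for p in self._pending:
            if not p[2] and match((p[0], p[1]), e, params):
                p[2] = True
                return True
        return False

    def predicts(self, e: Event, params: AssemblyParams) -> bool:
        return any(not p[2] and match((p[0], p[1]), e, params) for p in self._pending)

    def drop_resolved(self, t: float, w_t: float) -> None:
        self._pending = [p for p in self._pending if not p[2] or p[0] >= t - w_t]

    def feature_classes(self, params: AssemblyParams) -> list[float]:
        """Distinct cycle frequencies, clustered by the feature match width."""
        classes: list[float] = []
        for _, f in self.cycle:
            if not any(match_feature(f, c, params) for c in classes):
                classes.append(f)
        return classes

    def is_integrated(self, params: AssemblyParams) -> bool:
        return len(self.feature_classes(params)) >= 2

    def __repr__(self) -> str:  # pragma: no cover
        return (f"ClosedChain(id={self.id}, label={self.label!r}, "
                f"period={self.period}, competitive={self.competitive})")


def chains_equivalent(c1: ClosedChain, c2: ClosedChain, params: AssemblyParams,
                      t_now: Optional[float] = None) -> bool:
    """True iff the two loops predict matching events over two cycles.

    Every prediction of one chain inside a two-cycle horizon starting now
    must match (elliptically) a prediction of the other, and vice versa.
    """
    if t_now is None:
        t_now = max(c1.closed_at, c2.closed_at)
    horizon = 2.0 * max(c1.period, c2.period)
    w_t = params.match_width_time
    p1 = c1.predictions_between(t_now, t_now + horizon)
    p2 = c2.predictions_between(t_now - w_t, t_now + horizon + w_t)
    if not _all_covered(p1, p2, params, t_now, horizon, w_t):
        return False
    p2in = c2.predictions_between(t_now, t_now + horizon)
    p1w = c1.predictions_between(t_now - w_t, t_now + horizon + w_t)
    return _all_covered(p2in, p1w, params, t_now, horizon, w_t)


def _all_covered(preds, pool, params, t_now, horizon, w_t) -> bool:
    for pt, pf in preds:
        if pt > t_now + horizon - w_t:
            continue  # too close to the horizon edge to demand a partner
        if not any(match((pt, pf), (qt, qf), params) for qt, qf in pool):
            return False
    return True


@dataclass
class PredictionLedger:
    """Per-event predictedness counts used by the link probabilities."""

    counts: dict[float, int] = field(default_factory=dict)

    def record(self, onset: float, n_pred: int) -> None:
        self.counts[onset] = n_pred

    def n_pred(self, onset: float) -> int:
        return self.counts.get(onset, 0)


# ---------------------------------------------------------------------------
# assembler

class ChainAssembler:
    """Event-driven population of open and closed chains.

    Parameters
    ----------
    params : AssemblyParams
    rng : numpy Generator driving the branch, probation and admission draws.
    listener : optional object receiving dynamical impulses; any subset of
        the methods ``on_success(chain, t)``, ``on_collision(c1, c2, t)``,
        ``on_input_event(t)``, ``on_rediscovery(chain, t)``,
        ``on_admitted(chain, t)``, ``on_removed(chain, t)`` is used.
    branch_mode : "sample" (default) draws Bernoulli branches; "force" makes
        every branch with non-zero probability succeed and admits every
        chain that survives probation (used for worked-example traces).
    """

    def __init__(self, params: AssemblyParams, rng: np.random.Generator,
                 listener=None, branch_mode: str = "sample"):
        if branch_mode not in ("sample", "force"):
            raise ValueError("branch_mode must be 'sample' or 'force'")
        self.params = params
        self.rng = rng
        self.listener = listener
        self.branch_mode = branch_mode
        self.open_chains: list[OpenChain] = []
        self.probation_chains: list[ClosedChain] = []
        self.competitive_chains: list[ClosedChain] = []
        self.ledger = PredictionLedger()
        self.log: list[dict] = []
        self._last_event_time = -math.inf

    # -- draws --------------------------------------------------------------
    def _bernoulli(self, p: float) -> bool:
        if self.branch_mode == "force":
            return p > 0.0
        return self.rng.random() < p

    def _notify(self, name: str, *args) -> None:
        fn = getattr(self.listener, name, None)
        if fn is not None:
            fn(*args)

    # -- main entry ---------------------------------------------------------
    def process_event(self, e: Event) -> None:
        if e.onset <= self._last_event_time:
            raise ValueError("events must be processed in strictly increasing time")
        self._last_event_time = e.onset
        t = e.onset
        w_t = self.params.match_width_time

        for c in self.probation_chains + self.competitive_chains:
            c.generate_until(t + w_t)

        self._resolve_failures(t)
        self._probation_decisions(t)

        # predictedness of this event among competing chains
        n_e = sum(1 for c in self.competitive_chains if c.predicts(e, self.params))
        self.ledger.record(t, n_e)

        # matching, successes, collisions, normalisation
        matchers: list[ClosedChain] = []
        for c in list(self.probation_chains) + list(self.competitive_chains):
            if c.try_match(e, self.params):
                matchers.append(c)
                c.last_matched = (t, e.frequency, n_e)
                if c.competitive:
                    self._notify("on_success", c, t)
        comp_matchers = [c for c in matchers if c.competitive]
        for a, b in itertools.combinations(comp_matchers, 2):
            self._notify("on_collision", a, b, t)
        self._notify("on_input_event", t)

        # probation skip draws for non-predicted events
        for c in list(self.probation_chains):
            if c in matchers or t > c.probation_end:
                continue
            if not self._probation_skip(c, e, n_e):
                self._kill(c, t, reason="probation-skip-failed")

        self._extend_population(e, n_e)

        # a fresh singleton chain for every input event
        self.open_chains.append(OpenChain([e], creation_time=t, tail_n_pred=n_e))

        for c in self.probation_chains + self.competitive_chains:
            c.drop_resolved(t, w_t)

    def finalize(self, t_end: float) -> None:
        """Resolve outstanding predictions up to the end of the stimulus."""
        w_t = self.params.match_width_time
        for c in self.probation_chains + self.competitive_chains:
            c.generate_until(t_end - w_t)
        self._resolve_failures(t_end)
        self._probation_decisions(t_end)

    # -- stages -------------------------------------------------------------
    def _resolve_failures(self, t: float) -> None:
        w_t = self.params.match_width_time
        for c in list(self.probation_chains) + list(self.competitive_chains):
            if c.overdue(t, w_t):
                self._kill(c, t, reason="failed-prediction")

    def _probation_decisions(self, t: float) -> None:
        w_t = self.params.match_width_time
        for c in list(self.probation_chains):
            if t <= c.probation_end + w_t:
                continue
            # probation window fully resolved without failure
            self.probation_chains.remove(c)
            c.in_probation = False
            original = self._find_duplicate(c, t)
            if original is not None:
                # a re-formed copy of a competing chain: count the
                # rediscovery and discard the copy
                original.rediscoveries += 1
                self._notify("on_rediscovery", original, t)
                self._log("rediscovery", original, t)
            elif self._bernoulli(self.params.p_compete):
                c.competitive = True
                c.admitted_at = t
                self.competitive_chains.append(c)
                self._notify("on_admitted", c, t)
                self._log("admitted", c, t)
            else:
                c.alive = False
                c.died_at = t

    def _probation_skip(self, c: ClosedChain, e: Event, n_e: int) -> bool:
        """Skip draw for an event a probation chain does not predict."""
        for f in (f for _, f in c.cycle):
            if match_feature(f, e.frequency, self.params):
                return False  # cannot skip an event type the chain contains
        prev = getattr(c, "last_matched", None)
        if prev is None:
            prev_t, prev_f, prev_n = c.closed_at, c.cycle[0][1], 0
        else:
            prev_t, prev_f, prev_n = prev
        gap_s = max((e.onset - prev_t) / 1000.0, 1e-9)
        d = semitone_distance(prev_f, e.frequency)
        p = 1.0 - math.exp(-self.params.beta_skip_rate * d / gap_s
                           - self.params.beta_skip_ndiff * max(0, n_e - prev_n))
        return self._bernoulli(p)

    def _extend_population(self, e: Event, n_e: int) -> None:
        params = self.params
        survivors: list[OpenChain] = []
        for chain in self.open_chains:
            if params.max_open_span is not None and \
                    e.onset - chain.first.onset > params.max_open_span:
                continue  # grew too long without closure
            closing = match_feature(chain.first.frequency, e.frequency, params)
            n_inc = self._n_pred_for_include(chain, e, n_e) if closing else n_e
            pi = p_include(chain.tail, e, n_inc, params)
            ps = p_skip(chain.tail, e, n_e - chain.tail_n_pred,
                        chain.included_frequencies(), params)
            included = self._bernoulli(pi)
            skipped = self._bernoulli(ps)
            if included:
                child = OpenChain(chain.nodes + [e], chain.creation_time, n_e)
                if len(child.nodes) <= params.max_open_length:
                    survivors.append(child)
                    if match_feature(child.first.frequency, e.frequency, params):
                        self._close(child, e, n_e)
            if skipped:
                survivors.append(chain)
        self.open_chains = survivors

    def _n_pred_for_include(self, chain: OpenChain, e: Event, n_e: int) -> int:
        """Predictedness of ``e`` for a loop-closing inclusion.

        Competing chains equivalent to the loop the inclusion would
        complete are not counted: a chain's own predictions cannot
        explain away its own rediscovery.
        """
        predictors = [c for c in self.competitive_chains
                      if c.predicts(e, self.params)]
        if not predictors:
            return 0
        first = chain.first
        period = e.onset - first.onset
        cycle = [(n.onset - first.onset, n.frequency) for n in chain.nodes]
        candidate = ClosedChain(cycle, period, origin=first.onset,
                                closed_at=e.onset)
        n = sum(1 for c in predictors
                if not chains_equivalent(candidate, c, self.params,
                                         t_now=e.onset))
        return n

    def _close(self, chain: OpenChain, e: Event, n_e: int = 0) -> None:
        """Spawn the closed loop for an open chain whose ends match.

        A loop equivalent to a chain already in the competition is not
        rebuilt: the copy is discarded immediately and counted as a
        rediscovery of the original.
        """
        first = chain.first
        period = e.onset - first.onset
        cycle = [(n.onset - first.onset, n.frequency) for n in chain.nodes[:-1]]
        c = ClosedChain(cycle, period, origin=first.onset, closed_at=e.onset,
                        label=self._label(cycle, period))
        c.last_matched = (e.onset, e.frequency, n_e)
        self.probation_chains.append(c)
        self._log("closed", c, e.onset)

    def _find_duplicate(self, c: ClosedChain, t: float) -> Optional[ClosedChain]:
        for other in self.competitive_chains:
            if chains_equivalent(c, other, self.params, t_now=t):
                return other
        return None

    def _kill(self, c: ClosedChain, t: float, reason: str) -> None:
        c.alive = False
        c.died_at = t
        if c in self.probation_chains:
            self.probation_chains.remove(c)
        if c in self.competitive_chains:
            self.competitive_chains.remove(c)
            self._notify("on_removed", c, t)
        self._log(reason, c, t)

    def _label(self, cycle, period) -> str:
        freqs = sorted({f for _, f in cycle})
        return "/".join(f"{f:.0f}Hz@{o:.0f}ms" for o, f in cycle) + f"%{period:.0f}ms"

    def _log(self, kind: str, c: ClosedChain, t: float) -> None:
        classes = c.feature_classes(self.params)
        self.log.append({
            "time_ms": t, "kind": kind, "chain_id": c.id, "label": c.label,
            "period_ms": c.period,
            "n_features": len(classes),
            "frequencies": sorted(classes),
        })


# ---------------------------------------------------------------------------
# canonical chains for dynamics-only experiments

def canonical_chains(delta_f: float, delta_t: float, base_frequency: float = 400.0,
                     start: float = 0.0) -> dict[str, ClosedChain]:
    """The three loops most often discovered on an ABA− train.

    Returns ``{"ABA": ..., "A": ..., "B": ...}`` — the integrated loop
    (period 4·Δt, predicting every tone), the A stream (period 2·Δt) and
    the B stream (period 4·Δt).  ``start`` shifts the loop origins (ms).
    """
    f_a = base_frequency
    f_b = base_frequency * 2.0 ** (delta_f / 12.0)
    aba = ClosedChain([(0.0, f_a), (delta_t, f_b), (2 * delta_t, f_a)],
                      period=4 * delta_t, origin=start, closed_at=start, label="ABA-")
    a = ClosedChain([(0.0, f_a)], period=2 * delta_t, origin=start,
                    closed_at=start, label="A-")
    b = ClosedChain([(delta_t, f_b)], period=4 * delta_t, origin=start,
                    closed_at=start, label="-B--")
    for c in (aba, a, b):
        c.in_probation = False
        c.competitive = True
        c.admitted_at = start
    return {"ABA": aba, "A": a, "B": b}
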