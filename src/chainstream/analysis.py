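"""Summary statistics over simulated runs.

The analyses mirror the standard treatment of bistability button-press
data: the first classified phase of each run is analysed separately from
the subsequent phases, segregation dominance is time-weighted, the
probability-of-segregation time course is averaged across runs and
smoothed with a 2-s moving window, and log phase durations are tested
for normality with Shapiro-Wilk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .readout import INTEGRATED, NONE, SEGREGATED, Phase

__all__ = [
    "RunResult",
    "ConditionSummary",
    "classified_phases",
    "first_phase_stats",
    "subsequent_phase_stats",
    "segregation_time_course",
    "lognormality_test",
    "phase_histogram",
    "phases_frame",
    "summarize_condition",
]


@dataclass
class RunResult:
    """Everything retained from one simulated trial."""

    delta_f: float
    delta_t: float
    seed: int
    duration_ms: float
    phases: list[Phase]
    times: np.ndarray                  # decimated sample times (ms)
    labels: np.ndarray                 # percept label per sample
    chain_log: list[dict] = field(default_factory=list)
    traces_E: Optional[dict] = None
    traces_F: Optional[dict] = None

    def first_chain_time(self, kind: str) -> Optional[float]:
        """Time (ms) a chain of the given kind first entered the competition.

        ``kind`` is one of ``"integrated"``, ``"A"`` (low single stream),
        ``"B"`` (high single stream); None if never admitted.
        """
        for entry in self.chain_log:
            if entry["kind"] == "admitted" and entry.get("role") == kind:
                return entry["time_ms"]
        return None


@dataclass
class ConditionSummary:
    delta_f: float
    delta_t: float
    n_runs: int
    first_segregated_fraction: float
    mean_first_phase_duration_s: float
    subsequent_segregated_proportion: float
    mean_subsequent_phase_duration_s: float
    mean_phase_duration_s: float
    n_phases: int
    time_course_times_s: np.ndarray
    time_course_p_segregated: np.ndarray

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["time_course_times_s"] = np.asarray(self.time_course_times_s).tolist()
        d["time_course_p_segregated"] = np.asarray(self.time_course_p_segregated).tolist()
        return d


def classified_phases(run: RunResult) -> list[Phase]:
    """The run's phases with the unclassified ("none") stretches removed."""
    return [p for p in run.phases if p.label != NONE]


def phases_frame(runs: Sequence[RunResult], run_ids: Optional[Sequence] = None) -> pd.DataFrame:
    """Tidy phase table: one row per classified phase of every run."""
    rows = []
    for i, run in enumerate(runs):
        rid = run_ids[i] if run_ids is not None else i
        for j, p in enumerate(classified_phases(run)):
            rows.append({
                "run_id": rid, "delta_f": run.delta_f, "delta_t": run.delta_t,
                "phase_index": j, "label": p.label,
                "start_ms": p.start, "end_ms": p.end, "duration_ms": p.duration,
            })
    return pd.DataFrame(rows, columns=["run_id", "delta_f", "delta_t",
                                       "phase_index", "label", "start_ms",
                                       "end_ms", "duration_ms"])


def first_phase_stats(runs: Sequence[RunResult]) -> tuple[float, float, int]:
    """First-phase choice and duration.

    Returns ``(fraction_segregated_first, mean_first_duration_s,
    n_excluded)`` where the first phase is each run's first classified
    phase (integrated and segregated durations pooled) and runs without
    any classified phase are excluded but counted.
    """
    firsts = []
    excluded = 0
    for run in runs:
        ph = classified_phases(run)
        if not ph:
            excluded += 1
            continue
        firsts.append(ph[0])
    if not firsts:
        raise ValueError("no run contributed a classified phase")
    frac_seg = float(np.mean([p.label == SEGREGATED for p in firsts]))
    mean_dur = float(np.mean([p.duration for p in firsts])) / 1000.0
    return frac_seg, mean_dur, excluded


def subsequent_phase_stats(runs: Sequence[RunResult]) -> tuple[float, float, int]:
    """Time-weighted segregation proportion and mean duration after phase 1.

    Returns ``(proportion_segregated, mean_duration_s, n_without_subsequent)``.
    Runs with no phases beyond the first contribute nothing here; grid-level
    summaries impute them from the same run's other conditions (see
    :func:`impute_grid`).
    """
    seg_time = 0.0
    total_time = 0.0
    durations = []
    missing = 0
    for run in runs:
        ph = classified_phases(run)[1:]
        if not ph:
            missing += 1
            continue
        for p in ph:
            total_time += p.duration
            if p.label == SEGREGATED:
                seg_time += p.duration
            durations.append(p.duration)
    if total_time == 0:
        return float("nan"), float("nan"), missing
    return seg_time / total_time, float(np.mean(durations)) / 1000.0, missing


def impute_grid(per_condition: pd.DataFrame, value_col: str,
                run_col: str = "run_id") -> pd.DataFrame:
    """Replace missing per-run condition values by that run's mean elsewhere.

    Mirrors the missing-data rule used for participants: when a run (the
    model analogue of a participant) yields no subsequent phases in some
    condition, the value is replaced by the run's average over the
    conditions where it did.
    """
    out = per_condition.copy()
    means = out.groupby(run_col)[value_col].transform("mean")
    out[value_col] = out[value_col].fillna(means)
    return out


def segregation_time_course(runs: Sequence[RunResult],
                            window_s: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """P(segregated) at each time point, smoothed with a moving average.

    The indicator is 1 while segregation is reported and 0 otherwise
    ("none" counts as not reporting segregation), averaged pointwise
    across runs, then smoothed with a centred sliding window.
    """
    if not runs:
        raise ValueError("no runs supplied")
    times = runs[0].times
    for run in runs:
        if len(run.times) != len(times) or not np.allclose(run.times, times):
            raise ValueError("runs must share a time grid")
    ind = np.mean([(run.labels == SEGREGATED).astype(float) for run in runs], axis=0)
    step_s = (times[1] - times[0]) / 1000.0 if len(times) > 1 else 1.0
    w = max(1, int(round(window_s / step_s)))
    kernel = np.ones(w) / w
    # centred moving average; shrink the window near the edges
    smoothed = np.convolve(ind, kernel, mode="same")
    norm = np.convolve(np.ones_like(ind), kernel, mode="same")
    return times / 1000.0, smoothed / norm


def lognormality_test(durations_ms: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W test on the logarithms of phase durations (in ms)."""
    d = np.asarray(durations_ms, dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 durations")
    if np.ptp(d) == 0:
        raise ValueError("degenerate sample: all durations identical")
    w, p = stats.shapiro(np.log(d))
    return float(w), float(p)


def phase_histogram(durations_ms: Sequence[float],
                    bin_width_ms: float,
                    max_ms: Optional[float] = None) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of phase durations; returns (counts, bin_edges)."""
    d = np.asarray(durations_ms, dtype=float)
    if max_ms is None:
        max_ms = float(d.max()) if len(d) else bin_width_ms
    edges = np.arange(0.0, max_ms + bin_width_ms, bin_width_ms)
    counts, edges = np.histogram(d, bins=edges)
    return counts, edges


def summarize_condition(runs: Sequence[RunResult]) -> ConditionSummary:
    frac_seg, mean_first, _ = first_phase_stats(runs)
    prop_seg, mean_sub, _ = subsequent_phase_stats(runs)
    all_durations = [p.duration for run in runs for p in classified_phases(run)]
    tc_t, tc_p = segregation_time_course(runs)
    return ConditionSummary(
        delta_f=runs[0].delta_f, delta_t=runs[0].delta_t, n_runs=len(runs),
        first_segregated_fraction=frac_seg,
        mean_first_phase_duration_s=mean_first,
        subsequent_segregated_proportion=prop_seg,
        mean_subsequent_phase_duration_s=mean_sub,
        mean_phase_duration_s=float(np.mean(all_durations)) / 1000.0
        if all_durations else float("nan"),
        n_phases=len(all_durations),
        time_course_times_s=tc_t, time_course_p_segregated=tc_p)
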