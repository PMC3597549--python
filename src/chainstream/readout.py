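"""Mapping chain excitations onto categorical percept reports.

The readout mirrors the two-button forced choice of streaming
experiments: at each time sample the low-pass filtered excitation of the
integrated chain (the one predicting both frequency classes) is compared
with the filtered excitations of the segregated chains (those predicting
a single class).  *Integrated* is reported when the integrated chain
beats every segregated chain, *segregated* when any segregated chain
beats it (or when only segregated chains exist), and *none* when no
chain is in the competition.  Maximal constant-label runs form
perceptual phases; phases shorter than 300 ms are discarded and absorbed
into their neighbours, mirroring the treatment of human button presses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["NONE", "INTEGRATED", "SEGREGATED", "Phase",
           "classify_traces", "classify", "extract_phases"]

NONE = "none"
INTEGRATED = "integrated"
SEGREGATED = "segregated"


@dataclass(frozen=True)
class Phase:
    """A maximal stretch of one continuously reported percept (ms)."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("phase end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


def classify(integrated_excitations: Sequence[float],
             segregated_excitations: Sequence[float]) -> str:
    """Label one time sample from (filtered) excitation values.

    Values are for the currently competitive chains only; pass empty
    sequences for absent roles.
    """
    ints = [e for e in integrated_excitations if np.isfinite(e)]
    segs = [e for e in segregated_excitations if np.isfinite(e)]
    if not ints and not segs:
        return NONE
    if not segs:
        return INTEGRATED
    if not ints:
        return SEGREGATED
    return INTEGRATED if max(ints) > max(segs) else SEGREGATED


def classify_traces(filtered: dict[int, np.ndarray],
                    integrated_ids: set[int]) -> np.ndarray:
    """Vectorised labelling of a whole run.

    Parameters
    ----------
    filtered : mapping of chain id -> filtered-excitation trace
        (NaN where the chain is not competitive).
    integrated_ids : ids of the integrated-role chains.

    Returns an object array of labels, one per time sample.
    """
    if not filtered:
        raise ValueError("no traces supplied")
    n = len(next(iter(filtered.values())))
    int_max = np.full(n, -np.inf)
    seg_max = np.full(n, -np.inf)
    for cid, tr in filtered.items():
        target = int_max if cid in integrated_ids else seg_max
        np.fmax(target, np.where(np.isnan(tr), -np.inf, tr), out=target)
    labels = np.full(n, NONE, dtype=object)
    has_int = int_max > -np.inf
    has_seg = seg_max > -np.inf
    labels[has_int & ~has_seg] = INTEGRATED
    labels[has_seg & ~has_int] = SEGREGATED
    both = has_int & has_seg
    labels[both] = np.where(int_max[both] > seg_max[both], INTEGRATED, SEGREGATED)
    return labels


def extract_phases(times: np.ndarray, labels: np.ndarray,
                   min_duration: float = 300.0) -> list[Phase]:
    """Run-length encode a label series into phases.

    ``times`` are sample times in ms on a uniform grid; each label is
    taken to hold from its sample up to the next one.  Runs shorter than
    ``min_duration`` are discarded (shortest first) and absorbed into
    their neighbours; set ``min_duration=0`` to keep everything.
    """
    times = np.asarray(times, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if len(times) != len(labels):
        raise ValueError("times and labels must align")
    if len(times) == 0:
        return []
    step = times[1] - times[0] if len(times) > 1 else 0.0
    end_time = times[-1] + step
    runs: list[list] = []  # [start, end, label]
    for t, lab in zip(times, labels):
        if runs and runs[-1][2] == lab:
            runs[-1][1] = t + step
        else:
            runs.append([t, t + step, lab])
    if runs:
        runs[-1][1] = end_time

    def merge_adjacent(rs):
        out = []
        for r in rs:
            if out and out[-1][2] == r[2]:
                out[-1][1] = r[1]
            else:
                out.append(r)
        return out

    while min_duration > 0 and len(runs) > 1:
        durations = [r[1] - r[0] for r in runs]
        i = int(np.argmin(durations))
        if durations[i] >= min_duration:
            break
        r = runs.pop(i)
        if i > 0:
            runs[i - 1][1] = r[1]  # absorbed into the preceding phase
        else:
            runs[0][0] = r[0]
        runs = merge_adjacent(runs)
    return [Phase(r[0], r[1], r[2]) for r in runs]
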