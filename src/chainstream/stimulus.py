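"""Tone-sequence stimuli for auditory streaming simulations.

The model operates on discrete *events* (tone onsets).  The canonical
stimulus is the ABA− galloping train used in streaming experiments: a
low tone A, a higher tone B, A again, then a silent slot, repeating with
onset-to-onset interval ``delta_t``.  The A frequency is fixed (400 Hz by
default) and B lies ``delta_f`` semitones above it.  Arbitrary repetitive
tone patterns can be constructed directly from :class:`Event` lists or
imported from CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Event",
    "EventSequence",
    "StimulusSpec",
    "semitone_distance",
    "generate_aba_train",
]

#: Default tone length in ms (onset-based model; carried for completeness).
DEFAULT_TONE_DURATION_MS = 75.0


@dataclass(frozen=True)
class Event:
    """One discrete tone onset.

    Parameters
    ----------
    onset : float
        Onset time in ms (>= 0).
    frequency : float
        Tone frequency in Hz (> 0).
    duration : float
        Tone length in ms.  Unused by chain assembly and dynamics, which
        are onset-based.
    """

    onset: float
    frequency: float
    duration: float = DEFAULT_TONE_DURATION_MS

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset}")
        if self.frequency <= 0:
            raise ValueError(f"event frequency must be > 0, got {self.frequency}")


@dataclass
class EventSequence:
    """An ordered train of events plus the total stimulus duration (ms)."""

    events: list[Event]
    total_duration: float

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("events must be strictly ordered by onset")
        seen = {(e.onset, e.frequency) for e in self.events}
        if len(seen) != len(self.events):
            raise ValueError("duplicate (onset, frequency) pair in sequence")
        if self.events and self.events[-1].onset >= self.total_duration:
            raise ValueError("event onsets must precede total_duration")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_ms": [e.onset for e in self.events],
                "frequency_hz": [e.frequency for e in self.events],
                "duration_ms": [e.duration for e in self.events],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, total_duration: float | None = None) -> "EventSequence":
        events = [
            Event(float(r.onset_ms), float(r.frequency_hz), float(r.duration_ms))
            for r in frame.itertuples()
        ]
        if total_duration is None:
            total_duration = (events[-1].onset + events[-1].duration) if events else 0.0
        return cls(events, float(total_duration))

    @classmethod
    def from_csv(cls, path, total_duration: float | None = None) -> "EventSequence":
        return cls.from_frame(pd.read_csv(path), total_duration)


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of an ABA− train.

    ``delta_f`` is the A-to-B separation in semitones, ``delta_t`` the
    onset-to-onset interval in ms (so one ABA− cycle lasts ``4 * delta_t``),
    ``duration`` the train length in seconds.
    """

    delta_f: float
    delta_t: float
    duration: float
    base_frequency: float = 400.0
    tone_duration: float = DEFAULT_TONE_DURATION_MS

    def __post_init__(self) -> None:
        if self.delta_t <= 0:
            raise ValueError("delta_t must be > 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.base_frequency <= 0:
            raise ValueError("base_frequency must be > 0")


def semitone_distance(f1: float, f2: float) -> float:
    """Distance between two frequencies in semitones (12 per octave).

    Symmetric and non-negative:  d = |12 * log2(f2 / f1)|.
    """
    if f1 <= 0 or f2 <= 0:
        raise ValueError("frequencies must be positive")
    return abs(12.0 * math.log2(f2 / f1))


def semitones_above(base: float, semitones: float) -> float:
    """Frequency ``semitones`` above ``base`` on the equal-tempered scale."""
    return base * 2.0 ** (semitones / 12.0)


def generate_aba_train(spec: StimulusSpec) -> EventSequence:
    """Generate an ABA− train.

    Each 4·Δt cycle holds A at offset 0, B at Δt, A at 2·Δt and silence at
    3·Δt.  Only whole events with onset strictly inside the stimulus
    duration are emitted; partial trailing cycles are truncated at whole
    events.
    """
    total_ms = spec.duration * 1000.0
    f_a = spec.base_frequency
    f_b = semitones_above(spec.base_frequency, spec.delta_f)
    events: list[Event] = []
    cycle = 4.0 * spec.delta_t
    n_cycles = int(math.ceil(total_ms / cycle)) if total_ms > 0 else 0
    for c in range(n_cycles):
        t0 = c * cycle
        for offset, freq in ((0.0, f_a), (spec.delta_t, f_b), (2.0 * spec.delta_t, f_a)):
            t = t0 + offset
            if t < total_ms:
                events.append(Event(t, freq, spec.tone_duration))
    return EventSequence(events, total_ms)
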