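"""Stimulus timelines for vernier feature-fusion trials.

A trial presents a first vernier stimulus 'A' (evidence sign +1), an optional
blank inter-stimulus interval (ISI, sign 0) and a second vernier 'B' with the
opposite offset direction (sign -1).  The whole timeline is represented as an
ordered list of piecewise-constant signed segments; the input signal u(t) is
the polarity of the segment containing t and 0 outside the schedule.

Time is continuous, in milliseconds.  Segment intervals are half-open
[start, end) so the signal is single-valued at transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusSegment",
    "StimulusSchedule",
    "make_fusion_schedule",
    "signal_value",
    "signal_values",
    "offset_time",
]

_ALLOWED_POLARITIES = (-1, 0, 1)


@dataclass(frozen=True)
class StimulusSegment:
    """One piecewise-constant piece of the input signal.

    Parameters
    ----------
    polarity : int
        +1 during stimulus 'A', -1 during stimulus 'B', 0 for a blank.
    duration : float
        Length of the segment in milliseconds, finite and non-negative.
    """

    polarity: int
    duration: float

    def __post_init__(self) -> None:
        if self.polarity not in _ALLOWED_POLARITIES:
            raise ValueError(f"polarity must be one of {_ALLOWED_POLARITIES}, got {self.polarity!r}")
        if not math.isfinite(self.duration) or self.duration < 0:
            raise ValueError(f"duration must be finite and >= 0, got {self.duration!r}")


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered stimulus segments starting at t = 0."""

    segments: tuple[StimulusSegment, ...]
    condition_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def total_duration(self) -> float:
        return float(sum(seg.duration for seg in self.segments))

    def boundaries(self) -> np.ndarray:
        """Cumulative segment edge times [0, t1, ..., total]."""
        return np.concatenate([[0.0], np.cumsum([seg.duration for seg in self.segments])])

    def polarities(self) -> np.ndarray:
        return np.array([seg.polarity for seg in self.segments], dtype=float)


def make_fusion_schedule(
    d_a: float, d_b: float, isi: float = 0.0, condition_label: str | None = None
) -> StimulusSchedule:
    """Build the A -> (blank) -> B timeline of a feature-fusion trial.

    Zero-duration pieces are dropped, so sweeps that include a vanishing
    first or second vernier need no special-casing.
    """
    for name, dur in (("d_a", d_a), ("d_b", d_b), ("isi", isi)):
        if not math.isfinite(dur) or dur < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {dur!r}")
    if d_a == 0 and d_b == 0 and isi == 0:
        raise ValueError("schedule must have nonzero total duration")
    if condition_label is None:
        condition_label = f"A{d_a:g}_I{isi:g}_B{d_b:g}"
    pieces = [(+1, d_a), (0, isi), (-1, d_b)]
    segments = tuple(StimulusSegment(pol, dur) for pol, dur in pieces if dur > 0)
    return StimulusSchedule(segments=segments, condition_label=condition_label)


def signal_value(s: StimulusSchedule, t: float) -> int:
    """Input signal u(t): polarity of the segment containing t, 0 outside."""
    if t < 0:
        return 0
    start = 0.0
    for seg in s.segments:
        end = start + seg.duration
        if start <= t < end:
            return seg.polarity
        start = end
    return 0


def signal_values(s: StimulusSchedule, ts: np.ndarray) -> np.ndarray:
    """Vectorised ``signal_value`` over an array of times."""
    ts = np.asarray(ts, dtype=float)
    edges = s.boundaries()
    pols = s.polarities()
    idx = np.searchsorted(edges, ts, side="right") - 1
    out = np.zeros_like(ts)
    inside = (idx >= 0) & (idx < len(pols)) & (ts < edges[-1]) & (ts >= 0)
    out[inside] = pols[idx[inside]]
    return out


def offset_time(s: StimulusSchedule) -> float:
    """End time of the last nonzero-polarity segment (stimulus termination)."""
    if not s.segments:
        raise ValueError("empty schedule has no stimulus offset")
    edges = s.boundaries()
    last = None
    for i, seg in enumerate(s.segments):
        if seg.polarity != 0:
            last = i
    if last is None:
        raise ValueError("all-blank schedule has no stimulus offset")
    return float(edges[last + 1])
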