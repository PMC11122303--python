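"""Sleep calling from activity traces by the immobility criterion.

Fly sleep is scored operationally: any run of at least ``threshold_min``
(default 5) consecutive minutes with zero beam breaks is one sleep bout, and
every minute inside it is a SLEEP minute.  Shorter zero-runs and all minutes
with activity are WAKE.  Minutes with no valid reading are MISSING and break
zero-runs: only the observed portion of a run is scored, so missing data can
never fabricate sleep.  Runs truncated by the start or end of the recording
count as sleep if the observed portion reaches the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from enum import IntEnum

import numpy as np

from .io_dam import MinuteTrace


class SleepState(IntEnum):
    WAKE = 0
    SLEEP = 1
    MISSING = 2


@dataclass
class SleepTrace:
    """Per-minute sleep states and the list of (start_minute, duration) bouts."""

    fly_id: str
    states: np.ndarray
    bouts: list[tuple[int, int]]
    threshold_min: int = 5
    start_time: datetime = datetime(2024, 1, 1, 7, 0)
    strain: str = ""
    age_days: int = 0
    condition: dict = field(default_factory=dict)

    @property
    def n_minutes(self) -> int:
        return int(self.states.size)

    @property
    def total_sleep_min(self) -> int:
        return int(np.count_nonzero(self.states == SleepState.SLEEP))


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, length) pairs."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.concatenate(([0], starts))
    if m[-1]:
        ends = np.concatenate((ends, [m.size]))
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def call_sleep(trace: MinuteTrace, threshold_min: int = 5) -> SleepTrace:
    """Score per-minute sleep states on a trace.

    Deterministic and idempotent: re-calling on the same trace yields an
    identical result.
    """
    if threshold_min < 1:
        raise ValueError("threshold_min must be >= 1")
    counts = np.asarray(trace.counts)
    if not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("counts must be integers")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    missing = trace.missing

    states = np.full(counts.size, SleepState.WAKE, dtype=np.int8)
    states[missing] = SleepState.MISSING
    bouts = []
    for start, length in _true_runs((counts == 0) & ~missing):
        if length >= threshold_min:
            states[start:start + length] = SleepState.SLEEP
            bouts.append((start, length))
    return SleepTrace(fly_id=trace.fly_id, states=states, bouts=bouts,
                      threshold_min=threshold_min, start_time=trace.start_time,
                      strain=trace.strain, age_days=trace.age_days,
                      condition=dict(trace.condition))


@dataclass(frozen=True)
class SleepSummary:
    total_sleep_min: int
    n_bouts: int
    mean_bout_min: float  # NaN when there are no bouts
    observed_min: int     # denominator: window minutes with a valid reading
    window: tuple[int, int]


def sleep_summary(sleep: SleepTrace, window: tuple[int, int] | None = None) -> SleepSummary:
    """Summarize sleep over a half-open minute window [start, stop).

    Bouts are clipped to the window; a bout counts if it overlaps the window
    at all, and the mean bout length is over clipped durations.  MISSING
    minutes are excluded from the reported observed denominator.
    """
    n = sleep.n_minutes
    start, stop = (0, n) if window is None else window
    if not (0 <= start < stop <= n):
        raise ValueError(f"window [{start}, {stop}) is empty or outside the trace")
    seg = sleep.states[start:stop]
    total = int(np.count_nonzero(seg == SleepState.SLEEP))
    clipped = [min(stop, b + d) - max(start, b) for b, d in sleep.bouts]
    clipped = [c for c in clipped if c > 0]
    observed = int(np.count_nonzero(seg != SleepState.MISSING))
    mean = float(np.mean(clipped)) if clipped else math.nan
    return SleepSummary(total_sleep_min=total, n_bouts=len(clipped),
                        mean_bout_min=mean, observed_min=observed,
                        window=(start, stop))


def filter_dead(traces: list[MinuteTrace], terminal_window_h: float = 24.0,
                ) -> tuple[list[MinuteTrace], list[tuple[MinuteTrace, int | None]]]:
    """Split a cohort into live flies and presumed-dead flies.

    A fly whose final ``terminal_window_h`` hours contain no observed activity
    through the end of the recording is excluded (it most likely died during
    recording and its terminal immobility would otherwise be scored as a huge
    sleep bout).  Excluded flies are returned with the minute index of their
    last observed movement (None if they never moved).
    """
    window = int(round(terminal_window_h * 60))
    kept, excluded = [], []
    for trace in traces:
        if trace.n_minutes < window:
            raise ValueError(
                f"fly {trace.fly_id}: trace shorter than the {terminal_window_h} h window")
        observed_activity = (trace.counts > 0) & ~trace.missing
        if observed_activity[-window:].any():
            kept.append(trace)
        else:
            moves = np.flatnonzero(observed_activity)
            excluded.append((trace, int(moves[-1]) if moves.size else None))
    return kept, excluded
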