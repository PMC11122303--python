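"""Reading and writing per-minute multi-channel activity-monitor files.

The Drosophila Activity Monitoring System (DAM) records, for each of up to
32 flies housed in individual tubes, the number of infrared-beam breaks per
minute.  This module implements a simplified, fully documented dialect of
that tab-separated format and joins monitor channels with per-fly cohort
metadata.

Dialect (one row per minute, tab-separated, 42 columns)::

    index  date  time  status  r1..r6  c1..c32

where ``index`` is a 1-based row counter, ``date`` is ``DD Mon YY``,
``time`` is ``HH:MM:SS``, ``status`` is an integer reading-status code
(1 = valid; anything else marks the minute as missing), ``r1..r6`` are
reserved columns written as 0, and ``c1..c32`` are the non-negative integer
beam-break counts of channels 1-32.

Missing minutes (bad status rows, or gaps in the timestamp sequence) are
marked explicitly on the resulting traces and are never silently zero-filled:
downstream sleep calling treats them as "unknown", because a fabricated zero
would fabricate sleep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_CHANNELS = 32
N_RESERVED = 6
N_COLUMNS = 4 + N_RESERVED + N_CHANNELS
STATUS_OK = 1
DATE_FORMAT = "%d %b %y"
TIME_FORMAT = "%H:%M:%S"


class ParseError(ValueError):
    """A monitor file row could not be parsed."""


class IntegrityError(ValueError):
    """Monitor file timestamps are out of order or duplicated."""


@dataclass
class MinuteTrace:
    """One fly's per-minute beam-break counts plus cohort metadata.

    ``counts`` holds one non-negative integer per minute; ``missing`` is a
    parallel boolean mask marking minutes with no valid reading.  Counts at
    missing minutes carry no information (they are stored as read/written but
    must not be interpreted).
    """

    fly_id: str
    counts: np.ndarray
    missing: np.ndarray | None = None
    start_time: datetime = datetime(2024, 1, 1, 7, 0)
    strain: str = ""
    age_days: int = 0
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D sequence")
        if np.any(self.counts < 0):
            raise ValueError(f"fly {self.fly_id}: negative counts")
        if self.missing is None:
            self.missing = np.zeros(self.counts.size, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.counts.shape:
                raise ValueError("missing mask must match counts length")

    @property
    def n_minutes(self) -> int:
        return int(self.counts.size)

    @property
    def n_days(self) -> float:
        return self.counts.size / 1440.0


def write_monitor(traces: list[MinuteTrace], path: str | Path) -> Path:
    """Write traces to one monitor file, one channel per trace (max 32).

    All traces must share start time, length and missing-minute pattern
    (a monitor fails per row, so co-housed channels share missingness).
    Unused channels are zero-filled.  Inverse of :func:`read_monitor` on its
    own output.
    """
    if not traces:
        raise ValueError("cannot write an empty trace list")
    if len(traces) > N_CHANNELS:
        raise ValueError(f"at most {N_CHANNELS} traces per monitor file, got {len(traces)}")
    t0, n = traces[0].start_time, traces[0].n_minutes
    for tr in traces[1:]:
        if tr.start_time != t0 or tr.n_minutes != n:
            raise ValueError("all traces in a monitor file must share start time and length")
        if not np.array_equal(tr.missing, traces[0].missing):
            raise ValueError("all traces in a monitor file must share the missing-minute pattern")

    counts = np.zeros((n, N_CHANNELS), dtype=np.int64)
    for ch, tr in enumerate(traces):
        counts[:, ch] = tr.counts
    status = np.where(traces[0].missing, 0, STATUS_OK)

    path = Path(path)
    with path.open("w") as fh:
        for i in range(n):
            ts = t0 + timedelta(minutes=i)
            row = [str(i + 1), ts.strftime(DATE_FORMAT), ts.strftime(TIME_FORMAT),
                   str(int(status[i]))] + ["0"] * N_RESERVED + [str(c) for c in counts[i]]
            fh.write("\t".join(row) + "\n")
    return path


def read_monitor(path: str | Path, channel_map: dict[int, dict]) -> list[MinuteTrace]:
    """Read a monitor file, returning one :class:`MinuteTrace` per mapped channel.

    ``channel_map`` maps 1-based channel numbers to metadata dicts with at
    least ``fly_id`` (optionally ``strain``, ``age_days``, ``condition``).
    Rows with a non-OK status become missing minutes; gaps in the 1-minute
    timestamp sequence are filled with missing minutes and logged.  Unmapped
    channels containing activity are ignored with a logged warning.
    """
    path = Path(path)
    for ch in channel_map:
        if not 1 <= ch <= N_CHANNELS:
            raise ValueError(f"channel {ch} outside 1..{N_CHANNELS}")

    rows: list[np.ndarray] = []
    missing: list[bool] = []
    prev_ts: datetime | None = None
    start_ts: datetime | None = None
    n_gap = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != N_COLUMNS:
                raise ParseError(
                    f"{path}: line {lineno}: expected {N_COLUMNS} columns, got {len(parts)}")
            try:
                status = int(parts[3])
                channel_counts = np.array([int(v) for v in parts[4 + N_RESERVED:]],
                                          dtype=np.int64)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer field ({exc})") from None
            try:
                ts = datetime.strptime(f"{parts[1]} {parts[2]}",
                                       f"{DATE_FORMAT} {TIME_FORMAT}")
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad timestamp ({exc})") from None
            if prev_ts is not None:
                delta = (ts - prev_ts).total_seconds() / 60.0
                if delta <= 0:
                    raise IntegrityError(
                        f"{path}: line {lineno}: timestamp {ts} not after {prev_ts}")
                gap = int(round(delta)) - 1
                if gap > 0:
                    n_gap += gap
                    for _ in range(gap):
                        rows.append(np.zeros(N_CHANNELS, dtype=np.int64))
                        missing.append(True)
            else:
                start_ts = ts
            rows.append(channel_counts)
            missing.append(status != STATUS_OK)
            prev_ts = ts
    if not rows:
        raise ParseError(f"{path}: no data rows")
    if n_gap:
        logger.warning("%s: %d missing minute(s) inserted for timestamp gaps", path, n_gap)

    matrix = np.vstack(rows)
    missing_arr = np.array(missing, dtype=bool)

    unmapped_active = [ch for ch in range(1, N_CHANNELS + 1)
                       if ch not in channel_map and matrix[:, ch - 1].any()]
    if unmapped_active:
        logger.warning("%s: ignoring unmapped active channel(s) %s", path, unmapped_active)

    traces = []
    for ch, meta in sorted(channel_map.items()):
        traces.append(MinuteTrace(
            fly_id=meta["fly_id"],
            counts=matrix[:, ch - 1],
            missing=missing_arr.copy(),
            start_time=start_ts,
            strain=meta.get("strain", ""),
            age_days=int(meta.get("age_days", 0)),
            condition=dict(meta.get("condition", {})),
        ))
    return traces


# -- cohort-level helpers: monitor files + a metadata table --------------------

_META_COLUMNS = ["fly_id", "file", "channel", "strain", "age_days",
                 "temperature", "food", "dose", "regime"]


def write_cohort(traces: list[MinuteTrace], outdir: str | Path,
                 prefix: str = "Monitor") -> Path:
    """Write a cohort as monitor files (32 channels each) plus metadata.csv."""
    if not traces:
        raise ValueError("cannot write an empty cohort")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for k in range(0, len(traces), N_CHANNELS):
        chunk = traces[k:k + N_CHANNELS]
        fname = f"{prefix}{k // N_CHANNELS + 1}.txt"
        write_monitor(chunk, outdir / fname)
        for ch, tr in enumerate(chunk, start=1):
            cond = tr.condition
            records.append({
                "fly_id": tr.fly_id, "file": fname, "channel": ch,
                "strain": tr.strain, "age_days": tr.age_days,
                "temperature": cond.get("temperature", ""),
                "food": cond.get("food", ""), "dose": cond.get("dose", ""),
                "regime": cond.get("regime", ""),
            })
    meta_path = outdir / "metadata.csv"
    pd.DataFrame.from_records(records, columns=_META_COLUMNS).to_csv(meta_path, index=False)
    return meta_path


def read_cohort(indir: str | Path) -> list[MinuteTrace]:
    """Read a cohort written by :func:`write_cohort` (monitor files + metadata.csv)."""
    indir = Path(indir)
    meta = pd.read_csv(indir / "metadata.csv", keep_default_na=False)
    traces: dict[str, MinuteTrace] = {}
    for fname, sub in meta.groupby("file", sort=False):
        channel_map = {}
        for _, row in sub.iterrows():
            channel_map[int(row["channel"])] = {
                "fly_id": row["fly_id"],
                "strain": row["strain"],
                "age_days": int(row["age_days"]) if str(row["age_days"]) != "" else 0,
                "condition": {k: row[k] for k in ("temperature", "food", "dose", "regime")
                              if str(row[k]) != ""},
            }
        for tr in read_monitor(indir / fname, channel_map):
            traces[tr.fly_id] = tr
    return [traces[fid] for fid in meta["fly_id"]]
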