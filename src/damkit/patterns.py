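"""24 h profiles: 30-min binning, per-fly daily averages, group summaries.

Per-minute activity and sleep are reduced to 48-value 24 h profiles (one
value per 30-min clock bin).  Activity bins are mean counts/min over the
observed minutes of the bin, so partially observed bins remain comparable;
sleep bins are sleep minutes rescaled to a 30-observed-minute basis, hence
always in [0, 30].  A bin with more than 50% missing minutes is itself
marked missing (NaN).

Bin 0 is anchored at lights-on (7:00, Zeitgeber time 0) by default, so bins
0-23 cover the photophase under the standard 12:12 LD schedule.  Profiles
average full recording days per clock bin; the first recording day is
discarded by default as acclimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_dam import MinuteTrace
from .sleep import SleepState, SleepTrace, call_sleep

ACTIVITY = "activity"
SLEEP = "sleep"
N_BINS = 48
BIN_MIN = 30
MINUTES_PER_DAY = 1440
DEFAULT_ANCHOR_MIN = 7 * 60  # lights-on


@dataclass
class Profile48:
    """A 48-value 24 h profile for one fly (NaN marks missing bins).

    Bin k covers clock minutes [anchor + 30k, anchor + 30(k+1)), modulo 24 h.
    """

    fly_id: str
    kind: str
    values: np.ndarray
    bin_anchor_min: int = DEFAULT_ANCHOR_MIN
    n_days_averaged: int = 1
    strain: str = ""
    age_days: int = 0
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in (ACTIVITY, SLEEP):
            raise ValueError(f"kind must be {ACTIVITY!r} or {SLEEP!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_BINS,):
            raise ValueError(f"a profile has exactly {N_BINS} values")
        ok = self.values[~np.isnan(self.values)]
        if np.any(ok < 0):
            raise ValueError("profile values must be >= 0")
        if self.kind == SLEEP and np.any(ok > BIN_MIN):
            raise ValueError(f"sleep bins must be <= {BIN_MIN} minutes")


def bin_30min(values: np.ndarray, missing: np.ndarray | None = None,
              kind: str = ACTIVITY) -> tuple[np.ndarray, np.ndarray]:
    """Reduce a per-minute series to 30-min bins.

    For ``kind="activity"`` ``values`` are counts and each bin is the mean
    over observed minutes; for ``kind="sleep"`` ``values`` are
    :class:`SleepState` codes and each bin is the SLEEP-minute count rescaled
    to 30 observed minutes.  Returns (bin values, bin-missing mask); bins with
    more than half of their minutes missing are NaN.
    """
    values = np.asarray(values)
    if values.size % BIN_MIN != 0:
        raise ValueError(f"series length {values.size} is not a multiple of {BIN_MIN}")
    if missing is None:
        missing = (values == SleepState.MISSING) if kind == SLEEP \
            else np.zeros(values.size, dtype=bool)
    miss = np.asarray(missing, dtype=bool).reshape(-1, BIN_MIN)
    vals = values.reshape(-1, BIN_MIN)
    n_obs = BIN_MIN - miss.sum(axis=1)
    bin_missing = miss.sum(axis=1) > BIN_MIN // 2
    safe_n = np.maximum(n_obs, 1)
    if kind == ACTIVITY:
        sums = np.where(miss, 0, vals).sum(axis=1)
        bins = sums / safe_n
    elif kind == SLEEP:
        n_sleep = ((vals == SleepState.SLEEP) & ~miss).sum(axis=1)
        bins = n_sleep * BIN_MIN / safe_n
    else:
        raise ValueError(f"unknown kind {kind!r}")
    bins = bins.astype(float)
    bins[bin_missing | (n_obs == 0)] = np.nan
    return bins, bin_missing | (n_obs == 0)


def _series_of(obj: MinuteTrace | SleepTrace) -> tuple[np.ndarray, np.ndarray, str]:
    if isinstance(obj, MinuteTrace):
        return obj.counts, obj.missing, ACTIVITY
    if isinstance(obj, SleepTrace):
        return obj.states, obj.states == SleepState.MISSING, SLEEP
    raise TypeError(f"expected MinuteTrace or SleepTrace, got {type(obj).__name__}")


def daily_profile(obj: MinuteTrace | SleepTrace, *, drop_first_day: bool = True,
                  exclude_days: Iterable[int] = (),
                  bin_anchor_min: int = DEFAULT_ANCHOR_MIN) -> Profile48:
    """Across-days mean 24 h profile of one fly, aligned to the bin anchor.

    Leading minutes before the first anchor crossing and any trailing partial
    day are trimmed; the first full day is dropped as acclimation unless
    ``drop_first_day=False``; day indices in ``exclude_days`` (0-based, after
    trimming) are also omitted.  Raises if no usable day remains.
    """
    series, missing, kind = _series_of(obj)
    start_mod = obj.start_time.hour * 60 + obj.start_time.minute
    lead = (bin_anchor_min - start_mod) % MINUTES_PER_DAY
    series, missing = series[lead:], missing[lead:]
    n_days = series.size // MINUTES_PER_DAY
    skip = set(exclude_days) | ({0} if drop_first_day and n_days > 1 else set())
    used = [d for d in range(n_days) if d not in skip]
    if not used:
        raise ValueError(f"fly {obj.fly_id}: no usable recording day")
    day_bins = []
    for d in used:
        sl = slice(d * MINUTES_PER_DAY, (d + 1) * MINUTES_PER_DAY)
        bins, _ = bin_30min(series[sl], missing[sl], kind=kind)
        day_bins.append(bins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins stay NaN
        values = np.nanmean(np.vstack(day_bins), axis=0)
    return Profile48(fly_id=obj.fly_id, kind=kind, values=values,
                     bin_anchor_min=bin_anchor_min, n_days_averaged=len(used),
                     strain=obj.strain, age_days=obj.age_days,
                     condition=dict(obj.condition))


@dataclass
class GroupProfile:
    """Per-bin mean, standard error and n over a group of flies."""

    kind: str
    mean: np.ndarray
    sem: np.ndarray  # NaN where n < 2
    n: np.ndarray
    n_flies: int
    bin_anchor_min: int = DEFAULT_ANCHOR_MIN


def group_profile(profiles: Sequence[Profile48]) -> GroupProfile:
    """Average profiles across flies; missing bins are excluded per bin."""
    if not profiles:
        raise ValueError("no profiles to average")
    kinds = {p.kind for p in profiles}
    if len(kinds) > 1:
        raise ValueError(f"cannot mix profile kinds {sorted(kinds)}")
    anchors = {p.bin_anchor_min for p in profiles}
    if len(anchors) > 1:
        raise ValueError("profiles have different bin anchors")
    stack = np.vstack([p.values for p in profiles])
    n = np.sum(~np.isnan(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    sem = np.where(n >= 2, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return GroupProfile(kind=profiles[0].kind, mean=mean, sem=sem, n=n,
                        n_flies=len(profiles), bin_anchor_min=profiles[0].bin_anchor_min)


def daily_means(traces: Sequence[MinuteTrace],
                sleeps: Sequence[SleepTrace] | None = None, *,
                threshold_min: int = 5, drop_first_day: bool = True,
                bin_anchor_min: int = DEFAULT_ANCHOR_MIN) -> pd.DataFrame:
    """Per-fly daily activity (counts/min) and sleep (min/24 h) with group labels.

    One row per fly; condition fields are expanded into columns.  This table
    is the input handed to generic statistical routines.  Sleep is rescaled
    to a full 24 h basis when some bins are missing.
    """
    if not traces:
        raise ValueError("no traces")
    if sleeps is None:
        sleeps = [call_sleep(tr, threshold_min) for tr in traces]
    rows = []
    for tr, sl in zip(traces, sleeps):
        act = daily_profile(tr, drop_first_day=drop_first_day,
                            bin_anchor_min=bin_anchor_min)
        slp = daily_profile(sl, drop_first_day=drop_first_day,
                            bin_anchor_min=bin_anchor_min)
        ok = ~np.isnan(slp.values)
        sleep_min = float(np.sum(slp.values[ok]) * N_BINS / ok.sum()) if ok.any() else np.nan
        rows.append({"fly_id": tr.fly_id, "strain": tr.strain,
                     "age_days": tr.age_days, **tr.condition,
                     "activity_per_min": float(np.nanmean(act.values)),
                     "sleep_min_per_day": sleep_min,
                     "n_days": act.n_days_averaged})
    return pd.DataFrame(rows)


# -- flat-table round trip for CSV interchange ---------------------------------

_VALUE_COLS = [f"b{k:02d}" for k in range(N_BINS)]


def profiles_to_frame(profiles: Sequence[Profile48]) -> pd.DataFrame:
    """Flatten profiles to a table: id, group fields, 48 value columns."""
    rows = []
    for p in profiles:
        row = {"fly_id": p.fly_id, "kind": p.kind, "strain": p.strain,
               "age_days": p.age_days, "n_days": p.n_days_averaged,
               "bin_anchor_min": p.bin_anchor_min, **p.condition}
        row.update(dict(zip(_VALUE_COLS, p.values)))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame) -> list[Profile48]:
    """Inverse of :func:`profiles_to_frame`."""
    meta_extra = [c for c in df.columns
                  if c not in _VALUE_COLS
                  and c not in ("fly_id", "kind", "strain", "age_days",
                                "n_days", "bin_anchor_min")]
    out = []
    for _, row in df.iterrows():
        out.append(Profile48(
            fly_id=row["fly_id"], kind=row["kind"],
            values=row[_VALUE_COLS].to_numpy(dtype=float),
            bin_anchor_min=int(row.get("bin_anchor_min", DEFAULT_ANCHOR_MIN)),
            n_days_averaged=int(row.get("n_days", 1)),
            strain=row.get("strain", ""), age_days=int(row.get("age_days", 0)),
            condition={k: row[k] for k in meta_extra},
        ))
    return out
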