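"""Kaplan-Meier lifespan curves and log-rank (Mantel-Cox) comparison.

Survival cohorts are plain tables with columns ``fly_id``, ``group``,
``time`` (days) and ``event`` (1 = death observed, 0 = right-censored, e.g.
still alive at study end).  Estimation and testing are backed by lifelines;
this module fixes the conventions used throughout the pipeline: tied death
days share one pooled risk set, censored flies leave the risk set after
their censoring time, and the median is the smallest time with S(t) <= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .aging_score import holm_adjust


def _validate(cohort: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in cohort.columns:
            raise ValueError(f"cohort table lacks a {col!r} column")
    if (cohort["time"] < 0).any():
        raise ValueError("times must be non-negative")
    if "fly_id" in cohort.columns and cohort["fly_id"].duplicated().any():
        dup = cohort.loc[cohort["fly_id"].duplicated(), "fly_id"].iloc[0]
        raise ValueError(f"fly {dup!r} appears more than once")
    return cohort


@dataclass
class KMCurve:
    """Product-limit survival curve: one row per distinct death time."""

    times: np.ndarray      # sorted distinct event (death) times
    survival: np.ndarray   # S(t) just after each death time
    at_risk: np.ndarray    # risk-set size at each death time
    n_events: np.ndarray   # deaths at each death time
    n_total: int
    group: str | None = None

    def survival_at(self, t: float) -> float:
        """S(t); 1 before the first death."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    @property
    def median(self) -> float:
        """Smallest time with S(t) <= 0.5; NaN if the curve never reaches it."""
        below = np.flatnonzero(self.survival <= 0.5)
        return float(self.times[below[0]]) if below.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival,
                             "at_risk": self.at_risk, "n_events": self.n_events})


def km_estimate(cohort: pd.DataFrame, group: str | None = None) -> KMCurve:
    """Kaplan-Meier estimate, optionally restricted to one group label."""
    cohort = _validate(cohort)
    if group is not None:
        cohort = cohort[cohort["group"] == group]
        if cohort.empty:
            raise ValueError(f"group {group!r} is empty")
    if cohort.empty:
        raise ValueError("empty cohort")
    kmf = KaplanMeierFitter().fit(cohort["time"], cohort["event"])
    table = kmf.event_table
    deaths = table[table["observed"] > 0]
    times = deaths.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[times, kmf.survival_function_.columns[0]]
    return KMCurve(times=times, survival=surv.to_numpy(dtype=float),
                   at_risk=deaths["at_risk"].to_numpy(dtype=int),
                   n_events=deaths["observed"].to_numpy(dtype=int),
                   n_total=len(cohort), group=group)


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    groups: tuple[str, str]
    n: tuple[int, int]


def logrank_test(cohort: pd.DataFrame, group_col: str = "group") -> LogRankResult:
    """Log-rank (Mantel-Cox) test of equality of two survival distributions.

    The chi-square statistic (df = 1) sums observed-minus-expected deaths
    over pooled event times with hypergeometric expectations and variances.
    """
    cohort = _validate(cohort)
    labels = sorted(cohort[group_col].unique())
    if len(labels) != 2:
        raise ValueError(f"logrank_test needs exactly 2 groups, got {labels}")
    a = cohort[cohort[group_col] == labels[0]]
    b = cohort[cohort[group_col] == labels[1]]
    if a.empty or b.empty:
        raise ValueError("both groups must be non-empty")
    if cohort["event"].sum() == 0:
        raise ValueError("no events: the log-rank test is undefined")
    res = _ll_logrank(a["time"], b["time"],
                      event_observed_A=a["event"], event_observed_B=b["event"])
    return LogRankResult(statistic=float(res.test_statistic), df=1,
                         p_value=float(res.p_value),
                         groups=(str(labels[0]), str(labels[1])),
                         n=(len(a), len(b)))


def dose_response_summary(cohort: pd.DataFrame, dose_col: str = "dose",
                          control: str = "x0",
                          adjust: str | None = None) -> pd.DataFrame:
    """Median lifespan per dose group and pairwise log-rank tests vs control.

    ``adjust="holm"`` adds Holm-adjusted p-values over the family of
    control comparisons.
    """
    cohort = _validate(cohort)
    if dose_col not in cohort.columns:
        raise ValueError(f"cohort table lacks a {dose_col!r} column")
    doses = list(pd.unique(cohort[dose_col]))
    if len(doses) < 2:
        raise ValueError("need at least 2 dose groups")
    if control not in doses:
        raise ValueError(f"control dose {control!r} not present")

    rows = []
    for dose in doses:
        sub = cohort[cohort[dose_col] == dose]
        curve = km_estimate(sub)
        row = {"dose": dose, "n": len(sub), "n_deaths": int(sub["event"].sum()),
               "median": curve.median, "statistic": np.nan, "p_value": np.nan}
        if dose != control:
            pair = cohort[cohort[dose_col].isin([control, dose])]
            res = logrank_test(pair, group_col=dose_col)
            row["statistic"], row["p_value"] = res.statistic, res.p_value
        rows.append(row)
    out = pd.DataFrame(rows)
    if adjust == "holm":
        tested = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        adj[tested.to_numpy()] = holm_adjust(out.loc[tested, "p_value"])
        out["p_holm"] = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out
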