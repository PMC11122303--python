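"""Independent reference implementations used only for cross-checking.

Everything here is deliberately written from first principles (plain scans,
closed forms, permutation nulls) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def sleep_states_brute(counts, missing, threshold):
    """Minute-by-minute sleep scan: 0 = wake, 1 = sleep, 2 = missing."""
    n = len(counts)
    states = [0] * n
    run = []
    for i in range(n + 1):
        observed_zero = i < n and not missing[i] and counts[i] == 0
        if observed_zero:
            run.append(i)
        else:
            if len(run) >= threshold:
                for j in run:
                    states[j] = 1
            run = []
    for i in range(n):
        if missing[i]:
            states[i] = 2
    return states


def window_means_brute(values, missing, width=30):
    """Per-window mean of observed values; NaN when more than half missing."""
    out = []
    for k in range(0, len(values), width):
        v = values[k:k + width]
        m = missing[k:k + width]
        obs = [x for x, mm in zip(v, m) if not mm]
        n_missing = sum(m)
        out.append(float(np.mean(obs)) if n_missing <= width // 2 and obs else np.nan)
    return out


def chi2_2x2_closed_form(a, b, c, d):
    """n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) for the table [[a, b], [c, d]]."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


def km_survival_brute(times, events):
    """Product-limit S(t) at each distinct death time, by direct counting."""
    death_times = sorted({t for t, e in zip(times, events) if e})
    s = 1.0
    out = []
    for t in death_times:
        at_risk = sum(1 for ti in times if ti >= t)
        deaths = sum(1 for ti, e in zip(times, events) if e and ti == t)
        s *= 1.0 - deaths / at_risk
        out.append((t, at_risk, deaths, s))
    return out


def logrank_statistic(times, events, in_group1):
    """Mantel-Cox chi-square statistic from pooled event-time risk sets."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    g1 = np.asarray(in_group1, dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


def logrank_permutation_pvalue(times, events, in_group1, n_perm, rng):
    """Randomization p-value of the log-rank statistic under label shuffling.

    Vectorized over permutations: risk-set and death indicator matrices are
    fixed; only the group-membership vector is resampled.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    g1 = np.asarray(in_group1, dtype=float)
    event_times = np.unique(times[events])
    risk = times[None, :] >= event_times[:, None]             # (T, n)
    death = (times[None, :] == event_times[:, None]) & events  # (T, n)
    n_i = risk.sum(axis=1).astype(float)
    d_i = death.sum(axis=1).astype(float)

    def stat(labels):  # labels: (n, P)
        n1 = risk.astype(float) @ labels
        d1 = death.astype(float) @ labels
        frac = n1 / n_i[:, None]
        o_minus_e = (d1 - d_i[:, None] * frac).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = d_i[:, None] * frac * (1 - frac) * ((n_i - d_i) / np.maximum(n_i - 1, 1))[:, None]
        return o_minus_e ** 2 / v.sum(axis=0)

    observed = stat(g1[:, None])[0]
    perms = np.empty((times.size, n_perm))
    for k in range(n_perm):
        perms[:, k] = rng.permutation(g1)
    null = stat(perms)
    return (np.count_nonzero(null >= observed - 1e-12) + 1) / (n_perm + 1), observed
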