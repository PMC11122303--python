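"""Synthetic Drosophila activity-monitor cohorts.

Generates per-minute beam-break traces with realistic quiescent-bout
structure, and Gompertz-distributed lifespans, for configurable strain /
age / condition designs.  Two presets emulate classic wild-type laboratory
strains: a slow-aging, more active, shorter-sleeping strain (Canton-S-like)
and a fast-aging, less active, longer-sleeping, shorter-lived strain
(Harwich-like).

Activity model
--------------
Each fly is a two-state (active / quiescent) Markov chain on 1-minute steps.
While active, the minute's beam-break count is Poisson with a time-of-day
rate

    lambda(t) = mesor + morning bump + evening bump + daytime bump

where the bumps are Gaussian in clock time on the circular 24 h axis.
Quiescent minutes produce exactly zero counts; the quiescence-entry
probability is anti-phase to lambda(t) (circadian gating: siesta and night
sleep, consolidated wake at the activity peaks), and together with the mean
quiescent-bout length it sets the sleep amount seen by the 5-min immobility
rule.

Aging is a smooth morph of these parameters (:class:`AgeMorph`): the
background level (mesor) fades, sleep pressure rises, the peaks drift
slightly earlier, and amplitude is handed over from the morning and evening
peaks to an emerging single daytime peak — the bimodal evening-dominant young
rhythm turns into the unimodal daytime-shifted old rhythm.  Each fly also
carries individual random effects (overall level, sleep pressure, peak-time
jitter).  Environmental conditions (high temperature, caffeinated or
high-carbohydrate diet, constant darkness) enter as direction-of-effect
modifiers.

Lifespans follow a Gompertz law with hazard ``a * exp(b * t)``; deaths after
``max_day`` are right-censored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime
from typing import Sequence

import numpy as np
import pandas as pd

from .io_dam import MinuteTrace

MINUTES_PER_DAY = 1440
MIDDAY_HOUR = 14.0   # clock position of the emerging old-age daytime peak
DAYTIME_HANDOVER_GAIN = 1.0  # amplitude gain of the evening-to-daytime handover

# Direction-of-effect condition modifiers (multiplicative on activity rates,
# additive on sleep pressure, multiplicative on the Gompertz baseline hazard).
DOSE_ACTIVITY_EFFECT = {"x0": 1.0, "x1": 0.90, "x2.5": 0.80, "x10": 0.60}
DOSE_SLEEP_EFFECT = {"x0": 0.0, "x1": 0.001, "x2.5": 0.002, "x10": 0.004}
DOSE_HAZARD_EFFECT = {"x0": 1.0, "x1": 1.2, "x2.5": 1.4, "x10": 2.0}
FOOD_ACTIVITY_EFFECT = {"standard": 1.0, "carbohydrate": 0.80}
FOOD_SLEEP_EFFECT = {"standard": 0.0, "carbohydrate": 0.002}
TEMPERATURE_ACTIVITY_SLOPE = 0.02  # relative activity change per deg C from 25


class ParameterError(ValueError):
    """Invalid simulation parameter."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class StrainParams:
    """Generative parameters of one strain.

    Rates are counts/min, times clock hours, widths hours; ``sleep_pressure``
    is the per-minute probability of entering a quiescent bout whose mean
    length is ``mean_bout_min``.  ``gompertz_a``/``gompertz_b`` set the
    mortality hazard a*exp(b*t) per day; ``aging_rate`` scales how fast the
    age morph saturates (see :meth:`AgeMorph.for_age`).
    """

    name: str
    mesor: float = 1.0
    morning_peak_time: float = 8.0
    morning_peak_amp: float = 3.0
    evening_peak_time: float = 19.0
    evening_peak_amp: float = 4.0
    peak_width: float = 1.5
    sleep_pressure: float = 0.010
    mean_bout_min: float = 40.0
    gompertz_a: float = 0.002
    gompertz_b: float = 0.08
    aging_rate: float = 1.0
    # inter-fly variance within a group (not characterized by published data;
    # exposed as parameters): lognormal CV of the per-fly activity and
    # sleep-pressure multipliers, and SD (hours) of per-fly peak-time jitter.
    cv_activity: float = 0.30
    peak_jitter_h: float = 0.35
    cv_sleep: float = 0.25
    # circadian gating of quiescence: entry probability at clock time t is
    # sleep_pressure * (1 - coupling * lambda(t)/max lambda), so sleep is
    # anti-phase to the activity rhythm (daytime siesta, night sleep, wake
    # concentrated at the activity peaks); 0 = time-uniform quiescence.
    sleep_circadian_coupling: float = 0.75

    def __post_init__(self) -> None:
        _check(self.mesor >= 0, "mesor must be >= 0")
        _check(self.morning_peak_amp >= 0 and self.evening_peak_amp >= 0,
               "peak amplitudes must be >= 0")
        _check(0 <= self.morning_peak_time < 24 and 0 <= self.evening_peak_time < 24,
               "peak times must be clock hours in [0, 24)")
        _check(self.peak_width > 0, "peak_width must be > 0")
        _check(0 <= self.sleep_pressure <= 1, "sleep_pressure must be in [0, 1]")
        _check(self.mean_bout_min > 0, "mean_bout_min must be > 0")
        _check(self.gompertz_a > 0, "gompertz_a must be > 0")
        _check(self.gompertz_b >= 0, "gompertz_b must be >= 0")
        _check(self.aging_rate > 0, "aging_rate must be > 0")
        _check(self.cv_activity >= 0 and self.cv_sleep >= 0 and self.peak_jitter_h >= 0,
               "inter-fly variance parameters must be >= 0")
        _check(0 <= self.sleep_circadian_coupling <= 1,
               "sleep_circadian_coupling must be in [0, 1]")


# Strain presets: the slow-aging strain is more active, sleeps less and lives
# longer; the fast-aging strain is the opposite on every axis.
# The presets share one young-adult baseline; the strain contrasts the assay
# sees (lower activity, more sleep, earlier unimodal patterns in the fast
# ager at every tested age) emerge from the different aging rates alone.
CANTON_S = StrainParams(
    name="canton_s", mesor=1.15, morning_peak_amp=3.5, evening_peak_amp=4.5,
    morning_peak_time=8.0, evening_peak_time=19.0, peak_width=1.5,
    sleep_pressure=0.011, mean_bout_min=45.0,
    gompertz_a=0.002, gompertz_b=0.08, aging_rate=0.5,
    cv_activity=0.40,
)
HARWICH = StrainParams(
    name="harwich", mesor=1.0, morning_peak_amp=3.5, evening_peak_amp=4.5,
    morning_peak_time=8.0, evening_peak_time=19.0, peak_width=1.5,
    sleep_pressure=0.011, mean_bout_min=45.0,
    gompertz_a=0.004, gompertz_b=0.10, aging_rate=1.05,
    cv_activity=0.40,
)
PRESETS = {p.name: p for p in (CANTON_S, HARWICH)}


@dataclass(frozen=True)
class AgeMorph:
    """Age-dependent deformation of strain parameters.

    At ``age_days = 0`` the morph is the identity.  ``activity_scale``
    multiplies the background level and the morning/evening amplitudes;
    ``peak_shift_hours`` (negative = earlier) shifts the peaks;
    ``unimodality`` in [0, 1] hands amplitude over from the morning and
    evening peaks to the single daytime peak; ``sleep_gain`` adds to the
    quiescence-entry probability.
    """

    age_days: int = 0
    activity_scale: float = 1.0
    peak_shift_hours: float = 0.0
    unimodality: float = 0.0
    sleep_gain: float = 0.0

    # full-morph effect sizes and the age constants of the saturation curve
    _MAX_SCALE_LOSS = 0.5
    _MAX_SHIFT_H = -1.5
    _MAX_WIDEN = 0.3
    _MAX_SLEEP_GAIN = 0.012
    _REF_AGE_DAYS = 35.0
    _TAU_DAYS = 5.0

    def __post_init__(self) -> None:
        _check(self.age_days >= 0, "age_days must be >= 0")
        _check(0 < self.activity_scale <= 1, "activity_scale must be in (0, 1]")
        _check(0 <= self.unimodality <= 1, "unimodality must be in [0, 1]")
        _check(self.sleep_gain >= 0, "sleep_gain must be >= 0")
        if self.age_days == 0:
            _check(self.activity_scale == 1.0 and self.peak_shift_hours == 0.0
                   and self.unimodality == 0.0 and self.sleep_gain == 0.0,
                   "the age-0 morph must be the identity")

    @classmethod
    def for_age(cls, age_days: int, aging_rate: float = 1.0) -> "AgeMorph":
        """Morph at a given age.

        All effects follow a common log-age progression
        ``x = min(1, rate * ln(1 + age/tau) / ln(1 + ref/tau))`` — changes are
        fastest early in life and decelerate with age; ``aging_rate`` is the
        fraction of the full morph reached at the reference age (35 days).
        """
        _check(age_days >= 0, "age_days must be >= 0")
        x = min(1.0, aging_rate * math.log1p(age_days / cls._TAU_DAYS)
                / math.log1p(cls._REF_AGE_DAYS / cls._TAU_DAYS))
        return cls(
            age_days=age_days,
            activity_scale=1.0 - cls._MAX_SCALE_LOSS * x,
            peak_shift_hours=cls._MAX_SHIFT_H * x,
            unimodality=x,
            sleep_gain=cls._MAX_SLEEP_GAIN * x,
        )


@dataclass(frozen=True)
class SimConfig:
    """Recording design: days, light regime, condition, master seed."""

    n_days: int = 5
    light_regime: str = "LD"  # "LD" (12:12 light-dark) or "DD" (constant dark)
    lights_on: float = 7.0
    lights_off: float = 19.0
    seed: int = 0
    temperature_c: float = 25.0
    food: str = "standard"
    caffeine_dose: str = "x0"
    dd_morning_damping: float = 0.4  # morning-peak damping without light masking
    start_date: datetime = datetime(2024, 1, 1)

    def __post_init__(self) -> None:
        _check(self.n_days >= 1, "n_days must be >= 1")
        _check(self.light_regime in ("LD", "DD"), "light_regime must be LD or DD")
        _check(0 <= self.lights_on < 24 and 0 <= self.lights_off < 24,
               "lights_on/lights_off must be clock hours in [0, 24)")
        if self.light_regime == "LD":
            _check(self.lights_on < self.lights_off,
                   "LD regime requires lights_on before lights_off")
        _check(self.caffeine_dose in DOSE_ACTIVITY_EFFECT,
               f"unknown caffeine dose {self.caffeine_dose!r}")
        _check(self.food in FOOD_ACTIVITY_EFFECT, f"unknown food {self.food!r}")

    @property
    def start_time(self) -> datetime:
        """Recording starts at lights-on (Zeitgeber time 0)."""
        m = int(round(self.lights_on * 60))
        return self.start_date.replace(hour=m // 60, minute=m % 60,
                                       second=0, microsecond=0)

    @property
    def condition(self) -> dict:
        return {"temperature": self.temperature_c, "food": self.food,
                "dose": self.caffeine_dose, "regime": self.light_regime}


def _effective(params: StrainParams, morph: AgeMorph, config: SimConfig, *,
               fly_activity_mult: float = 1.0, fly_sleep_mult: float = 1.0,
               fly_jitter_h: float = 0.0) -> dict:
    """Strain parameters after the age morph, condition and fly-level effects.

    With the default fly-level arguments this is the group-expected
    parameterization (the fly-level lognormal multipliers have mean 1).
    """
    act_mult = (DOSE_ACTIVITY_EFFECT[config.caffeine_dose]
                * FOOD_ACTIVITY_EFFECT[config.food]
                * (1.0 + TEMPERATURE_ACTIVITY_SLOPE * (config.temperature_c - 25.0)))
    act_mult = max(act_mult, 0.0) * fly_activity_mult
    scale = morph.activity_scale * act_mult
    u = morph.unimodality
    m_amp = params.morning_peak_amp * scale * (1.0 - u)
    if config.light_regime == "DD":
        m_amp *= config.dd_morning_damping
    # aging hands amplitude over from the evening peak to a daytime peak at a
    # fixed clock position: the evening peak fades with the morning one while
    # the emerging daytime peak (exempt from the background scale loss) grows
    # with the unimodality weight, so the pattern transitions from a bimodal
    # evening-dominant rhythm to a unimodal daytime-shifted one
    e_amp = params.evening_peak_amp * scale * (1.0 - u)
    d_amp = params.evening_peak_amp * act_mult * DAYTIME_HANDOVER_GAIN * u
    shift = morph.peak_shift_hours + fly_jitter_h
    m_time = (params.morning_peak_time + shift) % 24.0
    e_time = (params.evening_peak_time + shift) % 24.0
    d_time = (MIDDAY_HOUR + fly_jitter_h) % 24.0
    p_enter = min(1.0, max(0.0,
                           fly_sleep_mult * (params.sleep_pressure + morph.sleep_gain)
                           + DOSE_SLEEP_EFFECT[config.caffeine_dose]
                           + FOOD_SLEEP_EFFECT[config.food]))
    return {
        "mesor": params.mesor * scale,
        "m_amp": m_amp, "m_time": m_time,
        "e_amp": e_amp, "e_time": e_time,
        "d_amp": d_amp, "d_time": d_time,
        "width": params.peak_width,
        "d_width": params.peak_width * (1.0 + AgeMorph._MAX_WIDEN * u),
        "p_enter": p_enter,
        "p_exit": 1.0 / params.mean_bout_min,
    }


def _bump(hours: np.ndarray, peak_time: float, amp: float, width: float) -> np.ndarray:
    d = (hours - peak_time + 12.0) % 24.0 - 12.0  # circular difference in hours
    return amp * np.exp(-0.5 * (d / width) ** 2)


def _lambda_from_eff(eff: dict) -> np.ndarray:
    hours = np.arange(MINUTES_PER_DAY) / 60.0
    return (eff["mesor"]
            + _bump(hours, eff["m_time"], eff["m_amp"], eff["width"])
            + _bump(hours, eff["e_time"], eff["e_amp"], eff["width"])
            + _bump(hours, eff["d_time"], eff["d_amp"], eff["d_width"]))


def lambda_profile(params: StrainParams, morph: AgeMorph, config: SimConfig) -> np.ndarray:
    """Group-expected active-state Poisson rate per minute of day (0 = midnight).

    Fly-level random effects average out of the mesor and amplitudes (their
    multipliers have mean 1); peak-time jitter additionally smears the peaks
    across flies, so group means match this curve exactly only where the
    bumps vanish or when ``peak_jitter_h`` is 0.
    """
    return _lambda_from_eff(_effective(params, morph, config))


def _entry_probability(lam: np.ndarray, p_enter: float, coupling: float) -> np.ndarray:
    """Per-minute quiescence-entry probability, gated by the activity rate."""
    if coupling > 0 and lam.max() > 0:
        return p_enter * (1.0 - coupling * lam / lam.max())
    return np.full(lam.size, p_enter)


def active_fraction(params: StrainParams, morph: AgeMorph, config: SimConfig) -> float:
    """Stationary active-state probability at the ungated entry rate.

    Exact for ``sleep_circadian_coupling = 0``; with gating the occupancy is
    time-dependent (see :func:`occupancy_profile`).
    """
    eff = _effective(params, morph, config)
    tot = eff["p_enter"] + eff["p_exit"]
    return 1.0 if tot == 0 else eff["p_exit"] / tot


def occupancy_profile(params: StrainParams, morph: AgeMorph, config: SimConfig) -> np.ndarray:
    """Quasi-stationary active-state probability per minute of day.

    phi(t) = p_exit / (p_exit + p_enter(t)); exact when the entry probability
    is constant over the day, an adiabatic approximation otherwise (the chain
    relaxes over ~mean_bout_min, faster than the rate varies).
    """
    eff = _effective(params, morph, config)
    p_ent = _entry_probability(_lambda_from_eff(eff), eff["p_enter"],
                               params.sleep_circadian_coupling)
    return eff["p_exit"] / (eff["p_exit"] + p_ent)


def simulate_trace(params: StrainParams, morph: AgeMorph, config: SimConfig,
                   fly_id: str, seed=None) -> MinuteTrace:
    """Simulate one fly's per-minute counts for ``config.n_days`` days.

    A two-state (active/quiescent) Markov chain runs on 1-minute steps with a
    constant quiescence-exit probability and a clock-gated entry probability;
    active minutes draw Poisson counts from the time-of-day rate, quiescent
    minutes are exactly 0.  Identical seeds give identical traces.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_days * MINUTES_PER_DAY
    # fly-level random effects (lognormal multipliers have mean 1)
    act_m = float(rng.lognormal(-params.cv_activity ** 2 / 2, params.cv_activity)) \
        if params.cv_activity > 0 else 1.0
    slp_m = float(rng.lognormal(-params.cv_sleep ** 2 / 2, params.cv_sleep)) \
        if params.cv_sleep > 0 else 1.0
    jit = float(rng.normal(0.0, params.peak_jitter_h)) if params.peak_jitter_h > 0 else 0.0
    eff = _effective(params, morph, config, fly_activity_mult=act_m,
                     fly_sleep_mult=slp_m, fly_jitter_h=jit)
    start_minute = int(round(config.lights_on * 60)) % MINUTES_PER_DAY
    lam = _lambda_from_eff(eff)[(start_minute + np.arange(n)) % MINUTES_PER_DAY]

    p_ent = _entry_probability(lam, eff["p_enter"], params.sleep_circadian_coupling)
    p_exit = eff["p_exit"]
    u = rng.random(n)
    active = np.empty(n, dtype=bool)
    state = bool(u[0] < (p_exit / (p_exit + p_ent[0]) if p_exit + p_ent[0] > 0 else 1.0))
    active[0] = state
    for t in range(1, n):
        state = (u[t] >= p_ent[t]) if state else (u[t] < p_exit)
        active[t] = state

    counts = np.zeros(n, dtype=np.int64)
    counts[active] = rng.poisson(lam[active])
    return MinuteTrace(fly_id=fly_id, counts=counts, start_time=config.start_time,
                       strain=params.name, age_days=morph.age_days,
                       condition=config.condition)


def simulate_cohort(groups: Sequence[tuple[StrainParams, AgeMorph, int]],
                    config: SimConfig) -> list[MinuteTrace]:
    """Simulate a multi-group cohort with per-fly seeds spawned from the master seed.

    ``groups`` is a sequence of (strain parameters, age morph, n flies).
    Fly ids are ``{strain}-a{age}-{index}``; duplicates are rejected.
    """
    groups = list(groups)
    if not groups:
        raise ParameterError("at least one group is required")
    for _, _, n in groups:
        _check(n >= 1, "each group needs n >= 1 flies")
    children = iter(np.random.SeedSequence(config.seed).spawn(
        sum(n for _, _, n in groups)))
    seen: set[str] = set()
    traces = []
    for params, morph, n in groups:
        for i in range(n):
            fly_id = f"{params.name}-a{morph.age_days:02d}-{i + 1:03d}"
            if fly_id in seen:
                raise ParameterError(f"duplicate fly id {fly_id!r}")
            seen.add(fly_id)
            traces.append(simulate_trace(params, morph, config, fly_id,
                                         seed=next(children)))
    return traces


def simulate_lifespans(params: StrainParams, n: int, max_day: int = 90, *,
                       seed=0, group: str | None = None, hazard_scale: float = 1.0,
                       round_to_days: bool = True) -> pd.DataFrame:
    """Draw ``n`` Gompertz lifespans; times past ``max_day`` are right-censored.

    The hazard is ``hazard_scale * gompertz_a * exp(gompertz_b * t)``
    (``hazard_scale`` carries condition effects such as caffeine dose).
    Returns a survival-cohort table with columns fly_id, group, time, event
    (1 = death observed, 0 = censored); times are whole days by default.
    """
    _check(n >= 1, "n must be >= 1")
    _check(max_day >= 0, "max_day must be >= 0")
    _check(hazard_scale > 0, "hazard_scale must be > 0")
    rng = np.random.default_rng(seed)
    a = params.gompertz_a * hazard_scale
    b = params.gompertz_b
    u = rng.random(n)
    if b == 0:
        t = -np.log1p(-u) / a
    else:
        t = np.log1p(-(b / a) * np.log1p(-u)) / b
    if round_to_days:
        t = np.maximum(np.ceil(t), 1.0)
    event = t <= max_day
    time = np.where(event, t, float(max_day))
    label = params.name if group is None else group
    return pd.DataFrame({
        "fly_id": [f"{label}-{i + 1:04d}" for i in range(n)],
        "group": label,
        "time": time,
        "event": event.astype(int),
    })
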