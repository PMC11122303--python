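"""PCA-based aging-phenotype scoring of 24 h activity/sleep profiles.

Per-fly 48-bin profiles are pooled and subjected to principal component
analysis (covariance of the n x 48 matrix).  The two leading components have
a reproducible behavioral reading once their arbitrary eigenvector signs are
fixed:

* **PC1** indexes the overall level: after orientation, a positive score
  means above-average activity (activity profiles) or below-average sleep
  (sleep profiles) — the "young-age" direction.
* **PC2** indexes the daily shape: a positive score means the unimodal,
  daytime-shifted pattern that replaces the young bimodal
  (morning + evening peak) rhythm with advancing age — the "old-age"
  direction.

Flies are classified by score sign (score <= 0 vs > 0), class rates are
tabulated per group (strain x age class), and rates of two groups are
compared with a Pearson chi-square test on the 2x2 counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .patterns import ACTIVITY, SLEEP, N_BINS, Profile48, DEFAULT_ANCHOR_MIN

LE0 = "LE0"  # score <= 0
GT0 = "GT0"  # score > 0


class DegenerateDataError(ValueError):
    """Profile ensemble has no variance to decompose."""


class OrientationError(ValueError):
    """The sign-fixing contrast is exactly zero; orientation is ambiguous."""


@dataclass
class PCAModel:
    """Mean profile, two orientation-fixed loading vectors, variance fractions."""

    kind: str
    mean_profile: np.ndarray
    loadings: np.ndarray           # shape (2, 48), rows orthonormal
    explained_fraction: np.ndarray  # shape (2,), PC1 >= PC2
    bin_anchor_min: int = DEFAULT_ANCHOR_MIN
    n_fitted: int = 0
    orientation: dict | None = None  # None until orient() fixes the signs


def fit_pca(profiles: Sequence[Profile48], *, impute_missing: bool = False) -> PCAModel:
    """Fit a two-component PCA to a single-kind profile ensemble.

    Centers on the mean profile and extracts the top two eigenvectors of the
    covariance matrix of the raw binned values (bins share units, so no
    correlation scaling).  Missing bins are an error unless
    ``impute_missing=True`` requests per-bin mean imputation.
    """
    if len(profiles) < 3:
        raise ValueError(f"PCA needs at least 3 profiles, got {len(profiles)}")
    kinds = {p.kind for p in profiles}
    if len(kinds) > 1:
        raise ValueError(f"cannot mix profile kinds {sorted(kinds)}")
    anchors = {p.bin_anchor_min for p in profiles}
    if len(anchors) > 1:
        raise ValueError("profiles have different bin anchors")
    X = np.vstack([p.values for p in profiles])
    nan_mask = np.isnan(X)
    if nan_mask.any():
        if not impute_missing:
            raise ValueError("profiles contain missing bins "
                             "(pass impute_missing=True to mean-impute)")
        col_mean = np.nanmean(X, axis=0)
        if np.isnan(col_mean).any():
            raise ValueError("a bin is missing in every profile; cannot impute")
        X = np.where(nan_mask, col_mean, X)
    total_var = X.var(axis=0, ddof=1).sum()
    if not np.isfinite(total_var) or total_var <= 1e-12:
        raise DegenerateDataError("profiles have zero total variance")
    pca = PCA(n_components=2, svd_solver="full").fit(X)
    return PCAModel(kind=profiles[0].kind,
                    mean_profile=pca.mean_.copy(),
                    loadings=pca.components_.copy(),
                    explained_fraction=pca.explained_variance_ratio_.copy(),
                    bin_anchor_min=profiles[0].bin_anchor_min,
                    n_fitted=X.shape[0])


def daytime_contrast(bin_anchor_min: int = DEFAULT_ANCHOR_MIN) -> np.ndarray:
    """Contrast vector: +1 on bins covering 10:00-16:00, -1 on 19:00-22:00."""
    c = np.zeros(N_BINS)
    for clock_min, sign in ((range(600, 960, 30), 1.0), (range(1140, 1320, 30), -1.0)):
        for m in clock_min:
            c[((m - bin_anchor_min) % 1440) // 30] = sign
    return c


def orient(model: PCAModel) -> PCAModel:
    """Fix the eigenvector signs so the scores read as aging phenotypes.

    PC1: positive score = above-average total level for activity profiles,
    below-average total for sleep profiles (both the "young-age" direction);
    decided by the sign of ``loadings[0] . ones``.  PC2: positive score = the
    old-age unimodal pattern, whose mass sits in daytime bins for activity
    but leaves a daytime trough for sleep; decided by the sign of
    ``loadings[1] . daytime_contrast``.  Idempotent: orienting an already
    oriented model changes nothing.
    """
    loadings = model.loadings.copy()
    ones = np.ones(N_BINS)
    contrast = daytime_contrast(model.bin_anchor_min)

    s1 = float(loadings[0] @ ones)
    if s1 == 0.0:
        raise OrientationError("PC1 total-level contrast is exactly zero")
    want_positive_total = model.kind == ACTIVITY
    flip1 = (s1 > 0) != want_positive_total
    if flip1:
        loadings[0] = -loadings[0]

    s2 = float(loadings[1] @ contrast)
    if s2 == 0.0:
        raise OrientationError("PC2 daytime contrast is exactly zero")
    want_positive_daytime = model.kind == ACTIVITY
    flip2 = (s2 > 0) != want_positive_daytime
    if flip2:
        loadings[1] = -loadings[1]

    orientation = {
        "pc1_rule": ("dot with all-ones > 0 (positive = above-average activity)"
                     if model.kind == ACTIVITY else
                     "dot with all-ones < 0 (positive = below-average sleep)"),
        "pc1_flipped": bool(flip1),
        "pc2_rule": ("dot with daytime contrast (10:00-16:00 minus 19:00-22:00) "
                     + ("> 0" if model.kind == ACTIVITY else "< 0")
                     + " (positive = unimodal daytime-shifted old-age pattern)"),
        "pc2_flipped": bool(flip2),
    }
    return replace(model, loadings=loadings, orientation=orientation)


@dataclass(frozen=True)
class ScoreRecord:
    fly_id: str
    strain: str
    age_days: int
    pc1: float
    pc2: float
    pc1_class: str
    pc2_class: str


def _classify(s: float) -> str:
    return LE0 if s <= 0 else GT0


def score(model: PCAModel, profile: Profile48) -> ScoreRecord:
    """Project one profile on the model: pc_k = loadings_k . (values - mean)."""
    if profile.kind != model.kind:
        raise ValueError(f"profile kind {profile.kind!r} != model kind {model.kind!r}")
    if np.isnan(profile.values).any():
        raise ValueError(f"fly {profile.fly_id}: profile has missing bins")
    centered = profile.values - model.mean_profile
    pc1 = float(model.loadings[0] @ centered)
    pc2 = float(model.loadings[1] @ centered)
    return ScoreRecord(fly_id=profile.fly_id, strain=profile.strain,
                       age_days=profile.age_days, pc1=pc1, pc2=pc2,
                       pc1_class=_classify(pc1), pc2_class=_classify(pc2))


def score_table(model: PCAModel, profiles: Sequence[Profile48]) -> pd.DataFrame:
    """Score many profiles; one row per fly."""
    return pd.DataFrame([vars(score(model, p)) for p in profiles])


def rate_table(scores: pd.DataFrame,
               by: Sequence[str] = ("strain", "age_days")) -> pd.DataFrame:
    """Counts and rates of score-sign classes per group, per component."""
    if scores.empty:
        raise ValueError("no score records")
    rows = []
    for key, sub in scores.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(sub)
        row = dict(zip(by, key))
        row["n"] = n
        for comp in ("pc1", "pc2"):
            n_le0 = int((sub[f"{comp}_class"] == LE0).sum())
            row[f"{comp}_n_le0"] = n_le0
            row[f"{comp}_n_gt0"] = n - n_le0
            row[f"{comp}_rate_le0"] = n_le0 / n
            row[f"{comp}_rate_gt0"] = (n - n_le0) / n
        rows.append(row)
    return pd.DataFrame(rows)


def joint_rate_table(scores: pd.DataFrame,
                     by: Sequence[str] = ("strain", "age_days")) -> pd.DataFrame:
    """Rates of the four joint (PC1 class, PC2 class) categories per group."""
    if scores.empty:
        raise ValueError("no score records")
    rows = []
    for key, sub in scores.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(sub)
        row = dict(zip(by, key))
        row["n"] = n
        for c1 in (LE0, GT0):
            for c2 in (LE0, GT0):
                cnt = int(((sub["pc1_class"] == c1) & (sub["pc2_class"] == c2)).sum())
                row[f"n_{c1.lower()}_{c2.lower()}"] = cnt
                row[f"rate_{c1.lower()}_{c2.lower()}"] = cnt / n
        rows.append(row)
    return pd.DataFrame(rows)


def two_group_counts(scores: pd.DataFrame, group_col: str, group_a, group_b,
                     component: str = "pc1") -> np.ndarray:
    """2x2 class-count table (rows = groups, cols = LE0/GT0) for compare_rates."""
    table = np.zeros((2, 2), dtype=int)
    for i, g in enumerate((group_a, group_b)):
        sub = scores[scores[group_col] == g]
        table[i, 0] = int((sub[f"{component}_class"] == LE0).sum())
        table[i, 1] = int((sub[f"{component}_class"] == GT0).sum())
    return table


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    low_expected: bool  # some expected cell count < 5


def compare_rates(table: np.ndarray | Sequence[Sequence[float]], *,
                  correction: bool = False) -> Chi2Result:
    """Pearson chi-square test of homogeneity on a 2x2 count table.

    No continuity correction by default; pass ``correction=True`` for the
    Yates-corrected statistic.  Emits a warning (and sets ``low_expected``)
    when any expected cell count is below 5.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if np.any(obs < 0):
        raise ValueError("cell counts must be non-negative")
    rows, cols, n = obs.sum(axis=1), obs.sum(axis=0), obs.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("a zero row/column margin leaves expected counts undefined")
    expected = np.outer(rows, cols) / n
    dev = np.abs(obs - expected)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float((dev ** 2 / expected).sum())
    low = bool((expected < 5).any())
    if low:
        warnings.warn("some expected cell counts are below 5; "
                      "the chi-square approximation may be poor", stacklevel=2)
    return Chi2Result(statistic=statistic, df=1,
                      p_value=float(stats.chi2.sf(statistic, df=1)),
                      expected=expected, low_expected=low)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment for a family of p-values."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]
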