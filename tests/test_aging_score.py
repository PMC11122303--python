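"""PCA aging scores: recovery of planted structure, orientation, rates, chi-square."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import damkit as dk
from damkit.aging_score import (LE0, GT0, DegenerateDataError, OrientationError,
                                daytime_contrast)
from damkit.patterns import ACTIVITY, SLEEP
from tests.oracles import chi2_2x2_closed_form


def profiles_from_matrix(X, kind=ACTIVITY):
    return [dk.Profile48(fly_id=f"f{i}", kind=kind, values=row)
            for i, row in enumerate(X)]


def two_factor_ensemble(n=400, sd_a=3.0, sd_b=1.0, seed=0):
    """mean + a*v1 + b*v2 with exactly orthonormal v1, v2 and sample-
    uncorrelated coefficients, so the PCA solution is known in closed form."""
    k = np.arange(48)
    v1 = np.cos(2 * np.pi * k / 48)
    v2 = np.sin(2 * np.pi * k / 48)
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    rng = np.random.default_rng(seed)
    a = rng.normal(0, sd_a, n)
    b = rng.normal(0, sd_b, n)
    a -= a.mean()
    b -= b.mean()
    b -= (a @ b) / (a @ a) * a  # exact sample-orthogonality of the coefficients
    base = 10.0 + 0.05 * k
    X = base + np.outer(a, v1) + np.outer(b, v2)
    return X, v1, v2, a, b


class TestFitPCA:
    def test_recovers_planted_directions_and_fractions(self):
        X, v1, v2, a, b = two_factor_ensemble()
        model = dk.fit_pca(profiles_from_matrix(X))
        for planted, fitted in ((v1, model.loadings[0]), (v2, model.loadings[1])):
            sign = np.sign(planted @ fitted)
            np.testing.assert_allclose(sign * fitted, planted, atol=1e-6)
        var_a, var_b = np.var(a, ddof=1), np.var(b, ddof=1)
        np.testing.assert_allclose(model.explained_fraction,
                                   [var_a / (var_a + var_b), var_b / (var_a + var_b)],
                                   atol=1e-9)

    def test_orthonormal_loadings_and_ordered_fractions(self):
        rng = np.random.default_rng(1)
        model = dk.fit_pca(profiles_from_matrix(rng.random((30, 48))))
        gram = model.loadings @ model.loadings.T
        np.testing.assert_allclose(gram, np.eye(2), atol=1e-8)
        assert model.explained_fraction[0] >= model.explained_fraction[1]

    def test_identical_profiles_rejected_as_degenerate(self):
        X = np.tile(np.linspace(0, 1, 48), (5, 1))
        with pytest.raises(DegenerateDataError):
            dk.fit_pca(profiles_from_matrix(X))

    def test_fewer_than_three_profiles_rejected(self):
        X = np.random.default_rng(2).random((2, 48))
        with pytest.raises(ValueError):
            dk.fit_pca(profiles_from_matrix(X))

    def test_missing_bins_require_imputation_flag(self):
        rng = np.random.default_rng(3)
        X = rng.random((6, 48))
        X[0, 5] = np.nan
        with pytest.raises(ValueError, match="missing"):
            dk.fit_pca(profiles_from_matrix(X))
        model = dk.fit_pca(profiles_from_matrix(X), impute_missing=True)
        assert np.isfinite(model.mean_profile).all()


class TestOrient:
    def _model(self, l1, l2, kind=ACTIVITY):
        return dk.PCAModel(kind=kind, mean_profile=np.zeros(48),
                           loadings=np.vstack([l1, l2]),
                           explained_fraction=np.array([0.6, 0.2]))

    def test_constant_positive_pc1_unchanged_for_activity(self):
        l1 = np.full(48, 1 / np.sqrt(48))
        l2 = daytime_contrast()
        l2 = l2 / np.linalg.norm(l2)
        m = dk.orient(self._model(l1, l2))
        np.testing.assert_allclose(m.loadings[0], l1)
        assert m.orientation["pc1_flipped"] is False

    def test_negated_pc1_is_flipped_back(self):
        l1 = np.full(48, -1 / np.sqrt(48))
        l2 = daytime_contrast() / np.linalg.norm(daytime_contrast())
        m = dk.orient(self._model(l1, l2))
        assert (m.loadings[0] > 0).all()
        assert m.orientation["pc1_flipped"] is True

    def test_sleep_pc1_points_to_low_sleep(self):
        l1 = np.full(48, 1 / np.sqrt(48))
        l2 = daytime_contrast() / np.linalg.norm(daytime_contrast())
        m = dk.orient(self._model(l1, l2, kind=SLEEP))
        # positive score must mean below-average sleep: loading flipped negative
        assert (m.loadings[0] < 0).all()

    def test_orientation_is_idempotent(self):
        rng = np.random.default_rng(4)
        X = rng.random((20, 48)) + np.linspace(0, 2, 48)
        once = dk.orient(dk.fit_pca(profiles_from_matrix(X)))
        twice = dk.orient(once)
        np.testing.assert_allclose(once.loadings, twice.loadings)

    def test_zero_contrast_is_ambiguous(self):
        l1 = np.full(48, 1 / np.sqrt(48))
        l2 = np.zeros(48)
        l2[0] = 1.0  # orthogonal to the daytime contrast (bin 0 = 7:00)
        with pytest.raises(OrientationError):
            dk.orient(self._model(l1, l2))

    def test_old_cohorts_score_old_after_orientation(self):
        """On simulated young vs old flies, orientation makes old cohorts sit
        lower on PC1 (less activity) and higher on PC2 (daytime pattern)."""
        cfg = dk.SimConfig(n_days=3, light_regime="DD", temperature_c=29.0, seed=6)
        young = dk.AgeMorph.for_age(3, dk.CANTON_S.aging_rate)
        old = dk.AgeMorph.for_age(32, dk.HARWICH.aging_rate)
        traces = dk.simulate_cohort([(dk.CANTON_S, young, 40),
                                     (dk.HARWICH, old, 40)], cfg)
        profs = [dk.daily_profile(t) for t in traces]
        model = dk.orient(dk.fit_pca(profs))
        scores = dk.score_table(model, profs)
        young_s = scores[scores.age_days == 3]
        old_s = scores[scores.age_days == 32]
        assert old_s.pc1.mean() < young_s.pc1.mean()
        assert (old_s.pc2 > 0).mean() > (young_s.pc2 > 0).mean()


class TestScore:
    @pytest.fixture
    def model(self):
        X, *_ = two_factor_ensemble(seed=7)
        return dk.orient(dk.fit_pca(profiles_from_matrix(X)))

    def test_profile_at_model_mean_scores_zero(self, model):
        p = dk.Profile48(fly_id="m", kind=ACTIVITY, values=model.mean_profile.copy())
        rec = dk.score(model, p)
        assert rec.pc1 == pytest.approx(0, abs=1e-9)
        assert rec.pc2 == pytest.approx(0, abs=1e-9)
        assert (rec.pc1_class, rec.pc2_class) == (LE0, LE0)  # 0 falls in <=0

    def test_mean_plus_two_loadings_scores_two(self, model):
        p = dk.Profile48(fly_id="p", kind=ACTIVITY,
                         values=model.mean_profile + 2 * model.loadings[0])
        rec = dk.score(model, p)
        assert rec.pc1 == pytest.approx(2.0, abs=1e-9)
        assert rec.pc2 == pytest.approx(0.0, abs=1e-9)

    def test_training_score_variance_reproduces_explained_fraction(self):
        X, *_ = two_factor_ensemble(seed=8)
        profs = profiles_from_matrix(X)
        model = dk.fit_pca(profs)
        table = dk.score_table(model, profs)
        total = (X - X.mean(axis=0)).var(axis=0, ddof=1).sum()
        assert np.var(table.pc1, ddof=1) / total == \
               pytest.approx(model.explained_fraction[0], rel=1e-9)

    def test_uniform_shift_moves_mean_not_scores(self):
        """Adding a constant to every profile is absorbed by the centering."""
        X, *_ = two_factor_ensemble(seed=9)
        profs = profiles_from_matrix(X)
        shifted = profiles_from_matrix(X + 5.0)
        m1, m2 = dk.fit_pca(profs), dk.fit_pca(shifted)
        s1 = dk.score_table(m1, profs)
        s2 = dk.score_table(m2, shifted)
        sign1 = np.sign(m1.loadings[0] @ m2.loadings[0])
        np.testing.assert_allclose(s1.pc1, sign1 * s2.pc1, atol=1e-8)

    def test_kind_mismatch_rejected(self, model):
        p = dk.Profile48(fly_id="s", kind=SLEEP, values=np.ones(48))
        with pytest.raises(ValueError):
            dk.score(model, p)


class TestRateTable:
    def make_scores(self, pc1s, group="g"):
        return pd.DataFrame({
            "fly_id": [f"f{i}" for i in range(len(pc1s))],
            "strain": group, "age_days": 0,
            "pc1": pc1s, "pc2": pc1s,
            "pc1_class": [LE0 if s <= 0 else GT0 for s in pc1s],
            "pc2_class": [LE0 if s <= 0 else GT0 for s in pc1s],
        })

    def test_half_and_half(self):
        table = dk.rate_table(self.make_scores([-1.0, 1.0]))
        assert table.loc[0, "pc1_rate_le0"] == 0.5
        assert table.loc[0, "pc1_n_le0"] + table.loc[0, "pc1_n_gt0"] == table.loc[0, "n"]

    def test_exact_zero_counts_as_le0(self):
        table = dk.rate_table(self.make_scores([0.0]))
        assert table.loc[0, "pc1_n_le0"] == 1

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(10)
        scores = self.make_scores(rng.normal(size=200))
        table = dk.rate_table(scores)
        assert table.loc[0, "pc1_n_le0"] == int((scores.pc1 <= 0).sum())

    def test_joint_rates_sum_to_one(self):
        rng = np.random.default_rng(11)
        scores = self.make_scores(rng.normal(size=100))
        joint = dk.joint_rate_table(scores)
        rate_cols = [c for c in joint.columns if c.startswith("rate_")]
        assert joint[rate_cols].sum(axis=1).iloc[0] == pytest.approx(1.0)


class TestCompareRates:
    def test_homogeneous_table(self):
        r = dk.compare_rates([[10, 10], [10, 10]])
        assert r.statistic == 0 and r.p_value == pytest.approx(1.0)
        assert r.df == 1

    def test_matches_closed_form(self):
        r = dk.compare_rates([[30, 10], [10, 30]])
        assert r.statistic == pytest.approx(chi2_2x2_closed_form(30, 10, 10, 30),
                                            rel=1e-12)

    def test_row_swap_invariance(self):
        a = dk.compare_rates([[25, 9], [12, 30]])
        b = dk.compare_rates([[12, 30], [25, 9]])
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            dk.compare_rates([[0, 0], [5, 5]])
        with pytest.raises(ValueError):
            dk.compare_rates([[5, 0], [5, 0]])

    def test_low_expected_count_warns(self):
        with pytest.warns(UserWarning, match="expected"):
            r = dk.compare_rates([[2, 8], [3, 7]])
        assert r.low_expected

    def test_yates_correction_matches_scipy(self):
        table = np.array([[18, 12], [9, 21]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ours_plain = dk.compare_rates(table)
            ours_yates = dk.compare_rates(table, correction=True)
        chi2_p, p_p, _, _ = stats.chi2_contingency(table, correction=False)
        chi2_y, p_y, _, _ = stats.chi2_contingency(table, correction=True)
        assert ours_plain.statistic == pytest.approx(chi2_p, rel=1e-12)
        assert ours_plain.p_value == pytest.approx(p_p, rel=1e-12)
        assert ours_yates.statistic == pytest.approx(chi2_y, rel=1e-12)

    def test_agrees_with_permutation_null_at_moderate_n(self):
        """Randomization of group labels reproduces the asymptotic p-value
        (n = 200; agreement within the asymptotic approximation error)."""
        table = np.array([[60, 40], [45, 55]])
        r = dk.compare_rates(table)
        labels = np.repeat([1, 0], 100)
        outcomes = np.concatenate([np.repeat([1, 0], [60, 40]),
                                   np.repeat([1, 0], [45, 55])])
        rng = np.random.default_rng(12)
        count = 0
        n_perm = 20000
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            a = int((outcomes & (perm == 1)).sum())
            stat = chi2_2x2_closed_form(a, 100 - a,
                                        60 + 45 - a, 100 - (60 + 45 - a))
            if stat >= r.statistic - 1e-12:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        assert abs(p_perm - r.p_value) < 0.015

    def test_holm_adjustment_is_monotone_and_bounded(self):
        adj = dk.holm_adjust([0.01, 0.04, 0.03])
        assert (adj >= [0.01, 0.04, 0.03]).all() and (adj <= 1).all()
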