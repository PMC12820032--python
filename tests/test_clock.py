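import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import methclock as mc
from methclock.clock import AgeTransform, TrainConfig, fit_clock, fit_restricted_clock

FAST = TrainConfig(
    corr_select_top_k=None,
    en_alpha_grid=(0.01, 0.1, 1.0),
    en_l1_ratio_grid=(0.5, 1.0),
    outer_folds=3,
    inner_folds=3,
    seed=1,
)


class TestAgeTransform:
    def test_threshold_and_forced_points(self):
        tf = AgeTransform(20.0)
        assert tf.forward(20.0) == pytest.approx(0.0, abs=1e-15)
        assert tf.forward(41.0) == pytest.approx(1.0, abs=1e-15)  # 21/21
        assert tf.forward(0.0) == pytest.approx(-np.log(21.0), abs=1e-12)

    def test_round_trip_both_branches(self):
        tf = AgeTransform(20.0)
        ages = np.linspace(0.0, 120.0, 10_000)
        np.testing.assert_allclose(tf.inverse(tf.forward(ages)), ages, atol=1e-12)

    def test_monotone_and_continuous_at_knot(self):
        tf = AgeTransform(20.0)
        grid = np.linspace(0, 100, 5000)
        vals = tf.forward(grid)
        assert np.all(np.diff(vals) > 0)
        assert abs(tf.forward(20.0 - 1e-9) - tf.forward(20.0 + 1e-9)) < 1e-8

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            AgeTransform().forward(-0.1)

    @settings(derandomize=True, max_examples=200)
    @given(
        age=st.floats(0.0, 150.0, allow_nan=False),
        adult=st.floats(1.0, 60.0, allow_nan=False),
    )
    def test_round_trip_property(self, age, adult):
        tf = AgeTransform(adult)
        assert tf.inverse(tf.forward(age)) == pytest.approx(age, abs=1e-9)
        assert tf.forward(adult) == pytest.approx(0.0, abs=1e-12)


def _informative_cohort(n=40, p=8, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    ages = np.linspace(20, 80, n)
    x = rng.uniform(0.2, 0.8, (n, p))
    x[:, 0] = ages / 100.0
    if noise:
        x += rng.normal(0, noise, x.shape)
    return x, ages


class TestFitClock:
    def test_single_informative_feature_near_exact(self):
        ages = np.linspace(20, 80, 40)
        x = (ages / 100.0)[:, None]  # one noiseless feature
        cfg = TrainConfig(
            corr_select_top_k=None,
            en_alpha_grid=(1e-4, 1e-3, 1e-2),
            en_l1_ratio_grid=(0.5, 1.0),
            outer_folds=3,
            inner_folds=3,
            seed=1,
        )
        model, cv = fit_clock(x, ages, cfg)
        rep = mc.regression_metrics(cv.oof_pred_years, ages)
        assert rep.mae < 1.0

    def test_determinism(self):
        x, ages = _informative_cohort(noise=0.01)
        m1, cv1 = fit_clock(x, ages, FAST)
        m2, cv2 = fit_clock(x, ages, FAST)
        np.testing.assert_array_equal(m1.en_coefs, m2.en_coefs)
        np.testing.assert_array_equal(m1.pca_components, m2.pca_components)
        np.testing.assert_array_equal(cv1.oof_pred_years, cv2.oof_pred_years)

    def test_preconditions(self):
        x, ages = _informative_cohort(n=5)
        with pytest.raises(ValueError, match="samples"):
            fit_clock(x, ages, FAST)
        x, _ = _informative_cohort(n=40)
        with pytest.raises(ValueError, match="constant"):
            fit_clock(x, np.full(40, 33.0), FAST)

    def test_no_leakage_fold_parameters_ignore_test_rows(self):
        x, ages = _informative_cohort(noise=0.02, seed=3)
        _, cv1 = fit_clock(x, ages, FAST)
        fold = cv1.folds[0]
        corrupted = x.copy()
        corrupted[fold.test_indices] = 0.99  # garbage in this fold's test rows
        _, cv2 = fit_clock(corrupted, ages, FAST)
        np.testing.assert_array_equal(cv2.folds[0].test_indices, fold.test_indices)
        np.testing.assert_array_equal(cv2.folds[0].impute_means, fold.impute_means)
        assert (cv2.folds[0].alpha, cv2.folds[0].l1_ratio) == (fold.alpha, fold.l1_ratio)

    def test_predictions_finite_with_missingness(self):
        x, ages = _informative_cohort(noise=0.02, seed=5)
        rng = np.random.default_rng(5)
        x[rng.random(x.shape) < 0.2] = np.nan
        model, cv = fit_clock(x, ages, FAST)
        assert np.all(np.isfinite(cv.oof_pred_years))
        pred, cov = mc.predict_age(model, x[:5])
        assert np.all(np.isfinite(pred))


class TestPredict:
    @staticmethod
    def _hand_model():
        # 2 features, identity PCA: prediction is fully hand-computable
        return mc.ClockModel(
            feature_kind="cpg",
            feature_ids=["chr1:10", "chr1:20"],
            impute_means=np.array([0.4, 0.6]),
            scale_means=np.array([0.5, 0.5]),
            scale_sds=np.array([0.1, 0.2]),
            pca_mean=np.array([0.0, 0.0]),
            pca_components=np.eye(2),
            en_intercept=0.5,
            en_coefs=np.array([0.8, -0.3]),
        )

    def test_hand_computed_linear_algebra(self):
        model = self._hand_model()
        x = np.array([[0.62, 0.44]])
        z = (x[0] - [0.5, 0.5]) / [0.1, 0.2]  # [1.2, -0.3]
        y = 0.5 + 0.8 * z[0] - 0.3 * z[1]  # 1.55
        expected = 1.55 * 21 + 20  # linear branch of the inverse transform
        pred, cov = mc.predict_age(model, x)
        assert pred[0] == pytest.approx(expected, abs=1e-10)
        assert cov[0] == 1.0

    def test_all_missing_predicts_imputed_value_coverage_zero(self):
        model = self._hand_model()
        pred_missing, cov = mc.predict_age(model, np.array([[np.nan, np.nan]]))
        pred_imputed, _ = mc.predict_age(model, model.impute_means[None, :])
        assert cov[0] == 0.0
        assert pred_missing[0] == pytest.approx(pred_imputed[0])

    def test_half_coverage(self):
        model = self._hand_model()
        _, cov = mc.predict_age(model, np.array([[0.5, np.nan]]))
        assert cov[0] == 0.5


class TestRestrictedClock:
    def test_all_sites_reduces_to_unrestricted(self):
        x, ages = _informative_cohort(noise=0.01, seed=7)
        m1, _ = fit_restricted_clock(x, ages, np.arange(x.shape[1]), FAST)
        m2, _ = fit_clock(x, ages, FAST)  # FAST already disables selection
        np.testing.assert_allclose(m1.en_coefs, m2.en_coefs)
        assert m1.feature_kind == "restricted_cpg"

    def test_feature_count_matches_allowed_set(self):
        x, ages = _informative_cohort(p=20, noise=0.01, seed=8)
        allowed = [0, 3, 5, 11]
        model, _ = fit_restricted_clock(x, ages, allowed, FAST)
        assert model.n_features == 4

    def test_empty_intersection_errors(self):
        x, ages = _informative_cohort()
        with pytest.raises(ValueError, match="empty"):
            fit_restricted_clock(x, ages, [], FAST)


class TestModelOnCohorts:
    def test_serialized_model_predicts_identically_on_cohort(self, small_cohort, tmp_path):
        cohort, _ = small_cohort
        model, _ = fit_clock(
            cohort.beta,
            cohort.ages,
            FAST,
            feature_ids=cohort.universe.site_ids,
        )
        p1, c1 = mc.predict_cohort(model, cohort)
        mc.write_model(model, tmp_path / "m.json")
        reloaded = mc.read_model(tmp_path / "m.json")
        p2, c2 = mc.predict_cohort(reloaded, cohort)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(c1, c2)

    def test_region_model_recomputes_member_means(self, small_cohort):
        cohort, _ = small_cohort
        corr = mc.age_correlation(cohort)
        rs = mc.build_regions(cohort.universe, corr, 0.075)
        feats, _ = mc.region_betas(cohort, rs)
        model, _ = fit_clock(
            feats,
            cohort.ages,
            FAST,
            feature_ids=rs.feature_ids(cohort.universe),
            feature_kind="region",
            feature_sites=rs.member_site_ids(cohort.universe),
        )
        rebuilt = mc.features_for_model(model, cohort)
        ids = rs.feature_ids(cohort.universe)
        cols = [ids.index(fid) for fid in model.feature_ids]
        np.testing.assert_allclose(
            np.nan_to_num(rebuilt, nan=-1.0),
            np.nan_to_num(feats[:, cols], nan=-1.0),
        )


def test_split_is_deterministic_and_sized():
    mask, test_idx = mc.train_test_split_indices(462, 75 / 462, seed=0)
    assert len(test_idx) == 75
    assert mask.sum() == 387
    mask2, test2 = mc.train_test_split_indices(462, 75 / 462, seed=0)
    np.testing.assert_array_equal(test_idx, test2)
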