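"""NIPALS PLS1: fitting, dual-route prediction, cross-validation, metrics."""

import numpy as np
import pytest

from mangospec.pls import (
    fit_pls,
    loo_cv,
    predict,
    predict_via_scores,
    regression_metrics,
    split_calibration_validation,
)


def _two_factor_problem(rng, n=20, p=12, noise=0.0):
    """y exactly linear in two orthogonal spectral factors."""
    f1 = np.sin(np.linspace(0, np.pi, p))
    f2 = np.cos(np.linspace(0, 3 * np.pi, p))
    t1, t2 = rng.standard_normal(n), rng.standard_normal(n)
    X = np.outer(t1, f1) + np.outer(t2, f2) + noise * rng.standard_normal((n, p))
    y = 2.0 * t1 - 1.0 * t2 + 5.0
    return X, y


class TestFit:
    def test_exact_two_factor_recovery(self, rng):
        X, y = _two_factor_problem(rng)
        model = fit_pls(X, y, 2)
        r2 = regression_metrics(y, predict(model, X)).r2
        assert r2 == pytest.approx(1.0, abs=1e-8)

    def test_full_rank_equals_min_norm_least_squares(self, rng):
        X = rng.standard_normal((10, 8))
        y = rng.standard_normal(10)
        model = fit_pls(X, y, 8)
        # oracle: pseudo-inverse minimum-norm solution on centered data
        Xc = X - X.mean(axis=0)
        b_oracle = np.linalg.pinv(Xc) @ (y - y.mean())
        np.testing.assert_allclose(model.coef, b_oracle, rtol=1e-6, atol=1e-9)

    def test_permutation_invariance(self, rng):
        X, y = _two_factor_problem(rng, noise=0.1)
        perm = rng.permutation(len(y))
        m1 = fit_pls(X, y, 3)
        m2 = fit_pls(X[perm], y[perm], 3)
        np.testing.assert_allclose(m1.coef, m2.coef, atol=1e-10)

    def test_beyond_rank_truncates_with_warning(self, rng):
        X, y = _two_factor_problem(rng)  # rank 2
        with pytest.warns(UserWarning):
            model = fit_pls(X, y, 6)
        assert model.n_components <= 3

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            fit_pls(rng.standard_normal((6, 4)), np.ones(6), 2)


class TestPredict:
    def test_reproduces_training_targets_in_exact_case(self, rng):
        X, y = _two_factor_problem(rng)
        model = fit_pls(X, y, 2)
        np.testing.assert_allclose(predict(model, X), y, atol=1e-8)

    def test_mean_spectrum_predicts_mean_response(self, rng):
        X, y = _two_factor_problem(rng, noise=0.2)
        model = fit_pls(X, y, 3)
        assert predict(model, model.x_mean[None, :])[0] == pytest.approx(
            model.y_mean, abs=1e-10
        )

    def test_dual_route_consistency(self, rng):
        """Compact-coefficient and score-space predictions agree."""
        X, y = _two_factor_problem(rng, noise=0.3)
        model = fit_pls(X, y, 4)
        X_new = rng.standard_normal((15, X.shape[1]))
        np.testing.assert_allclose(
            predict(model, X_new), predict_via_scores(model, X_new), atol=1e-8
        )

    def test_feature_mismatch_rejected(self, rng):
        X, y = _two_factor_problem(rng)
        model = fit_pls(X, y, 2)
        with pytest.raises(ValueError, match="feature count"):
            predict(model, np.zeros((2, 5)))

    def test_matches_sklearn_nipals(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _two_factor_problem(rng, n=30, p=20, noise=0.2)
        ours = fit_pls(X, y, 3)
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y)
        X_new = rng.standard_normal((10, 20))
        np.testing.assert_allclose(
            predict(ours, X_new), ref.predict(X_new).ravel(), atol=1e-8
        )


class TestLooCv:
    def test_noise_free_one_factor(self, rng):
        p = 10
        f = np.linspace(1, 2, p)
        t = rng.standard_normal(15)
        X = np.outer(t, f)
        y = 3 * t + 1
        cv = loo_cv(X, y, max_components=4)
        assert cv.n_components == 1
        assert cv.rmsecv[0] < 1e-8

    def test_matches_naive_double_loop_oracle(self, rng):
        X = rng.standard_normal((6, 5))
        y = rng.standard_normal(6)
        cv = loo_cv(X, y, max_components=3)
        # oracle: refit from scratch for every (component count, left-out)
        for a in (1, 2, 3):
            press = 0.0
            for i in range(6):
                keep = np.arange(6) != i
                model = fit_pls(X[keep], y[keep], a)
                press += (y[i] - predict(model, X[i][None, :])[0]) ** 2
            np.testing.assert_allclose(cv.rmsecv[a - 1], np.sqrt(press / 6),
                                       rtol=1e-9)

    def test_pure_noise_response(self):
        """Across simulations, RMSECV stays near sd(y) and A* stays small."""
        rng = np.random.default_rng(99)
        ratios, chosen = [], []
        for _ in range(30):
            X = rng.standard_normal((20, 10))
            y = rng.standard_normal(20)
            cv = loo_cv(X, y, max_components=6)
            ratios.append(cv.rmsecv[cv.n_components - 1] / y.std(ddof=1))
            chosen.append(cv.n_components)
        assert 0.7 < np.median(ratios) < 1.4
        assert np.median(chosen) <= 2

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            loo_cv(rng.standard_normal((2, 4)), np.array([1.0, 2.0]), 2)


class TestNoisePredictors:
    def test_noise_columns_raise_cv_error_not_training_fit(self):
        """Appending pure-noise bands never hurts the training fit but
        inflates RMSECV past the true component count (aggregate over 30
        simulated instances)."""
        rng = np.random.default_rng(5)
        train_deltas, cv_deltas = [], []
        for _ in range(30):
            X, y = _two_factor_problem(rng, n=16, p=8, noise=0.05)
            X_aug = np.hstack([X, rng.standard_normal((16, 8))])
            # full rank: PLS equals least squares, where extra columns can
            # only improve the training fit
            r2 = regression_metrics(y, predict(fit_pls(X, y, 8), X)).r2
            r2_aug = regression_metrics(
                y, predict(fit_pls(X_aug, y, 14), X_aug)
            ).r2
            train_deltas.append(r2_aug - r2)
            cv = loo_cv(X, y, 5)
            cv_aug = loo_cv(X_aug, y, 5)
            cv_deltas.append(cv_aug.rmsecv[4] - cv.rmsecv[1])
        assert min(train_deltas) > -1e-8
        assert np.mean(np.array(cv_deltas) > 0) > 0.8


class TestSplit:
    def test_study_ratio_twelve_eight(self):
        cal, val = split_calibration_validation(20, ratio=3 / 5, seed=0)
        assert len(cal) == 12 and len(val) == 8

    def test_three_quarter_ratio(self):
        cal, val = split_calibration_validation(20, ratio=3 / 4, seed=0)
        assert len(cal) == 15 and len(val) == 5

    def test_deterministic_and_partition(self):
        a = split_calibration_validation(37, ratio=0.6, seed=42)
        b = split_calibration_validation(37, ratio=0.6, seed=42)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        merged = np.sort(np.concatenate(a))
        np.testing.assert_array_equal(merged, np.arange(37))

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            split_calibration_validation(2, ratio=0.9, seed=0)


class TestMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2, 3], [1.0, 2, 3])
        assert m.r2 == 1.0 and m.rmse == 0.0

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2, 3, 4])
        m = regression_metrics(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_rmse(self):
        m = regression_metrics([1.0, 2, 3], [1.0, 2, 4])
        assert m.rmse == pytest.approx(np.sqrt(1 / 3), rel=1e-12)

    def test_negative_r2_possible(self):
        m = regression_metrics([1.0, 2, 3], [10.0, -4, 7])
        assert m.r2 < 0

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            regression_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
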