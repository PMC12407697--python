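"""Feature selection, standardization, linear SVM and cross-validation."""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.feature_selection import f_classif

from lamodc import (DecoderConfig, SessionSamples, f_statistic, feature_count_sweep,
                    leave_one_run_out, select_features, standardize,
                    train_linear_classifier)


def make_samples(X, y, run_id, region="V1"):
    n_v = X.shape[1]
    return SessionSamples(X=X, y=np.asarray(y), run_id=np.asarray(run_id),
                          region_label=np.asarray([region] * n_v),
                          shared_fov_mask=np.ones(n_v, bool),
                          depth_fractions=np.linspace(0, 1, X.shape[2]),
                          vertex_index=np.arange(n_v))


class TestFStatistic:
    def test_constant_feature_is_zero(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        y = np.array([1, 1, 1, -1, -1, -1])
        assert f_statistic(X, y)[0] == 0.0

    def test_separable_zero_variance_feature_is_flagged_infinite(self):
        X = np.array([[1.0], [1.0], [3.0], [3.0]])
        y = np.array([1, 1, -1, -1])
        assert np.isinf(f_statistic(X, y)[0])

    def test_hand_anova_oracle(self):
        # L = {0,1,2}, R = {2,3,4}: SSB = 6, MSW = 1 -> F = 6
        X = np.array([[0.0], [1.0], [2.0], [2.0], [3.0], [4.0]])
        y = np.array([1, 1, 1, -1, -1, -1])
        assert f_statistic(X, y)[0] == pytest.approx(6.0, abs=1e-12)

    def test_matches_sklearn_f_classif(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 25))
        y = np.repeat([1, -1], 20)
        ours = f_statistic(X, y)
        ref, _ = f_classif(X, y)
        assert np.allclose(ours, ref, rtol=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            f_statistic(np.zeros((4, 2)), np.ones(4))


class TestSelectFeatures:
    def test_planted_informative_vertices_recovered(self):
        rng = np.random.default_rng(1)
        n_s, n_v, n_d = 32, 60, 3
        y = np.tile([1, -1], n_s // 2)
        X = rng.standard_normal((n_s, n_v, n_d)) * 0.01
        informative = np.arange(10, 30)
        X[:, informative, :] += y[:, None, None] * 1.0
        samples = make_samples(X, y, np.repeat([0, 1], n_s // 2))
        cfg = DecoderConfig(n_features=20)
        feats = select_features(samples, cfg, [0, 1])
        assert set(feats[0]) == set(informative)

    def test_full_selection_is_identity(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((16, 12, 2))
        y = np.tile([1, -1], 8)
        samples = make_samples(X, y, np.repeat([0, 1], 8))
        feats = select_features(samples, DecoderConfig(n_features=12), [0, 1])
        assert set(feats[0]) == set(range(12))

    def test_mean_depth_mode_shares_one_set_across_depths(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((16, 30, 5))
        y = np.tile([1, -1], 8)
        samples = make_samples(X, y, np.repeat([0, 1], 8))
        feats = select_features(samples, DecoderConfig(n_features=5), [0, 1])
        for d in range(1, 5):
            assert np.array_equal(feats[d], feats[0])

    def test_per_depth_mode_can_differ(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((32, 30, 2))
        y = np.tile([1, -1], 16)
        X[:, 0, 0] += y * 2.0   # informative only at depth 0
        X[:, 1, 1] += y * 2.0   # informative only at depth 1
        samples = make_samples(X, y, np.repeat([0, 1], 16))
        feats = select_features(samples, DecoderConfig(n_features=1,
                                                       selection_mode="per_depth"),
                                [0, 1])
        assert feats[0][0] == 0 and feats[1][0] == 1

    def test_insufficient_vertices_rejected(self):
        X = np.zeros((8, 4, 1))
        samples = make_samples(X, np.tile([1, -1], 4), np.repeat([0, 1], 4))
        with pytest.raises(ValueError):
            select_features(samples, DecoderConfig(n_features=10), [0, 1])


class TestStandardize:
    def test_train_moments_and_test_transform(self):
        rng = np.random.default_rng(5)
        tr = rng.uniform(1, 5, (30, 8))
        te = tr.mean(axis=0, keepdims=True)
        ztr, zte = standardize(tr, te)
        assert np.allclose(ztr.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(ztr.std(axis=0), 1.0, atol=1e-10)
        assert np.allclose(zte, 0.0, atol=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        tr = rng.standard_normal((20, 5))
        ztr1, _ = standardize(tr, tr)
        ztr2, _ = standardize(3.0 * tr + 7.0, tr)
        assert np.allclose(ztr1, ztr2, atol=1e-10)

    def test_zero_variance_feature_dropped_with_warning(self):
        tr = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning):
            ztr, _ = standardize(tr, tr)
        assert ztr.shape[1] == 1


def svm_dual_qp(X, y, C=1.0):
    """Reference solution of the soft-margin dual via SLSQP."""
    K = (X @ X.T) * np.outer(y, y)
    n = len(y)
    res = minimize(lambda a: 0.5 * a @ K @ a - a.sum(),
                   x0=np.full(n, min(C, 0.1)),
                   jac=lambda a: K @ a - 1.0,
                   bounds=[(0.0, C)] * n,
                   constraints={"type": "eq", "fun": lambda a: a @ y,
                                "jac": lambda a: y.astype(float)},
                   method="SLSQP", options={"maxiter": 500, "ftol": 1e-12})
    return X.T @ (res.x * y)


class TestLinearClassifier:
    def test_separable_pair_classified_perfectly(self):
        Z = np.array([[-1.0], [1.0]])
        y = np.array([-1, 1])
        model = train_linear_classifier(Z, y)
        assert np.array_equal(model.predict(Z), y)

    def test_label_flip_negates_weights(self):
        rng = np.random.default_rng(7)
        Z = rng.standard_normal((20, 3)) + np.outer(np.tile([1, -1], 10), [1, 0.5, 0])
        y = np.tile([1, -1], 10)
        w_pos = train_linear_classifier(Z, y).coef_.ravel()
        w_neg = train_linear_classifier(Z, -y).coef_.ravel()
        cos = w_pos @ -w_neg / (np.linalg.norm(w_pos) * np.linalg.norm(w_neg))
        assert cos > 0.9999

    def test_matches_quadratic_program_oracle(self):
        rng = np.random.default_rng(8)
        y = np.tile([1, -1], 10)
        X = rng.standard_normal((20, 2)) + np.outer(y, [2.0, 1.0])
        w_qp = svm_dual_qp(X, y, C=1.0)
        w = train_linear_classifier(X, y, 1.0).coef_.ravel()
        cos = w @ w_qp / (np.linalg.norm(w) * np.linalg.norm(w_qp))
        assert cos > 0.9999

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_classifier(np.zeros((4, 2)), np.ones(4))


class TestCrossValidation:
    def _informative_samples(self, n_runs=4, per_run=16, n_v=30, n_d=3, snr=2.0,
                             seed=9):
        rng = np.random.default_rng(seed)
        n_s = n_runs * per_run
        y = np.tile([1, -1], n_s // 2)
        X = rng.standard_normal((n_s, n_v, n_d))
        X[:, :10, :] += snr * y[:, None, None]
        return make_samples(X, y, np.repeat(np.arange(n_runs), per_run))

    def test_fold_count_and_shape(self):
        samples = self._informative_samples()
        res = leave_one_run_out(samples, DecoderConfig(n_features=10))
        assert res.accuracy.shape == (4, 3)

    def test_noiseless_high_gain_session_is_perfect(self):
        samples = self._informative_samples(snr=50.0)
        res = leave_one_run_out(samples, DecoderConfig(n_features=10))
        assert np.allclose(res.mean_accuracy, 1.0)

    def test_no_test_set_leakage(self):
        """A feature that perfectly separates classes only in the held-out
        run must never be selected for that fold."""
        samples = self._informative_samples(n_runs=4)
        artifact = samples.X.shape[1] - 1
        test_run = 0
        sel = samples.run_id == test_run
        samples.X[:, artifact, :] = 0.01 * np.random.default_rng(0).standard_normal(
            (samples.X.shape[0], samples.X.shape[2]))
        samples.X[sel, artifact, :] = samples.y[sel][:, None] * 100.0
        res = leave_one_run_out(samples, DecoderConfig(n_features=5))
        fold_feats = res.selected[test_run]
        assert artifact not in fold_feats

    def test_fewer_than_two_runs_rejected(self):
        samples = self._informative_samples(n_runs=1)
        with pytest.raises(ValueError):
            leave_one_run_out(samples, DecoderConfig(n_features=5))


class TestFeatureCountSweep:
    def test_matrix_shape(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((32, 20, 2))
        y = np.tile([1, -1], 16)
        samples = make_samples(X, y, np.repeat([0, 1], 16))
        acc = feature_count_sweep(samples, DecoderConfig(n_features=5), [1, 3, 5])
        assert acc.shape == (3, 2)

    def test_single_dominant_vertex_selected_at_k1(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((32, 20, 1)) * 0.01
        y = np.tile([1, -1], 16)
        X[:, 7, 0] += y * 5.0
        samples = make_samples(X, y, np.repeat([0, 1], 16))
        acc = feature_count_sweep(samples, DecoderConfig(n_features=1), [1])
        assert acc[0, 0] == 1.0

    def test_full_count_matches_plain_cross_validation(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((32, 15, 2))
        y = np.tile([1, -1], 16)
        X[:, :5, :] += 0.8 * y[:, None, None]
        samples = make_samples(X, y, np.repeat([0, 1], 16))
        cfg = DecoderConfig(n_features=15)
        sweep = feature_count_sweep(samples, cfg, [15])
        direct = leave_one_run_out(samples, cfg)
        assert np.allclose(sweep[0], direct.mean_accuracy)
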