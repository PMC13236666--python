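"""Model layer: folds, metric identities, paired tests, Shapley axioms."""

import math

import numpy as np
import pandas as pd
import pytest

from ecgload.model import (
    classification_metrics,
    fit_predict,
    holm_correction,
    make_folds,
    paired_ttest,
    regression_metrics,
    shapley_attribution,
    _exact_shapley,
)


class TestFolds:
    def manifest(self, n=40):
        return pd.DataFrame(
            {
                "session_type": ["training", "competition"] * (n // 2),
                "stratum": (["low"] * (n // 2) + ["high"] * (n // 2)),
            }
        )

    def test_balanced_fold_sizes(self):
        m = self.manifest(40)
        assign = make_folds(m, k=10, seed=0)
        for f in range(10):
            sub = m[assign == f]
            assert len(sub) == 4
            assert (sub.session_type == "training").sum() == 2

    def test_partition_property(self):
        assign = make_folds(self.manifest(40), k=10, seed=0)
        assert sorted(np.unique(assign)) == list(range(10))
        assert assign.size == 40

    def test_deterministic_under_seed(self):
        m = self.manifest(40)
        np.testing.assert_array_equal(make_folds(m, 10, 3), make_folds(m, 10, 3))
        assert not np.array_equal(make_folds(m, 10, 3), make_folds(m, 10, 4))

    def test_small_stratum_falls_back_with_warning(self):
        m = self.manifest(40)
        m.loc[0, "stratum"] = "rare"
        with pytest.warns(UserWarning, match="falling back"):
            make_folds(m, k=10, seed=0)


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.mae == m.rmse == 0.0 and m.r2 == 1.0

    def test_mean_predictor_scores_zero(self, rng):
        y = rng.uniform(0, 10, 50)
        m = regression_metrics(y, np.full(50, y.mean()))
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert m.mae == pytest.approx(1 / 3)
        assert m.rmse == pytest.approx(math.sqrt(1 / 3), abs=1e-9)
        assert m.r2 == pytest.approx(0.5)  # SSres 1, SStot 2

    def test_rmse_at_least_mae(self, rng):
        y = rng.standard_normal(200)
        yhat = y + rng.standard_normal(200)
        m = regression_metrics(y, yhat)
        assert m.rmse >= m.mae >= 0

    def test_constant_target_r2_missing(self):
        m = regression_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert math.isnan(m.r2)


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        y = [0, 1, 2] * 10
        proba = np.eye(3)[y]
        m = classification_metrics(y, y, proba, classes=[0, 1, 2])
        assert m.accuracy == m.precision == m.recall == m.f1 == m.auc == 1.0

    def test_chance_level_auc(self, rng):
        y = rng.integers(0, 3, 3000)
        proba = rng.dirichlet(np.ones(3), size=3000)
        pred = proba.argmax(axis=1)
        m = classification_metrics(y, pred, proba, classes=[0, 1, 2])
        assert abs(m.auc - 0.5) < 0.05

    def test_harmonic_mean_identity(self):
        # one class: recall 1/2, precision 1 -> F1 = 2/3
        y = [1, 1, 0, 0]
        pred = [1, 0, 0, 0]
        m = classification_metrics(y, pred, classes=[0, 1])
        tp, fp, fn = 1, 0, 1
        prec, rec = 1.0, 0.5
        f1_pos = 2 * prec * rec / (prec + rec)
        assert f1_pos == pytest.approx(2 / 3)
        # macro over both classes
        assert m.recall == pytest.approx((1.0 + 0.5) / 2)

    def test_absent_class_warns(self):
        with pytest.warns(UserWarning, match="absent"):
            classification_metrics([0, 0, 1], [0, 0, 1], classes=[0, 1, 2])


class TestPairedTtest:
    def test_identical_folds(self):
        t, p = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        t, p = paired_ttest([2.0] * 5, [1.0] * 5)
        assert math.isinf(t) and p == 0.0

    def test_closed_form_small_sample(self):
        # differences [1, 2, 3]: t = mean / (sd / sqrt(n)) = 2 / (1/sqrt(3))
        t, p = paired_ttest([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * math.sqrt(3), abs=1e-4)
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert p == pytest.approx(0.0742, abs=1e-3)

    def test_holm_is_monotone_and_bounded(self):
        raw = {"ab": 0.01, "ac": 0.04, "bc": 0.3}
        adj = holm_correction(raw)
        assert adj["ab"] == pytest.approx(0.03)
        assert all(adj[k] >= raw[k] for k in raw)
        assert all(v <= 1.0 for v in adj.values())


class TestShapley:
    def test_single_feature_gets_full_credit(self, rng):
        X = rng.standard_normal((20, 1))
        bg = rng.standard_normal((50, 1))
        f = lambda Z: 3.0 * Z[:, 0] + 1.0  # noqa: E731
        res = shapley_attribution(f, X, background=bg)
        np.testing.assert_allclose(
            res.values[:, 0], f(X) - f(bg).mean(), atol=1e-9
        )

    def test_local_accuracy(self, rng):
        X = rng.standard_normal((10, 5))
        bg = rng.standard_normal((30, 5))
        f = lambda Z: np.sin(Z[:, 0]) + Z[:, 1] * Z[:, 2] - np.abs(Z[:, 3])  # noqa: E731
        res = shapley_attribution(f, X, background=bg)
        np.testing.assert_allclose(
            res.values.sum(axis=1) + res.base_value, f(X), atol=1e-9
        )

    def test_additive_model_recovers_components(self, rng):
        X = rng.standard_normal((40, 2))
        bg = rng.standard_normal((200, 2))
        g1 = lambda v: v**2  # noqa: E731
        g2 = lambda v: 2.0 * v  # noqa: E731
        f = lambda Z: g1(Z[:, 0]) + g2(Z[:, 1])  # noqa: E731
        res = shapley_attribution(f, X, background=bg)
        np.testing.assert_allclose(
            res.values[:, 0], g1(X[:, 0]) - g1(bg[:, 0]).mean(), atol=1e-9
        )
        np.testing.assert_allclose(
            res.values[:, 1], g2(X[:, 1]) - g2(bg[:, 1]).mean(), atol=1e-9
        )

    def test_duplicated_feature_splits_symmetrically(self, rng):
        x = rng.standard_normal((15, 1))
        X = np.hstack([x, x])
        bgx = rng.standard_normal((40, 1))
        bg = np.hstack([bgx, bgx])
        f = lambda Z: Z[:, 0] + Z[:, 1]  # noqa: E731
        res = shapley_attribution(f, X, background=bg)
        np.testing.assert_allclose(res.values[:, 0], res.values[:, 1], atol=1e-9)

    def test_sampled_path_close_to_exact(self, rng):
        X = rng.standard_normal((5, 4))
        bg = rng.standard_normal((40, 4))
        f = lambda Z: Z[:, 0] * Z[:, 1] + Z[:, 2] - 0.5 * Z[:, 3]  # noqa: E731
        exact = shapley_attribution(f, X, background=bg)
        approx = shapley_attribution(
            f, X, background=bg, max_exact=0, n_permutations=400, seed=0
        )
        assert approx.mc_error is not None
        assert np.max(np.abs(exact.values - approx.values)) < 0.35


class TestFitPredict:
    def test_permuted_target_has_no_skill(self, rng):
        X = rng.standard_normal((200, 4))
        y = X[:, 0] * 2 + rng.standard_normal(200) * 0.1
        y_perm = rng.permutation(y)
        pred, _ = fit_predict("gbt", X[:150], y_perm[:150], X[150:], seed=0)
        assert regression_metrics(y_perm[150:], pred).r2 <= 0.1

    def test_learnable_signal_is_learned(self, rng):
        X = rng.standard_normal((400, 4))
        y = 2 * X[:, 0] + X[:, 1]
        pred, _ = fit_predict("gbt", X[:300], y[:300], X[300:], seed=0)
        assert regression_metrics(y[300:], pred).r2 >= 0.9

    def test_degenerate_target_rejected(self, rng):
        X = rng.standard_normal((50, 3))
        with pytest.raises(ValueError, match="degenerate"):
            fit_predict("gbt", X, np.ones(50), X, seed=0)

    def test_svm_probabilities_shape(self, rng):
        X = rng.standard_normal((90, 3))
        y = (X[:, 0] > 0).astype(int) + (X[:, 1] > 0).astype(int)
        proba, est = fit_predict("svm", X, y, X[:10], task="classification", seed=0)
        assert proba.shape == (10, 3)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
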