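"""RF-initialized gradient boosting, cross-validation and metric formulas."""

import math

import numpy as np
import pandas as pd
import pytest

from preictal.entropy import FeatureMatrix
from preictal.model import (BoostingState, ConfusionMatrix, ModelParams,
                            cross_validate, fit_gbdt, fit_rf_init, metrics,
                            predict, sigmoid)


def make_matrix(X, y):
    frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    frame["label"] = y
    meta = pd.DataFrame({
        "segment_index": np.repeat(np.arange(max(len(y) // 60, 1)), 60)[:len(y)],
        "window_index": np.tile(np.arange(60), len(y) // 60 + 1)[:len(y)],
        "label": y,
        "start_abs_s": np.arange(len(y), dtype=float),
    })
    return FeatureMatrix(frame=frame, meta=meta)


@pytest.fixture()
def separable(rng):
    X = np.vstack([rng.normal(0, 1, (60, 4)), rng.normal(6, 1, (60, 4))])
    y = np.array([0] * 60 + [1] * 60)
    return X, y


class TestRFInit:
    def test_probability_half_maps_to_zero_score(self):
        from preictal.model import _logit
        assert _logit(np.array([0.5]))[0] == 0.0

    def test_probability_one_is_clipped_finite(self):
        from preictal.model import _logit
        h = _logit(np.array([1.0]))[0]
        assert math.isfinite(h)
        assert h == pytest.approx(math.log((1 - 1e-6) / 1e-6))

    def test_separable_scores_separate(self, separable):
        X, y = separable
        _, h0 = fit_rf_init(X, y, seed=1)
        assert h0[y == 1].min() > h0[y == 0].max()

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="class"):
            fit_rf_init(X, np.ones(10, dtype=int))


class TestGBDT:
    def test_residual_closed_form(self):
        # y = 1, H = 1 -> r = 1 - sigmoid(1) = 0.2689
        assert 1.0 - sigmoid(1.0) == pytest.approx(0.26894, abs=1e-5)

    def test_residuals_are_negative_gradients_every_round(self, separable):
        X, y = separable
        rf, h0 = fit_rf_init(X, y, seed=2)
        state = fit_gbdt(X, y, h0, ModelParams(n_rounds=5), seed=2, rf=rf,
                         keep_residuals=True)
        for t, r_t in enumerate(state.residuals):
            h_prev = state.partial_scores(X, t, h0=h0)
            assert np.allclose(r_t + sigmoid(h_prev), y, atol=1e-12)

    def test_zero_rounds_is_pure_rf(self, separable):
        X, y = separable
        rf, h0 = fit_rf_init(X, y, seed=3)
        state = fit_gbdt(X, y, h0, ModelParams(n_rounds=0), seed=3, rf=rf)
        _, proba = predict(state, X, h0=h0)
        assert np.allclose(proba, sigmoid(h0))

    def test_separable_training_accuracy_and_loss_decrease(self, separable):
        X, y = separable
        rf, h0 = fit_rf_init(X, y, seed=4)
        state = fit_gbdt(X, y, h0, ModelParams(n_rounds=50), seed=4, rf=rf)
        pred, _ = predict(state, X)
        assert (pred == y).mean() == 1.0
        assert state.train_loss[-1] < state.train_loss[0]

    def test_zero_init_is_standard_boosting_and_reproducible(self, rng):
        X = rng.standard_normal((200, 5))
        y = (X[:, 0] + 0.3 * rng.standard_normal(200) > 0).astype(int)
        a = fit_gbdt(X, y, None, ModelParams(n_rounds=30), seed=5)
        b = fit_gbdt(X, y, None, ModelParams(n_rounds=30), seed=5)
        assert a.train_loss == b.train_loss
        assert a.train_loss[-1] < a.train_loss[0]  # beats the no-learning start

    def test_non_binary_labels_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="binary"):
            fit_gbdt(X, np.arange(10), None)


class TestPredict:
    def test_tie_at_half_predicts_alarm(self, separable):
        X, y = separable
        state = fit_gbdt(X, y, None, ModelParams(n_rounds=0), seed=0)
        pred, proba = predict(state, X)
        assert np.all(proba == 0.5)
        assert np.all(pred == 1)

    def test_row_permutation_equivariance(self, separable, rng):
        X, y = separable
        rf, h0 = fit_rf_init(X, y, seed=6)
        state = fit_gbdt(X, y, h0, ModelParams(n_rounds=10), seed=6, rf=rf)
        perm = rng.permutation(len(X))
        pred, proba = predict(state, X)
        pred_p, proba_p = predict(state, X[perm])
        assert np.array_equal(pred_p, pred[perm])
        assert np.allclose(proba_p, proba[perm])

    def test_arity_mismatch_rejected(self, separable):
        X, y = separable
        state = fit_gbdt(X, y, None, ModelParams(n_rounds=1), seed=0)
        with pytest.raises(ValueError, match="features"):
            predict(state, X[:, :2])


class TestCrossValidate:
    def test_separable_data_perfect(self, separable):
        X, y = separable
        rep = cross_validate(make_matrix(X, y), k=10, seed=7)
        assert rep.mean_metrics["accuracy"] == 1.0
        assert rep.mean_metrics["fpr"] == 0.0

    def test_noise_labels_near_chance(self, rng):
        X = rng.standard_normal((600, 10))
        y = rng.integers(0, 2, 600)
        rep = cross_validate(make_matrix(X, y), k=10, seed=8)
        assert 0.35 <= rep.mean_metrics["accuracy"] <= 0.65

    def test_stratified_fold_contract(self, rng):
        X = rng.standard_normal((100, 3))
        y = np.array([0] * 50 + [1] * 50)
        from sklearn.model_selection import StratifiedKFold
        folds = list(StratifiedKFold(10, shuffle=True,
                                     random_state=0).split(X, y))
        sizes = [len(te) for _, te in folds]
        assert max(sizes) - min(sizes) <= 1
        for _, te in folds:
            assert abs(y[te].sum() - len(te) / 2) <= 1

    def test_out_of_fold_cover_every_row_once(self, separable):
        X, y = separable
        rep = cross_validate(make_matrix(X, y), k=5, seed=9)
        assert np.all(rep.oof_pred >= 0)
        assert np.all(np.isfinite(rep.oof_proba))

    def test_determinism(self, separable):
        X, y = separable
        a = cross_validate(make_matrix(X, y), k=5, seed=10)
        b = cross_validate(make_matrix(X, y), k=5, seed=10)
        assert a.mean_metrics == b.mean_metrics
        assert np.array_equal(a.oof_pred, b.oof_pred)

    def test_group_by_segment_keeps_segments_whole(self, rng):
        X = rng.standard_normal((240, 4))
        y = np.repeat([1, 0, 1, 0], 60)
        fm = make_matrix(X, y)
        rep = cross_validate(fm, k=2, seed=11, group_by_segment=True)
        assert np.all(rep.oof_pred >= 0)


class TestMetrics:
    def test_worked_example(self):
        got = metrics(ConfusionMatrix(tp=3, tn=4, fp=1, fn=2))
        assert got["accuracy"] == pytest.approx(0.7)
        assert got["sensitivity"] == pytest.approx(0.6)
        assert got["fpr"] == pytest.approx(0.2)
        assert got["f1"] == pytest.approx(2 / 3)

    def test_perfect_classifier(self):
        got = metrics(ConfusionMatrix(tp=10, tn=10, fp=0, fn=0))
        assert (got["accuracy"], got["sensitivity"], got["fpr"],
                got["f1"]) == (1.0, 1.0, 0.0, 1.0)

    def test_zero_denominator_sentinel(self):
        got = metrics(ConfusionMatrix(tp=0, tn=5, fp=1, fn=0))
        assert math.isnan(got["sensitivity"])
        assert got["accuracy"] == pytest.approx(5 / 6)

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, tn=0, fp=0, fn=0)
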