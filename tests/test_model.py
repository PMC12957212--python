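import math

import numpy as np
import pytest

from paircraft import (
    ClassifierConfig, FeedForwardClassifier, TrainConfig, lr_at, predict,
    train, tune_threshold,
)
from paircraft.model import bce_loss


def grid_scan_mcc(scores, labels, n_points=10_001):
    """Dense-grid brute-force threshold scan (independent of tune_threshold)."""
    from sklearn.metrics import matthews_corrcoef
    best_t, best_m = 0.0, -2.0
    for t in np.linspace(0.0, 1.0, n_points):
        calls = (np.asarray(scores) >= t).astype(int)
        if calls.min() == calls.max():
            m = 0.0
        else:
            m = matthews_corrcoef(labels, calls)
        if m > best_m + 1e-12:
            best_t, best_m = t, m
    return best_t, best_m


class TestClassifierArchitecture:
    def test_parameter_count_closed_form(self):
        clf = FeedForwardClassifier(ClassifierConfig(input_dim=2048), seed=0)
        # first hidden + three 1024x1024 hidden + single sigmoid output,
        # each with its bias vector
        expected = (2048 * 1024 + 1024) + 3 * (1024 * 1024 + 1024) + (1024 + 1)
        assert clf.n_parameters == expected == 5_248_001

    def test_output_in_unit_interval(self):
        clf = FeedForwardClassifier(
            ClassifierConfig(input_dim=6, hidden_layers=2, hidden_width=8), seed=1)
        p = clf.predict_proba(np.random.default_rng(0).normal(size=(20, 6)) * 50)
        assert np.all((p > 0) & (p < 1))

    def test_inference_deterministic_without_dropout(self):
        cfg = ClassifierConfig(input_dim=4, hidden_layers=2, hidden_width=8, dropout=0.0)
        clf = FeedForwardClassifier(cfg, seed=2)
        X = np.random.default_rng(1).normal(size=(5, 4))
        np.testing.assert_array_equal(clf.predict_proba(X), clf.predict_proba(X))

    def test_invalid_input_dim_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig(input_dim=0)

    def test_gradients_match_finite_differences(self):
        cfg = ClassifierConfig(input_dim=3, hidden_layers=1, hidden_width=4, dropout=0.0)
        clf = FeedForwardClassifier(cfg, seed=3)
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 3))
        y = rng.integers(0, 2, size=6)
        loss, grad_w, grad_b = clf.loss_and_gradients(X, y)
        eps = 1e-6
        for (i, j) in [(0, 1), (1, 2), (2, 0)]:
            clf.weights[0][i, j] += eps
            lp, _, _ = clf.loss_and_gradients(X, y)
            clf.weights[0][i, j] -= 2 * eps
            lm, _, _ = clf.loss_and_gradients(X, y)
            clf.weights[0][i, j] += eps
            assert grad_w[0][i, j] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4)


class TestLearningRateSchedule:
    CFG = TrainConfig()

    def test_stated_points(self):
        assert lr_at(4, self.CFG) == pytest.approx(5e-4)
        assert lr_at(0, self.CFG) == 0.0
        assert lr_at(50, self.CFG) == pytest.approx(0.0, abs=1e-18)
        assert lr_at(27, self.CFG) == pytest.approx(5e-4 / 2)  # cosine midpoint

    def test_continuous_and_bounded(self):
        xs = np.linspace(0, 50, 2001)
        vals = np.array([lr_at(x, self.CFG) for x in xs])
        assert np.all(vals >= 0)
        assert vals.max() == pytest.approx(5e-4)
        assert xs[np.argmax(vals)] == pytest.approx(4.0)
        assert np.max(np.abs(np.diff(vals))) < 5e-4 * 0.05  # no jumps


class TestTrainEarlyStopping:
    @staticmethod
    def _no_batches(epoch):
        return iter(())

    def _scripted(self, losses):
        cfg = ClassifierConfig(input_dim=2, hidden_layers=1, hidden_width=2, dropout=0.0)
        clf = FeedForwardClassifier(cfg, seed=0)
        dummy_val = (np.zeros((2, 2)), np.array([0, 1]))
        return train(clf, self._no_batches, dummy_val, TrainConfig(),
                     validation_loss_fn=lambda c, e: losses[e - 1])

    def test_minimum_at_35_stops_at_45(self):
        losses = [1.0 - e / 100 for e in range(1, 36)] + [0.9] * 15
        _, hist = self._scripted(losses)
        assert hist.best_epoch == 35
        assert hist.stopped_epoch == 45
        assert hist.best_validation_loss == min(losses[:45])

    def test_monotone_decrease_runs_to_max(self):
        losses = [1.0 - e / 100 for e in range(1, 51)]
        _, hist = self._scripted(losses)
        assert hist.stopped_epoch == 50 and hist.best_epoch == 50

    def test_restores_best_state_and_learns_separable_data(self):
        """On linearly separable pair features the loss falls and held-out
        accuracy is nearly perfect."""
        rng = np.random.default_rng(11)

        def sample(n):
            X = rng.normal(size=(n, 8))
            y = rng.integers(0, 2, size=n)
            X[:, 0] = np.where(y == 1, rng.uniform(0.5, 1.5, n),
                               rng.uniform(-1.5, -0.5, n))
            return X, y

        X_tr, y_tr = sample(400)
        X_val, y_val = sample(200)
        cfg = ClassifierConfig(input_dim=8, hidden_layers=2, hidden_width=16, dropout=0.0)
        clf = FeedForwardClassifier(cfg, seed=7)
        tcfg = TrainConfig(learning_rate=5e-3, max_epochs=30, warmup_epochs=2)

        def batches(epoch):
            order = np.random.default_rng(epoch).permutation(len(y_tr))
            for i in range(0, len(order), 64):
                sel = order[i:i + 64]
                yield X_tr[sel], y_tr[sel]

        clf, hist = train(clf, batches, (X_val, y_val), tcfg)
        assert hist.train_loss[-1] < hist.train_loss[0]
        acc = np.mean((clf.predict_proba(X_val) >= 0.5) == y_val)
        assert acc > 0.95
        # restored state reproduces the recorded best validation loss
        assert bce_loss(clf.predict_proba(X_val), y_val) == pytest.approx(
            hist.best_validation_loss)


class TestTuneThreshold:
    def test_perfect_separation(self):
        choice = tune_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert 0.2 < choice.t < 0.8
        assert choice.mcc_at_t == pytest.approx(1.0)

    def test_constant_scores_tie_break_to_zero(self):
        choice = tune_threshold([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert choice.t == 0.0 and choice.mcc_at_t == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="MCC undefined"):
            tune_threshold([0.1, 0.9], [1, 1])

    def test_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(13)
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        choice = tune_threshold(scores, labels)
        _, grid_mcc = grid_scan_mcc(scores, labels)
        assert choice.mcc_at_t >= grid_mcc - 1e-12

    def test_returned_mcc_is_recomputable(self):
        from paircraft import confusion, mcc
        rng = np.random.default_rng(14)
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        choice = tune_threshold(scores, labels)
        counts = confusion(labels, (scores >= choice.t).astype(int))
        assert mcc(counts) == pytest.approx(choice.mcc_at_t)


class TestPredict:
    def test_threshold_rule_uses_geq(self):
        cfg = ClassifierConfig(input_dim=2, hidden_layers=1, hidden_width=2, dropout=0.0)
        clf = FeedForwardClassifier(cfg, seed=0)
        X = np.random.default_rng(0).normal(size=(20, 2))
        scores, calls = predict(clf, X, threshold=0.5)
        np.testing.assert_array_equal(calls, (scores >= 0.5).astype(int))
        # score exactly at threshold is a positive call
        s0 = float(scores[0])
        _, calls_at = predict(clf, X, threshold=s0)
        assert calls_at[0] == 1
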