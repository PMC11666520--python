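"""Metrics, stratified folds, fixed-epoch training and CV protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmoit import (
    EncoderConfig,
    GridSpec,
    LabelVector,
    ModelSpec,
    TrainConfig,
    build_model,
    evaluate,
    grid_search,
    run_cv,
    stratified_kfold,
    train_model,
)
from dmoit.train_eval import baseline_classifiers


def manual_weighted_f1(y, p):
    """Hand confusion-matrix weighted F1 (independent oracle)."""
    total = 0.0
    for c in (0, 1):
        tp = np.sum((p == c) & (y == c))
        fp = np.sum((p == c) & (y != c))
        fn = np.sum((p != c) & (y == c))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        total += (y == c).mean() * f1
    return total


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0])
        assert evaluate(y, y) == (1.0, 1.0)

    def test_worked_confusion_example(self):
        acc, f1 = evaluate(np.array([0, 0, 1, 0]), np.array([0, 0, 1, 1]))
        assert acc == 0.75
        assert f1 == pytest.approx(0.7333, abs=1e-4)

    def test_degenerate_all_one_class(self):
        acc, f1 = evaluate(np.zeros(4, dtype=int), np.array([0, 0, 1, 1]))
        assert acc == 0.5
        assert f1 == pytest.approx(1 / 3, abs=1e-4)

    def test_matches_hand_formula_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(2, 30)
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            acc, f1 = evaluate(p, y)
            assert acc == pytest.approx(np.mean(y == p))
            assert f1 == pytest.approx(manual_weighted_f1(y, p), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0]), np.array([0, 1]))


class TestStratifiedKFold:
    def test_balanced_ten_samples_one_of_each_per_fold(self):
        y = np.array([0, 1] * 5)
        folds = stratified_kfold(y, k=5, seed=0)
        for f in range(5):
            fold_y = y[folds == f]
            assert sorted(fold_y.tolist()) == [0, 1]

    def test_partition_is_exact(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 37)
        y[:6] = 0
        y[6:12] = 1
        folds = stratified_kfold(y, k=5, seed=2)
        assert folds.min() >= 0 and folds.max() == 4
        assert np.bincount(folds).sum() == 37

    def test_same_seed_same_folds(self):
        y = np.array([0, 1] * 20)
        assert np.array_equal(stratified_kfold(y, 5, 3), stratified_kfold(y, 5, 3))

    def test_class_smaller_than_k_rejected(self):
        y = np.array([0] * 10 + [1] * 3)
        with pytest.raises(ValueError):
            stratified_kfold(y, k=5, seed=0)

    @settings(max_examples=25, deadline=None)
    @given(n0=st.integers(5, 40), n1=st.integers(5, 40), seed=st.integers(0, 100))
    def test_stratification_bound(self, n0, n1, seed):
        y = np.array([0] * n0 + [1] * n1)
        folds = stratified_kfold(y, k=5, seed=seed)
        for f in range(5):
            fold_y = y[folds == f]
            for c, nc in ((0, n0), (1, n1)):
                expected = nc / 5
                assert abs(np.sum(fold_y == c) - expected) <= 1


class TestTrainModel:
    WIDTHS = [6, 4]

    def _data(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        xs = [rng.uniform(0, 1, (n, w)) for w in self.WIDTHS]
        y = (xs[0][:, 0] > 0.5).astype(int)
        return xs, y

    def test_zero_learning_rate_leaves_weights_unchanged(self):
        xs, y = self._data()
        model = build_model(ModelSpec("m1", self.WIDTHS, EncoderConfig()), seed=1)
        before = [p.data.copy() for p in model.parameters()]
        cfg = TrainConfig(learn_rate=0.0, epochs=2, batch_size=16, average_tail=0.0)
        train_model(model, xs, y, cfg, np.arange(30))
        for b, p in zip(before, model.parameters()):
            assert np.array_equal(b, p.data)

    def test_loss_decreases_on_separable_toy(self):
        xs, y = self._data(n=60, seed=2)
        # widen the margin so the toy is cleanly separable
        xs[0][:, 0] = np.where(y == 1, 0.9, 0.1)
        model = build_model(ModelSpec("m2", self.WIDTHS, EncoderConfig(input_dropout=0.0)), seed=3)
        hist = train_model(
            model, xs, y,
            TrainConfig(epochs=50, batch_size=16, weight_decay=0.0, seed=4),
            np.arange(60),
        )
        assert hist["train_loss"][-1] < 0.5 * hist["train_loss"][0]

    def test_same_seed_identical_validation_metrics(self):
        xs, y = self._data(n=50, seed=5)
        results = []
        for _ in range(2):
            model = build_model(ModelSpec("m1", self.WIDTHS, EncoderConfig()), seed=6)
            hist = train_model(
                model, xs, y, TrainConfig(epochs=3, batch_size=16, seed=7),
                np.arange(40), np.arange(40, 50),
            )
            results.append(hist["val_f1"])
        assert results[0] == results[1]

    def test_overlapping_rows_rejected(self):
        xs, y = self._data()
        model = build_model(ModelSpec("m1", self.WIDTHS, EncoderConfig()), seed=8)
        with pytest.raises(ValueError):
            train_model(model, xs, y, TrainConfig(epochs=1), np.arange(10), np.arange(5, 15))


class TestGridSearch:
    def test_full_grid_has_324_combinations(self):
        assert sum(1 for _ in GridSpec().combinations()) == 324

    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(9)
        xs = [rng.uniform(0, 1, (40, 5))]
        y = np.array([0, 1] * 20)
        grid = GridSpec.small()
        best, table = grid_search(grid, "m2", xs, y, seed=0, epochs=2)
        assert best == next(grid.combinations())
        assert len(table) == 1 and not table["skipped"].any()

    def test_infeasible_combinations_skipped_and_logged(self):
        rng = np.random.default_rng(10)
        xs = [rng.uniform(0, 1, (40, 5))]
        y = np.array([0, 1] * 20)
        grid = GridSpec(
            learn_rate=[0.001], batch_size=[16], num_heads=[3],
            num_blocks=[1], dropout_rate=[0.1], dense_dim=[32, 33],
        )
        best, table = grid_search(grid, "m2", xs, y, seed=0, epochs=2)
        assert table["skipped"].tolist() == [True, False]
        assert best["dense_dim"] == 33


class TestRunCV:
    def test_perfect_signal_toy_every_architecture(self, margin_toy_cv):
        for arch, res in margin_toy_cv.items():
            assert res.mean_accuracy >= 0.95, f"{arch}: {res.mean_accuracy}"

    def test_cv_has_five_folds(self, margin_toy_cv):
        res = margin_toy_cv["dmoit"]
        assert len(res.accuracies) == 5 and len(res.f1s) == 5
        assert set(res.folds) == set(range(5))

    def test_label_permuted_data_near_chance(self, margin_toy):
        bundle, labels = margin_toy
        rng = np.random.default_rng(3)
        yp = rng.permutation(labels.labels)
        permuted = LabelVector(labels.sample_ids, yp)
        res = baseline_classifiers(bundle, permuted, "XGB", seed=4)
        prev = max(yp.mean(), 1 - yp.mean())
        assert abs(res.mean_accuracy - prev) <= 0.1

    def test_unknown_tag_rejected(self, margin_toy):
        bundle, labels = margin_toy
        with pytest.raises(ValueError):
            run_cv("mlp", bundle, labels)


class TestBaselines:
    def test_xgb_solves_perfect_signal_toy(self, margin_toy):
        bundle, labels = margin_toy
        res = baseline_classifiers(bundle, labels, "XGB", seed=0)
        assert res.mean_accuracy >= 0.95

    def test_protocol_matches_run_cv_interface(self, margin_toy):
        bundle, labels = margin_toy
        res = baseline_classifiers(bundle, labels, "LR", seed=1)
        assert len(res.accuracies) == 5
        assert res.predictions.shape == (bundle.n_samples,)
        assert set(res.predictions) <= {0, 1}

    def test_concatenated_width(self, margin_toy):
        bundle, _ = margin_toy
        assert bundle.concatenated().shape[1] == sum(m.n_features for m in bundle)
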