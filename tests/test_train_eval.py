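"""Hold-out split, training loop behavior, and per-class metrics."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from hear.data import WindowedDataset, normalize
from hear.losses import LossConfig
from hear.nn import build_model
from hear.train import (
    EvaluationReport,
    TrainConfig,
    evaluate,
    metrics_from_confusion,
    report_from_predictions,
    split_holdout,
    train,
)


def _dataset(y, T=12, S=2, C=2, seed=0, names=None):
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    names = names or [f"c{i}" for i in range(y.max() + 1)]
    return WindowedDataset(rng.normal(size=(len(y), T, S, C)), y, names, T, T)


class TestSplitHoldout:
    def test_train_side_takes_floor_of_fraction(self):
        ds = _dataset(np.zeros(708, dtype=int) , names=["only", "pad"])
        # need >= 2 classes? single class is fine for the split itself
        tr, va = split_holdout(ds, TrainConfig(split_fraction=0.8, seed=0))
        assert len(tr) == 566  # floor(0.8 * 708)
        assert len(va) == 142

    def test_same_seed_same_partition(self):
        y = np.repeat([0, 1, 2], 20)
        ds = _dataset(y)
        cfg = TrainConfig(seed=5)
        tr1, va1 = split_holdout(ds, cfg)
        tr2, va2 = split_holdout(ds, cfg)
        np.testing.assert_array_equal(tr1.X, tr2.X)
        np.testing.assert_array_equal(va1.y, va2.y)

    def test_disjoint_and_stratified(self):
        y = np.repeat([0, 1, 2], [50, 30, 20])
        ds = _dataset(y, seed=3)
        tr, va = split_holdout(ds, TrainConfig(split_fraction=0.8, seed=1))
        assert len(tr) + len(va) == len(ds)
        np.testing.assert_array_equal(tr.class_counts(), [40, 24, 16])
        # disjointness via unique window contents
        tr_keys = {t.tobytes() for t in tr.X}
        va_keys = {v.tobytes() for v in va.X}
        assert not tr_keys & va_keys

    def test_class_with_one_window_error(self):
        y = np.array([0, 0, 0, 1])
        with pytest.raises(ValueError, match="fewer than 2"):
            split_holdout(_dataset(y), TrainConfig())

    def test_invalid_fraction_error(self):
        with pytest.raises(ValueError):
            TrainConfig(split_fraction=1.0)


class TestTrainingLoop:
    def _separable_run(self, tiny_spec, loss, max_epochs=25):
        from hear.generate import generate_dataset, make_profiles, scenario
        profiles = make_profiles(3, seed=0, n_channels=2, noise_std=0.0,
                                 phase_jitter=0.05)
        scen = scenario("S1", majority=24, class_names=("a", "b", "c"))
        ds = generate_dataset(profiles, scen, T=12, S=2, seed=0)
        cfg = TrainConfig(learning_rate=2e-3, batch_size=16,
                          max_epochs=max_epochs, patience=max_epochs, seed=0)
        tr, va = split_holdout(ds, cfg)
        tr, stats = normalize(tr, "fit")
        va, _ = normalize(va, stats)
        model = build_model(tiny_spec, seed=0)
        history = train(model, tr, va, loss=loss, cfg=cfg)
        return model, history, va

    def test_learns_noise_free_separable_classes(self, tiny_spec):
        model, history, va = self._separable_run(tiny_spec, LossConfig())
        assert history["train_accuracy"].iloc[-1] >= 0.99

    def test_history_bounded_by_max_epochs(self, tiny_spec):
        _, history, _ = self._separable_run(
            tiny_spec, LossConfig.cross_entropy(), max_epochs=4)
        assert len(history) <= 4
        assert list(history.columns) == [
            "epoch", "train_loss", "train_accuracy", "val_loss", "val_accuracy"]

    def test_loss_decreases_from_first_epoch(self, tiny_spec):
        _, history, _ = self._separable_run(tiny_spec, LossConfig())
        assert history["train_loss"].iloc[-1] < history["train_loss"].iloc[0]

    def test_shape_mismatch_error(self, tiny_spec):
        model = build_model(tiny_spec, seed=0)
        bad = _dataset(np.repeat([0, 1, 2], 4), T=10)
        with pytest.raises(ValueError):
            train(model, bad, bad, cfg=TrainConfig(max_epochs=1))


class TestEvaluate:
    def test_perfect_predictions_score_one(self):
        y = np.repeat([0, 1, 2], 5)
        rep = report_from_predictions(y, y, ["a", "b", "c"])
        assert rep.accuracy == 1.0
        np.testing.assert_array_equal(rep.precision, 1.0)
        np.testing.assert_array_equal(rep.recall, 1.0)
        np.testing.assert_array_equal(rep.f1, 1.0)

    def test_constant_predictor_on_balanced_seven_classes(self):
        y = np.repeat(np.arange(7), 10)
        rep = report_from_predictions(y, np.zeros_like(y), list("abcdefg"))
        assert rep.accuracy == pytest.approx(1 / 7)

    def test_hand_computed_two_class_confusion(self):
        """[[50, 10], [5, 35]]: precision 50/55, recall 50/60 for class 1."""
        p, r, f1 = metrics_from_confusion(np.array([[50, 10], [5, 35]]))
        assert p[0] == pytest.approx(50 / 55)
        assert r[0] == pytest.approx(50 / 60)
        assert f1[0] == pytest.approx(2 * (50/55) * (50/60) / (50/55 + 50/60))

    def test_confusion_rows_sum_to_support(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 4, 100)
        pred = rng.integers(0, 4, 100)
        rep = report_from_predictions(y, pred, list("abcd"))
        np.testing.assert_array_equal(
            rep.confusion.sum(axis=1), np.bincount(y, minlength=4))

    def test_absent_class_flagged_with_zero_recall(self):
        y = np.array([0, 0, 1, 1])
        pred = np.array([0, 2, 1, 1])
        rep = report_from_predictions(y, pred, ["a", "b", "c"])
        assert rep.recall[2] == 0.0
        assert any("absent" in w for w in rep.warnings)

    def test_macro_metrics_match_sklearn_oracle(self):
        """Independent cross-check of the confusion-matrix arithmetic on
        random prediction sets."""
        rng = np.random.default_rng(1)
        for trial in range(20):
            M = int(rng.integers(2, 6))
            n = int(rng.integers(20, 200))
            y = rng.integers(0, M, n)
            pred = rng.integers(0, M, n)
            if len(np.unique(y)) < M:
                continue
            rep = report_from_predictions(y, pred, [str(i) for i in range(M)])
            p, r, f1, _ = precision_recall_fscore_support(
                y, pred, labels=np.arange(M), average="macro", zero_division=0)
            assert rep.macro_precision == pytest.approx(p, abs=1e-12)
            assert rep.macro_recall == pytest.approx(r, abs=1e-12)
            assert rep.macro_f1 == pytest.approx(f1, abs=1e-12)

    def test_evaluate_runs_model(self, tiny_spec):
        model = build_model(tiny_spec, seed=0)
        ds = _dataset(np.repeat([0, 1, 2], 4))
        rep = evaluate(model, ds, scenario="S1", loss_kind="focal")
        assert isinstance(rep, EvaluationReport)
        assert rep.scenario == "S1"
        assert 0.0 <= rep.accuracy <= 1.0
        assert rep.confusion.sum() == len(ds)

    def test_empty_dataset_error(self, tiny_spec):
        model = build_model(tiny_spec, seed=0)
        empty = WindowedDataset(np.empty((0, 12, 2, 2)), np.empty(0, int),
                                ["a"], 12, 12)
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, empty)

    def test_report_csv_roundtrip(self, tmp_path):
        y = np.repeat([0, 1], 10)
        rep = report_from_predictions(y, y, ["a", "b"])
        path = tmp_path / "report.csv"
        rep.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert list(df["class"]) == ["a", "b", "macro_average"]
        assert df["f1"].iloc[-1] == 1.0
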