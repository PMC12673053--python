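import math

import numpy as np
import pytest

from coughvision.training import (
    ClassifierBackend,
    PixelLogisticBackend,
    TrainConfig,
    WeightedSegmentClassifier,
    aggregate_pilot,
    compute_class_weights,
    lr_at_step,
    pilot_sweep,
    subset_sample,
    train,
)


class TestClassWeights:
    def test_direct_formula(self):
        cw = compute_class_weights(10, 90)
        assert cw.w_cough == pytest.approx(5.0)
        assert cw.w_non_cough == pytest.approx(0.5556, abs=1e-4)

    def test_balanced_classes_unit_weights(self):
        cw = compute_class_weights(50, 50)
        assert cw.w_cough == cw.w_non_cough == 1.0

    def test_full_scale_training_counts(self):
        # cough = TP+FN, non-cough = TN+FP of the full-scale training split
        cw = compute_class_weights(55645 + 292, 2274484 + 1058)
        assert cw.w_cough == pytest.approx(20.84, abs=0.01)
        assert cw.w_non_cough == pytest.approx(0.5123, abs=1e-4)

    def test_weighted_mass_conservation(self, rng):
        for _ in range(20):
            n1, n0 = rng.integers(1, 10_000, size=2)
            cw = compute_class_weights(int(n1), int(n0))
            assert cw.w_cough * n1 + cw.w_non_cough * n0 == pytest.approx(n1 + n0)

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights(0, 100)


class TestLrSchedule:
    CONFIG = TrainConfig()

    def test_peak_at_end_of_warmup(self):
        assert lr_at_step(100, 1000, self.CONFIG) == pytest.approx(5e-5)

    def test_zero_at_final_step(self):
        assert lr_at_step(1000, 1000, self.CONFIG) == pytest.approx(0.0, abs=1e-20)

    def test_half_peak_at_decay_midpoint(self):
        # decay spans [100, 1000]; its midpoint is step 550
        assert lr_at_step(550, 1000, self.CONFIG) == pytest.approx(2.5e-5)

    def test_continuous_and_non_negative(self):
        lrs = [lr_at_step(s, 500, self.CONFIG) for s in range(501)]
        assert min(lrs) >= 0
        diffs = np.abs(np.diff(lrs))
        assert diffs.max() < self.CONFIG.lr_peak  # no jumps

    def test_zero_total_steps_rejected(self):
        with pytest.raises(ValueError):
            lr_at_step(0, 0, self.CONFIG)


class ScriptedBackend(ClassifierBackend):
    """Backend whose validation scores follow a script, one entry per epoch.

    The training loop evaluates the monitor exactly once per epoch, so
    ``predict_scores`` advances the script by one entry per call.
    """

    def __init__(self, scripted_scores):
        self.scripted = scripted_scores
        self.epoch = -1
        self.restored = None

    def prepare(self, images):
        return np.asarray(images, dtype=float)

    def init(self, n_features, rng):
        self.epoch = -1

    def step_batch(self, features, y, sample_weight, lr):
        return 0.0

    def predict_scores(self, features):
        self.epoch += 1
        return np.asarray(self.scripted[min(self.epoch, len(self.scripted) - 1)])

    def get_state(self):
        return {"epoch": self.epoch}

    def set_state(self, state):
        self.restored = state["epoch"]


def _run_scripted(scripted, yv, **config_kwargs):
    backend = ScriptedBackend(scripted)
    X = np.zeros((4, 1))
    y = np.array([0, 1, 0, 1])
    Xv = np.zeros((len(yv), 1))
    config = TrainConfig(batch_size=4, **config_kwargs)
    return train(backend, X, y, Xv, yv, config, prepared=True)


class TestTrainLoop:
    def test_strictly_improving_monitor_runs_max_epochs(self):
        # validation loss falls every epoch -> no early stop
        yv = np.array([1, 0, 1, 0])
        scripted = [
            np.where(yv == 1, 0.5 + 0.015 * e, 0.5 - 0.015 * e).clip(0.01, 0.99)
            for e in range(1, 30)
        ]
        _, history = _run_scripted(
            scripted, yv, max_epochs=8, patience=3, monitor="loss"
        )
        assert len(history) == 8

    def test_flat_monitor_stops_after_patience(self):
        yv = np.array([1, 0, 1, 0])
        scripted = [np.array([0.9, 0.1, 0.9, 0.1])] * 30  # constant, perfect
        fitted, history = _run_scripted(scripted, yv, max_epochs=20, patience=5)
        # epoch 1 sets the best; epochs 2..6 bring no improvement
        assert len(history) == 6
        assert history.attrs["best_epoch"] == 1
        assert fitted.restored == 0  # state snapshot taken at epoch 1

    def test_empty_training_set_rejected(self):
        backend = PixelLogisticBackend()
        with pytest.raises(ValueError, match="empty"):
            train(backend, np.zeros((0, 4)), np.zeros(0), np.zeros((2, 4)),
                  np.array([0, 1]), TrainConfig(), prepared=True)

    def test_shared_subjects_rejected(self):
        backend = PixelLogisticBackend()
        X = np.zeros((4, 2))
        y = np.array([0, 1, 0, 1])
        with pytest.raises(ValueError, match="share subjects"):
            train(
                backend, X, y, X, y, TrainConfig(), prepared=True,
                train_subjects=np.array(["a", "a", "b", "b"]),
                val_subjects=np.array(["b", "c", "c", "c"]),
            )


def separable_images(n, seed):
    """Synthetic 224x224x3 images: positives bright in the upper band."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.integers(0, 60, size=(n, 224, 224, 3)).astype(np.uint8)
    X[y == 1, :64, :, :] += 150
    return X, y


class TestReferenceBackend:
    def test_separable_data_reaches_high_f1(self):
        X, y = separable_images(240, seed=2)
        clf = WeightedSegmentClassifier(
            lr_peak=1e-2, max_epochs=10, batch_size=64, seed=0
        )
        clf.fit(X, y)
        val_f1 = clf.history_["val_f1"].max()
        assert val_f1 > 90.0
        assert (clf.predict(X[:20]) == y[:20]).mean() > 0.9

    def test_estimator_sklearn_contract(self):
        from sklearn.base import clone

        clf = WeightedSegmentClassifier(max_epochs=3, seed=1)
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()
        clf.set_params(feature_size=14)
        assert clf.feature_size == 14

    def test_deterministic_given_seed(self):
        X, y = separable_images(120, seed=5)
        p1 = WeightedSegmentClassifier(lr_peak=1e-2, max_epochs=4, seed=3).fit(X, y).predict_proba(X)
        p2 = WeightedSegmentClassifier(lr_peak=1e-2, max_epochs=4, seed=3).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_feature_size_must_divide_input(self):
        with pytest.raises(ValueError):
            PixelLogisticBackend(feature_size=30)


class _PreparedLogistic(PixelLogisticBackend):
    def prepare(self, images):
        return np.asarray(images, dtype=np.float64)


def _pilot_data(seed, n_train=200, n_eval=60):
    rng = np.random.default_rng(seed)

    def block(n):
        y = rng.integers(0, 2, n)
        X = rng.normal(0, 1, size=(n, 8))
        X[:, 0] += 2.5 * y
        return {"X": X, "y": y}

    return {
        "train": block(n_train),
        "validation": block(n_eval),
        "test": block(n_eval),
    }


class TestPilotSweep:
    def test_two_config_mechanics_and_best_flag(self):
        data = {"a": _pilot_data(0), "b": _pilot_data(1)}
        config = TrainConfig(lr_peak=5e-2, max_epochs=6, batch_size=64, seed=0)
        sweep = pilot_sweep(data, config, backend_factory=_PreparedLogistic)
        assert list(sweep["config_id"]) == ["a", "b"]
        assert sweep["best"].sum() >= 1
        assert sweep.loc[sweep["best"], "test_f1"].iloc[0] == sweep["test_f1"].max()

    def test_identical_config_identical_rows(self):
        shared = _pilot_data(7)
        data = {"one": shared, "two": shared}
        config = TrainConfig(lr_peak=5e-2, max_epochs=4, batch_size=64, seed=0)
        sweep = pilot_sweep(data, config, backend_factory=_PreparedLogistic)
        a = sweep.drop(columns=["config_id", "best"]).iloc[0]
        b = sweep.drop(columns=["config_id", "best"]).iloc[1]
        assert a.equals(b)

    def test_pilot_uses_stronger_weight_decay(self):
        assert TrainConfig().pilot().weight_decay == 0.01
        assert TrainConfig().weight_decay == 0.001

    def test_aggregation_arithmetic(self):
        import pandas as pd

        sweep = pd.DataFrame(
            {
                "config_id": ["500_64_32", "500_64_16", "750_64_32"],
                "train_f1": [90.0, 92.0, 94.0],
                "validation_f1": [80.0, 82.0, 84.0],
                "test_f1": [70.0, 72.0, 74.0],
                "train_test_gap": [-20.0, -20.0, -20.0],
                "test_precision": [75.0, 76.0, 77.0],
                "test_recall": [65.0, 66.0, 67.0],
            }
        )
        by_dur = aggregate_pilot(sweep, "duration").set_index("group")
        assert by_dur.loc["500 ms", "test_f1"] == pytest.approx(71.0)
        by_hop = aggregate_pilot(sweep, "hop").set_index("group")
        assert by_hop.loc["50%", "test_f1"] == pytest.approx(72.0)
        assert by_hop.loc["25%", "test_f1"] == pytest.approx(72.0)
        by_frame = aggregate_pilot(sweep, "frame").set_index("group")
        assert by_frame.loc["64", "train_f1"] == pytest.approx(92.0)


class TestSubsetSample:
    def test_event_anchored_subset_shared_across_configs(self):
        rng = np.random.default_rng(0)
        n = 500
        labels = rng.integers(0, 2, n)
        events = np.where(labels == 1, rng.integers(0, 40, n), -1)
        subjects = np.repeat(["s1", "s2"], n // 2)
        m1 = subset_sample(labels, events, subjects, 0.1, seed=4)
        m2 = subset_sample(labels, events, subjects, 0.1, seed=4)
        np.testing.assert_array_equal(m1, m2)
        # every cough segment of a chosen event is kept together
        chosen = set(events[m1 & (labels == 1)])
        for ev in chosen:
            for subject in ("s1", "s2"):
                sel = (subjects == subject) & (events == ev) & (labels == 1)
                if sel.any():
                    assert m1[sel].all() or not m1[sel].any()
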