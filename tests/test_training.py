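"""Label rules, splits, loss, schedule, metrics and the training loop."""

import numpy as np
import pandas as pd
import pytest

import eegcube as ec
from eegcube.training import RepeatedEvaluation

from conftest import random_window_dataset, tiny_conv_spec


class TestBinarizeRating:
    @pytest.mark.parametrize("rating,expected", [(9.0, 1), (1.0, 0), (5.0, 0), (5.01, 1)])
    def test_threshold_rule(self, rating, expected):
        assert ec.binarize_rating(rating) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[1, 9\]"):
            ec.binarize_rating(0.5)


class TestSplitDataset:
    def test_80_20_partition(self):
        ds = random_window_dataset(100)
        train, test = ec.split_dataset(ds, 0.8, seed=0)
        assert (len(train), len(test)) == (80, 20)

    def test_same_seed_reproduces_partition(self):
        ds = random_window_dataset(50)
        a = ec.split_dataset(ds, 0.8, seed=5)
        b = ec.split_dataset(ds, 0.8, seed=5)
        assert a[0].provenance.equals(b[0].provenance)
        np.testing.assert_array_equal(a[1].tensors, b[1].tensors)

    def test_partition_is_disjoint_and_exhaustive(self):
        ds = random_window_dataset(37)
        train, test = ec.split_dataset(ds, 0.8, seed=1)
        got = sorted(
            map(tuple, pd.concat([train.provenance, test.provenance]).to_numpy())
        )
        assert got == sorted(map(tuple, ds.provenance.to_numpy()))
        assert len(train) + len(test) == 37

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            ec.split_dataset(random_window_dataset(10), 1.0, seed=0)


class TestCrossEntropyLoss:
    def test_confident_correct_prediction_is_zero(self):
        assert ec.cross_entropy_loss([1], [1.0]) == pytest.approx(0.0, abs=1e-6)

    def test_half_probability_is_ln_two(self):
        assert ec.cross_entropy_loss([1], [0.5]) == pytest.approx(np.log(2), abs=1e-9)

    def test_mean_over_batch(self):
        assert ec.cross_entropy_loss([1, 1], [1.0, 0.5]) == pytest.approx(0.3466, abs=1e-4)

    def test_permutation_invariance(self):
        y = [0, 1, 1, 0, 1]
        p = [0.2, 0.9, 0.6, 0.1, 0.7]
        assert ec.cross_entropy_loss(y, p) == pytest.approx(
            ec.cross_entropy_loss(y[::-1], p[::-1])
        )

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="zero samples"):
            ec.cross_entropy_loss([], [])

    def test_probability_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ec.cross_entropy_loss([1], [1.2])


class TestSchedule:
    def test_decay_every_ten_epochs(self):
        config = ec.TrainConfig()
        assert config.learning_rate(0) == pytest.approx(0.01)
        assert config.learning_rate(9) == pytest.approx(0.01)
        assert config.learning_rate(10) == pytest.approx(0.009)
        # 25th epoch (0-based index 24) sits in the third decade
        assert config.learning_rate(24) == pytest.approx(0.01 * 0.9 ** 2)


class TestConfusionAndMetrics:
    def test_perfect_all_high(self):
        c = ec.confusion_counts([1, 1, 1], [1, 1, 1])
        assert (c.fp, c.fn) == (0, 0)
        assert c.tp == 3

    def test_complement_predictions(self):
        c = ec.confusion_counts([0, 1, 0], [1, 0, 1])
        assert (c.tp, c.tn) == (0, 0)

    def test_worked_example(self):
        pred = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        act = [1, 1, 1, 0, 1, 1, 0, 0, 0, 0]
        c = ec.confusion_counts(pred, act)
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 1, 2, 4)
        m = ec.compute_metrics(c)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.60)
        assert m.f1 == pytest.approx(0.6667, abs=1e-4)
        assert m.accuracy == pytest.approx(0.70)
        assert m.degenerate == ()

    def test_all_correct_gives_ones(self):
        m = ec.compute_metrics(ec.confusion_counts([0, 1, 1], [0, 1, 1]))
        assert (m.recall, m.precision, m.f1, m.accuracy) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_denominator_flagged(self):
        m = ec.compute_metrics(ec.ConfusionCounts(tp=0, tn=2, fp=0, fn=3))
        assert m.precision == 0.0
        assert "precision" in m.degenerate

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ec.confusion_counts([1, 0], [1])

    def test_metric_identities_against_brute_force(self):
        """Confusion-derived metrics equal direct re-derivation from label pairs."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = rng.integers(2, 40)
            pred = rng.integers(0, 2, n)
            act = rng.integers(0, 2, n)
            c = ec.confusion_counts(pred, act)
            assert c.total == n
            m = ec.compute_metrics(c)
            assert m.accuracy == pytest.approx(np.mean(pred == act))
            pos = act == 1
            if pos.any():
                assert m.recall == pytest.approx(np.mean(pred[pos] == 1))
            if (pred == 1).any():
                assert m.precision == pytest.approx(np.mean(act[pred == 1] == 1))
            if m.precision + m.recall > 0:
                assert m.f1 == pytest.approx(
                    2 * m.precision * m.recall / (m.precision + m.recall)
                )


class TestTrainModel:
    def test_two_runs_same_seed_identical(self):
        ds = random_window_dataset(24)
        config = ec.TrainConfig(epochs=3, batch_size=8, seed=4)
        a = ec.train_model(tiny_conv_spec(), ds, "valence", config)
        b = ec.train_model(tiny_conv_spec(), ds, "valence", config)
        assert a.history["loss"].iloc[-1] == b.history["loss"].iloc[-1]
        np.testing.assert_array_equal(a.predict(ds.tensors), b.predict(ds.tensors))

    def test_history_records_loss_and_accuracy_per_epoch(self):
        ds = random_window_dataset(16)
        trained = ec.train_model(tiny_conv_spec(), ds, "arousal",
                                 ec.TrainConfig(epochs=2, batch_size=8, seed=0))
        assert list(trained.history.columns) == ["epoch", "lr", "loss", "train_accuracy"]
        assert len(trained.history) == 2
        assert (trained.history["loss"] >= 0).all()

    def test_non_binary_labels_rejected(self):
        ds = random_window_dataset(8)
        ds.labels_valence[0] = 3
        with pytest.raises(ValueError, match="binary"):
            ec.train_model(tiny_conv_spec(), ds, "valence", ec.TrainConfig(epochs=1))

    def test_predictions_are_binary(self):
        ds = random_window_dataset(12)
        trained = ec.train_model(tiny_conv_spec(), ds, "valence",
                                 ec.TrainConfig(epochs=1, seed=0))
        pred = trained.predict(ds.tensors)
        assert set(np.unique(pred)) <= {0, 1}


class TestRepeatedEvaluation:
    def test_mean_and_population_sd(self):
        per_repeat = pd.DataFrame({
            "repeat": [0, 1],
            "recall": [0.6, 0.7], "precision": [0.6, 0.7],
            "f1": [0.6, 0.7], "accuracy": [0.6, 0.7],
        })
        ev = RepeatedEvaluation(task="valence", per_repeat=per_repeat, confusions=[])
        assert ev.summary.loc["accuracy", "mean"] == pytest.approx(0.65)
        assert ev.summary.loc["accuracy", "sd"] == pytest.approx(0.05)

    def test_emits_one_confusion_matrix_per_repeat(self):
        ds = random_window_dataset(40, seed=2)
        config = ec.TrainConfig(epochs=1, repeats=3, seed=0)
        result = ec.run_repeated_evaluation(tiny_conv_spec(), ds, "valence", config)
        assert len(result.confusions) == 3
        assert len(result.per_repeat) == 3
        mat = result.confusions[0].as_matrix()
        assert mat.to_numpy().sum() == 8  # 20% of 40 windows held out

    def test_identical_invocations_identical_tables(self):
        ds = random_window_dataset(30, seed=6)
        config = ec.TrainConfig(epochs=1, repeats=2, seed=1)
        a = ec.run_repeated_evaluation(tiny_conv_spec(), ds, "valence", config)
        b = ec.run_repeated_evaluation(tiny_conv_spec(), ds, "valence", config)
        assert a.per_repeat.equals(b.per_repeat)
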