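from __future__ import annotations

import logging

import numpy as np
import pytest

from macrotraj import (
    ClassLabel,
    ModelConfig,
    build_model,
    confusion_matrix,
    evaluate,
    predict,
    train,
)
from macrotraj.classifier import ConfusionMatrix, parameter_count
from macrotraj.dataset_builder import FeatureRecord, ShapeError


def blob_records(rng, n_per_class=50, dim=10, sep=8.0, prefix="b"):
    """Three well-separated Gaussian blobs: a linearly separable toy."""
    centers = np.zeros((3, dim))
    centers[0, 0] = sep
    centers[1, 1] = sep
    centers[2, 2] = sep
    records = []
    for c, label in enumerate(ClassLabel):
        X = rng.normal(0, 1.0, size=(n_per_class, dim)) + centers[c]
        records += [
            FeatureRecord(f"{prefix}{c}_{i}", X[i], label)
            for i in range(n_per_class)
        ]
    return records


class TestBuildModel:
    def test_parameter_count_matches_closed_form(self):
        config = ModelConfig()
        sizes = (76, 10, 20, 32, 64, 64, 32, 20, 10, 3)
        expected = sum(a * b + b for a, b in zip(sizes, sizes[1:]))
        model = build_model(config, 76)
        actual = sum(w.size for w in model.weights) + sum(
            b.size for b in model.biases
        )
        assert actual == expected == parameter_count(76, config)

    def test_output_is_a_probability_distribution(self, rng):
        model = build_model(ModelConfig(), 76)
        P = model.predict_proba(rng.normal(0, 50, size=(20, 76)))
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-6)
        assert (P >= 0).all()

    def test_same_seed_gives_identical_initial_predictions(self, rng):
        X = rng.normal(size=(5, 76))
        a = build_model(ModelConfig(seed=3), 76).predict_proba(X)
        b = build_model(ModelConfig(seed=3), 76).predict_proba(X)
        np.testing.assert_array_equal(a, b)

    def test_unknown_input_dim_rejected(self):
        with pytest.raises(ValueError):
            build_model(ModelConfig(), 0)


class TestTrain:
    def test_separable_blobs_reach_high_training_accuracy(self, rng):
        records = blob_records(rng)
        model = build_model(ModelConfig(epochs=50, seed=0), 10)
        result = train(model, records, records)
        assert result.accuracy[-1] >= 0.99

    def test_agrees_with_sklearn_on_the_separable_toy(self, rng):
        """Independent route: sklearn's MLP on the same blobs should agree
        with our network's near-perfect separation."""
        from sklearn.neural_network import MLPClassifier

        records = blob_records(rng)
        X = np.stack([r.features for r in records])
        y = np.array([r.label.index for r in records])
        sk = MLPClassifier(hidden_layer_sizes=(16,), max_iter=800,
                           random_state=0).fit(X, y)
        model = build_model(ModelConfig(epochs=50, seed=0), 10)
        train(model, records, records)
        _, ours = predict(model, records)
        assert sk.score(X, y) >= 0.99
        assert np.mean([p.index == t for p, t in zip(ours, y)]) >= 0.99

    def test_history_lengths_equal_epochs(self, rng):
        records = blob_records(rng, n_per_class=10)
        model = build_model(ModelConfig(epochs=1, seed=0), 10)
        result = train(model, records, records)
        for series in (result.loss, result.accuracy, result.val_loss,
                       result.val_accuracy):
            assert len(series) == 1
        assert all(v >= 0 for v in result.loss)
        assert all(0 <= v <= 1 for v in result.accuracy)

    def test_same_seed_reproduces_histories_exactly(self, rng):
        records = blob_records(rng, n_per_class=15)

        def go():
            model = build_model(ModelConfig(epochs=5, seed=4), 10)
            return train(model, records, records)

        assert go().loss == go().loss

    def test_missing_class_warns_but_trains(self, rng, caplog):
        records = [r for r in blob_records(rng, n_per_class=10)
                   if r.label is not ClassLabel.M2]
        model = build_model(ModelConfig(epochs=1, seed=0), 10)
        with caplog.at_level(logging.WARNING):
            train(model, records, records)
        assert any("M2" in rec.message for rec in caplog.records)

    def test_feature_length_mismatch_rejected(self, rng):
        records = blob_records(rng, n_per_class=5)
        model = build_model(ModelConfig(epochs=1, seed=0), 76)
        with pytest.raises(ShapeError):
            train(model, records, records)


class TestPredict:
    def test_probabilities_sum_to_one(self, rng):
        records = blob_records(rng, n_per_class=5)
        model = build_model(ModelConfig(seed=0), 10)
        probs, labels = predict(model, records)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert len(labels) == len(records)

    def test_argmax_label_and_tie_break(self):
        probs = np.array([[0.2, 0.2, 0.6], [0.4, 0.4, 0.2], [0.3, 0.4, 0.3]])
        classes = list(ClassLabel)
        picked = [classes[i] for i in probs.argmax(axis=1)]
        assert picked == [ClassLabel.M2, ClassLabel.M0, ClassLabel.M1]

    def test_overfit_toy_recovers_training_labels(self, rng):
        records = blob_records(rng, n_per_class=30)
        model = build_model(ModelConfig(epochs=60, seed=1), 10)
        train(model, records, records)
        _, labels = predict(model, records)
        assert all(p is r.label for p, r in zip(labels, records))


class TestConfusionMatrix:
    def test_perfect_predictions_give_identity_pattern(self):
        labels = [ClassLabel.M0] * 4 + [ClassLabel.M1] * 5 + [ClassLabel.M2] * 6
        cm = confusion_matrix(labels, labels)
        np.testing.assert_allclose(np.diag(cm.percent), 100.0)
        assert cm.overall_accuracy == 1.0

    def test_constant_classifier_fills_first_column(self):
        labels = [ClassLabel.M0, ClassLabel.M1, ClassLabel.M2] * 3
        cm = confusion_matrix(labels, [ClassLabel.M0] * 9)
        np.testing.assert_allclose(cm.percent[:, 0], 100.0)

    def test_row_normalization_worked_example(self):
        counts = np.array([[87, 2, 11], [0, 1, 0], [0, 0, 1]])
        cm = ConfusionMatrix(counts)
        np.testing.assert_allclose(cm.percent[0], [87.0, 2.0, 11.0])

    def test_rows_sum_to_100(self, rng):
        true = [list(ClassLabel)[i] for i in rng.integers(0, 3, 60)]
        pred = [list(ClassLabel)[i] for i in rng.integers(0, 3, 60)]
        cm = confusion_matrix(true, pred)
        np.testing.assert_allclose(cm.percent.sum(axis=1), 100.0)


class TestEvaluate:
    def test_empty_validation_rejected(self, rng):
        model = build_model(ModelConfig(seed=0), 10)
        with pytest.raises(ValueError):
            evaluate(model, [])

    def test_evaluate_on_overfit_toy_is_diagonal(self, rng):
        records = blob_records(rng, n_per_class=20)
        model = build_model(ModelConfig(epochs=60, seed=0), 10)
        train(model, records, records)
        cm, acc = evaluate(model, records)
        assert acc == 1.0
        np.testing.assert_allclose(np.diag(cm.percent), 100.0)


class TestSeparationMonotonicity:
    def test_validation_accuracy_degrades_with_class_overlap(self):
        """As the three simulated motility modes converge toward a common
        random walk, leakage-free (group-aware) validation accuracy falls."""
        import macrotraj as mt

        levels = [
            {},  # shipped defaults: well separated
            dict(
                spinner=mt.SpinnerParams(radius=2.0, positional_noise_sd=0.8),
                jumper=mt.JumperParams(jump_prob=0.12, jump_len_min=3,
                                       jump_len_max=6, confinement=0.05),
                mover=mt.MoverParams(step_length=1.0, heading_sd=1.2),
            ),
            dict(
                spinner=mt.SpinnerParams(radius=0.8, positional_noise_sd=1.0,
                                         angular_step=2.0),
                jumper=mt.JumperParams(jump_prob=0.02, small_step_sd=1.0,
                                       jump_len_min=1.5, jump_len_max=2.5,
                                       confinement=0.0),
                mover=mt.MoverParams(step_length=1.0, heading_sd=2.5),
            ),
        ]
        accs = []
        for kw in levels:
            cfg = mt.SimConfig(n_per_class=30, seed=0, **kw)
            tracks = mt.generate_labeled_dataset(cfg)
            records = mt.build_dataset(mt.augment_trackset(tracks))
            split = mt.shuffle_split(records, 0.8, seed=0,
                                     group_by_origin=True)
            model = build_model(ModelConfig(epochs=40, seed=0), 76)
            train(model, split.train, split.validation)
            _, acc = evaluate(model, split.validation)
            accs.append(acc)
        assert accs[0] > accs[1] > accs[2]
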