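"""Training protocol: epoch arithmetic, presets, estimator behaviour and
a seeded learning smoke test."""

import numpy as np
import pytest
from sklearn.base import clone

from ecgtcn import (TCNClassifier, TrainingConfig, experiment_preset,
                    generate_dataset, iterations_per_epoch, make_split,
                    total_iterations, total_param_count, train)
from ecgtcn.ecg5000 import TRAIN_COUNTS_AFTER


class TestEpochArithmetic:
    def test_published_training_size_gives_460_iterations(self):
        n = sum(TRAIN_COUNTS_AFTER.values())
        assert n == 9204
        assert iterations_per_epoch(n, 20) == 460

    def test_total_iterations_115000(self):
        assert total_iterations(9204, 20, 250) == 115000

    def test_partial_batch_dropped(self):
        assert iterations_per_epoch(99, 20) == 4

    def test_invalid_batch_size(self):
        with pytest.raises(ValueError):
            iterations_per_epoch(100, 0)


class TestPresets:
    def test_headline_preset_fields(self):
        pre = experiment_preset("1")
        assert len(pre.spec.blocks) == 4
        assert pre.spec.n_filters == 16
        assert pre.spec.kernel_sizes == (2, 4, 6, 8)
        assert pre.plan.fold_increase() == {3: 24, 4: 12, 5: 24}
        cfg = pre.config
        assert (cfg.learning_rate, cfg.batch_size, cfg.epochs,
                cfg.dropout) == (0.0025, 20, 250, 0.3)

    def test_preset_4_parameter_total(self):
        assert total_param_count(experiment_preset("4").spec).kilo_label == "2.7 K"

    def test_preset_11_differs_only_in_sp_fold(self):
        p1, p11 = experiment_preset("1"), experiment_preset("11")
        assert p1.spec == p11.spec
        assert p11.plan.fold_increase()[4] == 24

    def test_preset_12_sp_fold_6(self):
        assert experiment_preset("12").plan.fold_increase()[4] == 6

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="preset"):
            experiment_preset("13")


class TestTrainingConfig:
    def test_defaults_match_protocol(self):
        cfg = TrainingConfig()
        assert cfg.learning_rate == 0.0025
        assert (cfg.batch_size, cfg.epochs, cfg.dropout) == (20, 250, 0.3)
        assert cfg.adam_betas == (0.9, 0.999)

    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            TrainingConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainingConfig(selection="magic")


def _two_class_toy(n=200, seed=0):
    props = {1: 0.5, 3: 0.5}
    full = generate_dataset(n, props, seed=seed, noise_sd=0.02)
    return make_split(full, 0.9, seed=seed)


class TestEstimator:
    def test_sklearn_params_roundtrip(self):
        clf = TCNClassifier(n_blocks=2, kernel_sizes=(2, 3), epochs=3)
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()

    def test_two_class_toy_learns_above_90_percent(self):
        """n=200 low-noise 2-class fixture, 5 epochs."""
        tr, te = _two_class_toy()
        clf = TCNClassifier(n_blocks=2, n_filters=8, kernel_sizes=(2, 4),
                            epochs=5, random_state=0)
        clf.fit(tr.X, tr.y, eval_set=(te.X, te.y))
        assert (clf.predict(te.X) == te.y).mean() > 0.9
        proba = clf.predict_proba(te.X)
        np.testing.assert_allclose(proba.sum(1), 1.0, atol=1e-6)

    def test_loss_decreases_early(self):
        """Median first-to-last training loss over 3 seeds falls in 5 epochs."""
        drops = []
        for seed in (0, 1, 2):
            tr, te = _two_class_toy(seed=seed)
            clf = TCNClassifier(n_blocks=2, n_filters=8, kernel_sizes=(2, 4),
                                epochs=5, random_state=seed)
            clf.fit(tr.X, tr.y, eval_set=(te.X, te.y))
            drops.append(clf.history_.train_loss[0] - clf.history_.train_loss[-1])
        assert np.median(drops) > 0

    def test_selected_weights_reproduce_minimum_monitor_loss(self):
        tr, te = _two_class_toy()
        clf = TCNClassifier(n_blocks=2, n_filters=8, kernel_sizes=(2, 4),
                            epochs=5, random_state=1)
        clf.fit(tr.X, tr.y, eval_set=(te.X, te.y))
        hist = clf.history_
        assert hist.selected_epoch == int(np.argmin(hist.monitor_loss))
        class_index = {c: i for i, c in enumerate(clf.classes_)}
        y_idx = np.array([class_index[c] for c in te.y])
        loss, _ = clf._evaluate(te.X, y_idx)
        assert loss == pytest.approx(min(hist.monitor_loss), abs=1e-9)

    def test_history_arithmetic_invariants(self):
        tr, te = _two_class_toy()
        clf = TCNClassifier(n_blocks=1, n_filters=4, kernel_sizes=(2,),
                            epochs=2, random_state=0)
        clf.fit(tr.X, tr.y, eval_set=(te.X, te.y))
        hist = clf.history_
        assert hist.iterations_per_epoch == len(tr) // 20
        assert hist.total_iterations == hist.iterations_per_epoch * 2
        assert 0 <= hist.selected_epoch < hist.n_epochs

    def test_same_seed_same_model(self):
        tr, te = _two_class_toy()
        outs = []
        for _ in range(2):
            clf = TCNClassifier(n_blocks=1, n_filters=4, kernel_sizes=(2,),
                                epochs=2, random_state=5)
            clf.fit(tr.X, tr.y, eval_set=(te.X, te.y))
            outs.append(clf.predict_proba(te.X))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            TCNClassifier(epochs=1).fit(np.zeros((30, 140)), np.ones(30))

    def test_eval_set_with_unseen_label_rejected(self):
        tr, te = _two_class_toy()
        clf = TCNClassifier(n_blocks=1, n_filters=4, kernel_sizes=(2,), epochs=1)
        with pytest.raises(ValueError, match="unseen"):
            clf.fit(tr.X, tr.y, eval_set=(te.X, np.full(len(te), 9)))


class TestFunctionalWrapper:
    def test_train_wraps_estimator(self):
        tr, te = _two_class_toy()
        pre = experiment_preset("1", seed=0)
        cfg = TrainingConfig(epochs=2, seed=0)
        from ecgtcn import TCNSpec

        spec = TCNSpec.build(1, 4, (2,))
        clf, hist = train(spec, cfg, tr, te)
        assert hist.n_epochs == 2
        assert clf.history_ is hist

    def test_empty_dataset_rejected(self):
        from ecgtcn import HeartbeatDataset, TCNSpec

        empty = HeartbeatDataset(np.empty((0, 140)), np.empty(0))
        tr, te = _two_class_toy()
        with pytest.raises(ValueError, match="non-empty"):
            train(TCNSpec.build(1, 4, (2,)), TrainingConfig(epochs=1), tr, empty)
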