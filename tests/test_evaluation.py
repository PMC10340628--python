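"""Evaluation protocol: folds, SVM grid search, deep training, metrics."""

import numpy as np
import pytest

from pdscreen.cohort import CohortSpec, gen_cohort
from pdscreen.evaluation import (EarlyStopping, ExperimentConfig, ListDataset,
                                 SVMConfig, TrainConfig, compute_metrics,
                                 desk_scale_text_train_config, run_experiment,
                                 speaker_folds, svm_fit_predict, train_deep)
from pdscreen.text import NgramCNN, NgramCNNConfig


def _labels(n_pd=20, n_hc=20):
    return {f"PD{i}": "PD" for i in range(n_pd)} | {f"HC{i}": "HC" for i in range(n_hc)}


class TestSpeakerFolds:
    def test_balanced_cohort_splits_two_per_class(self):
        plan = speaker_folds(_labels(), k=10, seed=0)
        labels = _labels()
        for fold in range(10):
            _, test = plan.fold_speakers(fold)
            assert len(test) == 4
            assert sum(labels[s] == "PD" for s in test) == 2

    def test_partition_property(self):
        plan = speaker_folds(_labels(), k=10, seed=0)
        for fold in range(10):
            train, test = plan.fold_speakers(fold)
            assert not set(train) & set(test)
            assert sorted(train + test) == sorted(_labels())

    def test_fold_sizes_differ_by_at_most_one(self):
        plan = speaker_folds(_labels(11, 12), k=5, seed=1)
        sizes = np.bincount(list(plan.assignments.values()), minlength=5)
        assert sizes.max() - sizes.min() <= 1

    def test_seed_controls_assignment(self):
        a = speaker_folds(_labels(), k=10, seed=3).assignments
        b = speaker_folds(_labels(), k=10, seed=3).assignments
        c = speaker_folds(_labels(), k=10, seed=4).assignments
        assert a == b
        assert a != c

    def test_fewer_speakers_than_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            speaker_folds(_labels(2, 2), k=10, seed=0)


class TestSVM:
    def test_grid_has_42_candidates(self):
        cfg = SVMConfig()
        assert len(cfg.C_grid) * len(cfg.gamma_grid) == 42

    def test_separable_blobs_reach_perfect_training_accuracy(self, rng):
        X = np.vstack([rng.standard_normal((20, 2)),
                       rng.standard_normal((20, 2)) + 8.0])
        y = np.array([0] * 20 + [1] * 20)
        scores, (C, gamma) = svm_fit_predict(X, y, X, seed=0)
        assert ((scores >= 0.5).astype(int) == y).all()
        assert C in SVMConfig().C_grid and gamma in SVMConfig().gamma_grid

    def test_single_class_training_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="single-class"):
            svm_fit_predict(X, np.ones(10), X)


class TestEarlyStopping:
    def test_strict_improvement_never_stops(self):
        es = EarlyStopping(patience=40)
        for epoch in range(1, 201):
            assert es.update(1.0 / epoch, epoch)
            assert not es.should_stop

    def test_frozen_loss_stops_after_patience(self):
        es = EarlyStopping(patience=40)
        stopped_at = None
        for epoch in range(1, 201):
            es.update(1.0, epoch)
            if es.should_stop:
                stopped_at = epoch
                break
        assert stopped_at == 41
        assert es.best_epoch == 1


def _separable_text_data(rng, n=24, d=6):
    """Two token-matrix classes with shifted row means."""
    Ms, ys = [], []
    for i in range(n):
        y = i % 2
        shift = 1.5 if y else -1.5
        Ms.append(rng.standard_normal((int(rng.integers(5, 12)), d)) + shift)
        ys.append(y)
    return ListDataset(Ms, ys)


class TestTrainDeep:
    def test_empty_validation_rejected(self, rng):
        m = NgramCNN(NgramCNNConfig(d=6, filters=4))
        ds = _separable_text_data(rng)
        with pytest.raises(ValueError, match="validation"):
            train_deep(m, ds, ListDataset([], []), TrainConfig())

    def test_separable_data_fits_to_high_accuracy(self, rng):
        train = _separable_text_data(rng)
        val = _separable_text_data(rng, n=8)
        cfg = TrainConfig(epochs=60, early_stopping_patience=15,
                          dropout_grid=(0.0,), l2_grid=(1e-4,), seed=0)
        m, hist = train_deep(NgramCNN(NgramCNNConfig(d=6, filters=4, seed=1)),
                             train, val, cfg)
        preds = m.predict_proba(train.items).argmax(axis=1)
        assert (preds == train.y).mean() >= 0.95
        assert hist["stopped_epoch"] <= 60

    def test_zero_learning_rate_stops_at_patience_plus_one(self, rng):
        train = _separable_text_data(rng)
        val = _separable_text_data(rng, n=8)
        cfg = TrainConfig(epochs=50, early_stopping_patience=4, lr=0.0,
                          dropout_grid=(0.0,), l2_grid=(0.0,), seed=0)
        _, hist = train_deep(NgramCNN(NgramCNNConfig(d=6, filters=4, seed=1)),
                             train, val, cfg)
        assert hist["stopped_epoch"] == 5
        assert hist["best_epoch"] == 1

    def test_hyperparameters_selected_from_grids(self, rng):
        train = _separable_text_data(rng, n=16)
        val = _separable_text_data(rng, n=8)
        cfg = TrainConfig(epochs=4, early_stopping_patience=2,
                          dropout_grid=(0.0, 0.4), l2_grid=(1e-4, 5e-3), seed=0)
        _, hist = train_deep(NgramCNN(NgramCNNConfig(d=6, filters=4, seed=1)),
                             train, val, cfg)
        assert hist["dropout"] in cfg.dropout_grid
        assert hist["l2"] in cfg.l2_grid


class TestComputeMetrics:
    def test_confusion_matrix_arithmetic(self):
        # TP=4, TN=4, FP=1, FN=1
        scores = [0.9] * 4 + [0.1] + [0.1] * 4 + [0.9]
        labels = [1] * 5 + [0] * 5
        m = compute_metrics(scores, labels)
        assert m == {"accuracy": 80.0, "sensitivity": 80.0,
                     "specificity": 80.0, "f1": 80.0}

    def test_perfect_scores(self):
        m = compute_metrics([1.0, 1.0, 0.0], [1, 1, 0])
        assert all(v == 100.0 for v in m.values())

    def test_threshold_tie_counts_as_positive(self):
        m = compute_metrics([0.5, 0.5], [1, 0])
        assert m["sensitivity"] == 100.0 and m["specificity"] == 0.0

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_metrics([0.5, 0.6], [1, 1])

    def test_metric_identities(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        if labels.all() or not labels.any():
            labels[0] = 1 - labels[0]
        m = compute_metrics(scores, labels)
        pred = (scores >= 0.5).astype(int)
        acc = 100.0 * (pred == labels).mean()
        assert abs(m["accuracy"] - acc) < 1e-12
        tp = ((pred == 1) & (labels == 1)).sum()
        fp = ((pred == 1) & (labels == 0)).sum()
        fn = ((pred == 0) & (labels == 1)).sum()
        if tp + fp > 0 and tp > 0:
            prec = tp / (tp + fp)
            rec = tp / (tp + fn)
            assert abs(m["f1"] - 100.0 * 2 * prec * rec / (prec + rec)) < 1e-9


class TestRunExperiment:
    def test_unknown_branch_rejected_at_startup(self, small_cohort):
        with pytest.raises(ValueError, match="unknown branch"):
            run_experiment(small_cohort, ExperimentConfig(branch="nope"))

    def test_report_structure_and_aggregate_recompute(self, small_cohort):
        cfg = ExperimentConfig(branch="text_functionals", n_folds=3, seed=5)
        rep = run_experiment(small_cohort, cfg)
        assert len(rep.folds) == 3
        assert sum(len(f.test_speakers) for f in rep.folds) == 12
        for metric, (mean, std) in rep.aggregate.items():
            vals = np.array([f.metrics[metric] for f in rep.folds])
            assert mean == pytest.approx(vals.mean(), abs=1e-12)
            assert std == pytest.approx(vals.std(), abs=1e-12)
        table = rep.score_table()
        assert len(table) == 12
        assert table["score"].between(0, 1).all()

    def test_identical_config_reproduces_report_exactly(self, small_cohort):
        cfg = ExperimentConfig(branch="text_ngram", n_folds=3, seed=5,
                               train=desk_scale_text_train_config(5))
        r1 = run_experiment(small_cohort, cfg)
        r2 = run_experiment(small_cohort, cfg)
        assert r1.to_dict() == r2.to_dict()
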