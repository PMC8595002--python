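import numpy as np
import pytest

from mieeg import (
    BaseLearnerSpec,
    ConfusionCounts,
    FeatureMatrix,
    RandomSubspaceConfig,
    RotationForestConfig,
    ValidationError,
    accuracy,
    auc,
    confusion_from_predictions,
    cross_validate,
    f_measure,
    run_experiment_grid,
    summarize_reports,
    tpr_fpr,
)


def brute_force_metrics(tp, tn, fp, fn):
    """Independent arithmetic oracle for the four confusion metrics."""
    acc = (tp + tn) / (tp + tn + fp + fn) * 100
    f = tp / (tp + (fp + fn) / 2) if tp + fp + fn else 0.0
    tpr = tp / (tp + fn) if tp + fn else None
    fpr = fp / (fp + tn) if fp + tn else None
    return acc, f, tpr, fpr


def brute_force_auc(scores, labels, positive=1):
    """Exhaustive pair counting: (wins + ties/2) / (n_pos * n_neg)."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_perfect(self):
        c = ConfusionCounts(5, 5, 0, 0)
        assert accuracy(c) == 100.0
        assert f_measure(c) == 1.0
        assert tpr_fpr(c) == (1.0, 0.0)

    def test_always_wrong(self):
        c = ConfusionCounts(0, 0, 3, 7)
        assert accuracy(c) == 0.0
        assert f_measure(c) == 0.0

    def test_worked_example(self):
        c = ConfusionCounts(30, 40, 10, 20)
        assert accuracy(c) == pytest.approx(70.0, abs=1e-12)
        assert tpr_fpr(c) == pytest.approx((0.6, 0.2), abs=1e-12)
        c2 = ConfusionCounts(30, 0, 10, 20)
        assert f_measure(c2) == pytest.approx(0.6667, abs=1e-4)

    def test_inverted_perfect(self):
        assert tpr_fpr(ConfusionCounts(0, 0, 5, 5)) == (0.0, 1.0)

    def test_degenerate_f_measure_warns(self):
        with pytest.warns(UserWarning):
            assert f_measure(ConfusionCounts(0, 10, 0, 0)) == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            accuracy(ConfusionCounts())

    def test_stratum_validation(self):
        with pytest.raises(ValidationError):
            tpr_fpr(ConfusionCounts(0, 5, 5, 0))  # no positives
        with pytest.raises(ValidationError):
            tpr_fpr(ConfusionCounts(5, 0, 0, 5))  # no negatives

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionCounts(tp=-1)

    def test_1000_random_tables_match_oracle(self, rng):
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 200, size=4)
            c = ConfusionCounts(int(tp), int(tn), int(fp), int(fn))
            acc_o, f_o, tpr_o, fpr_o = brute_force_metrics(tp, tn, fp, fn)
            if c.total > 0:
                assert accuracy(c) == pytest.approx(acc_o, abs=1e-12)
            if tp + fp + fn > 0:
                assert f_measure(c) == pytest.approx(f_o, abs=1e-12)
            if tpr_o is not None and fpr_o is not None:
                got = tpr_fpr(c)
                assert got[0] == pytest.approx(tpr_o, abs=1e-12)
                assert got[1] == pytest.approx(fpr_o, abs=1e-12)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 2, 2]) == 1.0

    def test_all_tied(self):
        assert auc([0.5] * 6, [1, 2, 1, 2, 1, 2]) == 0.5

    def test_example_vs_pair_counting(self):
        scores = [0.9, 0.8, 0.4, 0.3]
        labels = [1, 2, 1, 2]
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    def test_100_random_vectors_match_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 60))
            labels = rng.integers(1, 3, size=n)
            if len(set(labels)) < 2:
                labels[0], labels[1] = 1, 2
            # quantized scores force plenty of ties
            scores = np.round(rng.random(n), 1)
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auc([0.1, 0.2], [1, 1])


def _random_features(n, seed=0, subjects=("A",)):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 95))
    y = np.array([1, 2] * (n // 2))
    subj = [subjects[i % len(subjects)] for i in range(n)]
    return FeatureMatrix(X, y, subj)


def _leaky_features(n, seed=0):
    fm = _random_features(n, seed)
    fm.values[:, 0] = fm.labels  # label leaked into a feature
    return fm


class TestCrossValidate:
    def test_stratified_fold_sizes(self):
        fm = _random_features(200, seed=1)
        rep = cross_validate(fm, BaseLearnerSpec("knn"), None, n_folds=10,
                             seed=0)
        for c in rep.per_fold:
            assert c.total == 20
            assert c.tp + c.fn == 10  # positives per fold
            assert c.fp + c.tn == 10

    def test_oracle_classifier_is_perfect(self):
        fm = _leaky_features(100)
        rep = cross_validate(fm, BaseLearnerSpec("rep_tree"), None,
                             n_folds=5, seed=0)
        assert rep.accuracy == 100.0
        assert rep.auc == 1.0

    def test_determinism(self):
        fm = _leaky_features(60)
        a = cross_validate(fm, BaseLearnerSpec("random_tree"),
                           RandomSubspaceConfig(n_members=3, seed=0),
                           n_folds=5, seed=3)
        b = cross_validate(fm, BaseLearnerSpec("random_tree"),
                           RandomSubspaceConfig(n_members=3, seed=0),
                           n_folds=5, seed=3)
        assert a.to_dict() == b.to_dict()

    def test_pooled_accuracy_equals_weighted_fold_mean(self):
        fm = _random_features(110, seed=2)
        rep = cross_validate(fm, BaseLearnerSpec("knn"), None, n_folds=10,
                             seed=1)
        weighted = sum(accuracy(c) * c.total for c in rep.per_fold) \
            / sum(c.total for c in rep.per_fold)
        assert rep.accuracy == pytest.approx(weighted, abs=1e-9)

    def test_folds_partition_indices(self):
        # disjointness/coverage via a counting classifier wrapper is
        # equivalent to: every instance is scored exactly once
        fm = _random_features(80, seed=3)
        rep = cross_validate(fm, BaseLearnerSpec("knn"), None, n_folds=8,
                             seed=0)
        assert sum(c.total for c in rep.per_fold) == 80

    def test_class_too_small(self):
        fm = _random_features(10)
        with pytest.raises(ValidationError):
            cross_validate(fm, BaseLearnerSpec("knn"), None, n_folds=10,
                           seed=0)


class TestExperimentGrid:
    def test_cell_count(self):
        fm = _leaky_features(120, seed=4)
        fm.subject_ids = ["S1"] * 60 + ["S2"] * 60
        fm.labels = np.array([1, 2] * 60)
        reports = run_experiment_grid(
            fm,
            [BaseLearnerSpec("knn"), BaseLearnerSpec("rep_tree")],
            {"rsm": RandomSubspaceConfig(n_members=3, seed=0),
             "rof": RotationForestConfig(n_members=3, seed=0)},
            n_folds=5, seed=0)
        # 2 ensembles x 2 bases x (2 subjects + ALL) = 12 cells
        assert len(reports) == 12
        subjects = {r.subject for r in reports}
        assert subjects == {"S1", "S2", "ALL"}
        assert all(not r.skipped for r in reports)

    def test_small_subject_skipped_not_fatal(self):
        fm = _leaky_features(104, seed=5)
        fm.subject_ids = ["S1"] * 100 + ["tiny"] * 4
        reports = run_experiment_grid(
            fm, [BaseLearnerSpec("knn")],
            {"rsm": RandomSubspaceConfig(n_members=3, seed=0)},
            n_folds=10, seed=0)
        tiny = [r for r in reports if r.subject == "tiny"]
        assert len(tiny) == 1 and tiny[0].skipped
        assert all(not r.skipped for r in reports if r.subject != "tiny")

    def test_summary_table_shape(self):
        fm = _leaky_features(60, seed=6)
        reports = run_experiment_grid(
            fm, [BaseLearnerSpec("knn")],
            {"rsm": RandomSubspaceConfig(n_members=3, seed=0)},
            n_folds=5, seed=0)
        df = summarize_reports(reports)
        assert set(df.columns) >= {"subject", "classifier", "accuracy",
                                   "f_measure", "auc"}
        assert len(df) == len(reports)


def test_confusion_from_predictions():
    c = confusion_from_predictions([1, 1, 2, 2, 1], [1, 2, 2, 1, 1])
    assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 1, 1)
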