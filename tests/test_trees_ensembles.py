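import numpy as np
import pytest

from mieeg import (
    BaseLearnerSpec,
    RandomSubspaceConfig,
    RotationForestConfig,
    ValidationError,
    load_model,
    save_model,
    train_base,
    train_random_subspace,
    train_rotation_forest,
)
from mieeg.ensembles import predict
from mieeg.trees import DecisionTree


class TestBaseLearners:
    def test_1nn_self_classification(self, blob_data):
        X, y = blob_data
        clf = train_base(BaseLearnerSpec("knn"), (X, y), seed=0)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_svm_separable_blobs(self, blob_data):
        X, y = blob_data
        clf = train_base(BaseLearnerSpec("svm"), (X, y), seed=0)
        rng = np.random.default_rng(1)
        X_test = rng.normal(size=(40, 95))
        X_test[:20, :5] += 8.0
        y_test = np.array([1] * 20 + [2] * 20)
        assert np.mean(clf.predict(X_test) == y_test) == 1.0

    def test_rep_tree_pruning_shrinks(self, rng):
        X = rng.normal(size=(200, 10))
        y = ((X[:, 0] > 0) ^ (rng.random(200) < 0.2)).astype(int) + 1
        clf = train_base(BaseLearnerSpec("rep_tree"), (X, y), seed=0)
        assert clf.n_nodes_ <= clf.n_nodes_pre_prune_

    def test_c45_pruning_shrinks(self, rng):
        X = rng.normal(size=(200, 10))
        y = ((X[:, 0] > 0) ^ (rng.random(200) < 0.25)).astype(int) + 1
        clf = train_base(BaseLearnerSpec("c45_like"), (X, y), seed=0)
        assert clf.n_nodes_ <= clf.n_nodes_pre_prune_

    def test_trees_learn_simple_rule(self, rng):
        X = rng.normal(size=(300, 5))
        y = (X[:, 2] > 0.1).astype(int) + 1
        for kind in ("c45_like", "rep_tree", "random_tree"):
            clf = train_base(BaseLearnerSpec(kind), (X, y), seed=0)
            X_new = rng.normal(size=(100, 5))
            y_new = (X_new[:, 2] > 0.1).astype(int) + 1
            assert np.mean(clf.predict(X_new) == y_new) > 0.9, kind

    def test_tree_proba_rows_normalized(self, rng):
        X = rng.normal(size=(100, 5))
        y = (X[:, 0] > 0).astype(int) + 1
        clf = train_base(BaseLearnerSpec("random_tree"), (X, y), seed=0)
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValidationError):
            train_base(BaseLearnerSpec("knn"), (X, np.ones(10, int)), 0)

    def test_unknown_kind(self):
        with pytest.raises(ValidationError):
            BaseLearnerSpec("perceptron")

    def test_tree_determinism(self, rng):
        X = rng.normal(size=(150, 8))
        y = (X[:, 1] + X[:, 3] > 0).astype(int) + 1
        a = DecisionTree(max_features="log2plus1", random_state=5).fit(X, y)
        b = DecisionTree(max_features="log2plus1", random_state=5).fit(X, y)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))
        assert a.n_nodes_ == b.n_nodes_


class TestRotationForest:
    def test_group_partition_arithmetic(self, blob_data):
        X, y = blob_data
        cfg = RotationForestConfig(n_members=2, group_size=3, seed=0)
        model = train_rotation_forest(cfg, BaseLearnerSpec("knn"), (X, y))
        for groups in model.feature_groups:
            assert len(groups) == 32           # ceil(95 / 3)
            assert len(groups[-1]) == 2        # 95 = 31 x 3 + 2
            flat = np.sort(np.concatenate(groups))
            np.testing.assert_array_equal(flat, np.arange(95))

    def test_rotations_blockwise_orthonormal(self, blob_data):
        X, y = blob_data
        cfg = RotationForestConfig(n_members=5, group_size=7, seed=3)
        model = train_rotation_forest(cfg, BaseLearnerSpec("knn"), (X, y))
        for R in model.transforms:
            assert np.max(np.abs(R.T @ R - np.eye(95))) < 1e-8

    def test_group_size_too_large(self, blob_data):
        X, y = blob_data
        cfg = RotationForestConfig(group_size=200, seed=0)
        with pytest.raises(ValidationError):
            train_rotation_forest(cfg, BaseLearnerSpec("knn"), (X, y))

    def test_1nn_rotation_invariance_single_member(self, blob_data):
        # one member, one full-size group, full sample: the member is a
        # plain 1-NN on globally rotated features, and 1-NN is invariant
        # under any orthogonal map, so predictions match the bare learner
        X, y = blob_data
        cfg = RotationForestConfig(n_members=1, group_size=95,
                                   class_subset_fraction=1.0,
                                   bootstrap_fraction=1.0, seed=0)
        model = train_rotation_forest(cfg, BaseLearnerSpec("knn"), (X, y))
        bare = train_base(BaseLearnerSpec("knn"), (X, y), seed=0)
        rng = np.random.default_rng(2)
        X_test = rng.normal(size=(50, 95)) + X[rng.integers(0, len(X), 50)]
        np.testing.assert_array_equal(model.predict(X_test),
                                      bare.predict(X_test))

    def test_scores_are_member_average(self, blob_data):
        X, y = blob_data
        cfg = RotationForestConfig(n_members=4, seed=1)
        model = train_rotation_forest(cfg, BaseLearnerSpec("random_tree"),
                                      (X, y))
        X_q = X[:5]
        by_hand = np.mean([
            member.predict_proba(X_q @ R)
            for member, R in zip(model.members, model.transforms)
        ], axis=0)
        np.testing.assert_allclose(model.predict_proba(X_q), by_hand,
                                   atol=1e-12)


class TestRandomSubspace:
    def test_subspace_size(self, blob_data):
        X, y = blob_data
        cfg = RandomSubspaceConfig(n_members=6, subspace_fraction=0.5, seed=0)
        model = train_random_subspace(cfg, BaseLearnerSpec("knn"), (X, y))
        for idx in model.transforms:
            assert len(idx) == 47              # floor(0.5 x 95)
            assert len(np.unique(idx)) == 47   # duplicate-free

    def test_full_space_single_member_identity(self, blob_data):
        X, y = blob_data
        cfg = RandomSubspaceConfig(n_members=1, subspace_fraction=1.0, seed=4)
        model = train_random_subspace(cfg, BaseLearnerSpec("rep_tree"), (X, y))
        bare = train_base(BaseLearnerSpec("rep_tree"), (X, y), seed=4)
        rng = np.random.default_rng(0)
        X_test = rng.normal(size=(60, 95))
        np.testing.assert_array_equal(model.predict(X_test),
                                      bare.predict(X_test))

    def test_majority_vote_unanimity(self, blob_data):
        X, y = blob_data
        cfg = RandomSubspaceConfig(n_members=11, subspace_fraction=0.8,
                                   seed=0)
        model = train_random_subspace(cfg, BaseLearnerSpec("knn"), (X, y))
        assert np.mean(model.predict(X) == y) == 1.0

    def test_empty_subspace_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([1, 2] * 10)
        cfg = RandomSubspaceConfig(subspace_fraction=0.1, seed=0)
        with pytest.raises(ValidationError):
            train_random_subspace(cfg, BaseLearnerSpec("knn"), (X, y))

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            RandomSubspaceConfig(n_members=0)
        with pytest.raises(ValidationError):
            RandomSubspaceConfig(subspace_fraction=1.5)
        with pytest.raises(ValidationError):
            RotationForestConfig(group_size=0)


class TestPredictContract:
    def test_scores_sum_to_one(self, blob_data):
        X, y = blob_data
        for model in (
            train_rotation_forest(RotationForestConfig(n_members=3, seed=0),
                                  BaseLearnerSpec("random_tree"), (X, y)),
            train_random_subspace(RandomSubspaceConfig(n_members=3, seed=0),
                                  BaseLearnerSpec("random_tree"), (X, y)),
        ):
            labels, scores = predict(model, X[:20])
            np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)
            assert set(labels) <= {1, 2}

    def test_training_set_recovered_with_1nn(self, blob_data):
        X, y = blob_data
        model = train_rotation_forest(
            RotationForestConfig(n_members=3, seed=0),
            BaseLearnerSpec("knn"), (X, y))
        labels, _ = predict(model, X)
        np.testing.assert_array_equal(labels, y)

    def test_width_mismatch(self, blob_data):
        X, y = blob_data
        model = train_random_subspace(RandomSubspaceConfig(seed=0),
                                      BaseLearnerSpec("knn"), (X, y))
        with pytest.raises(ValidationError):
            model.predict(X[:, :40])

    def test_determinism(self, blob_data):
        X, y = blob_data
        a = train_rotation_forest(RotationForestConfig(n_members=3, seed=9),
                                  BaseLearnerSpec("random_tree"), (X, y))
        b = train_rotation_forest(RotationForestConfig(n_members=3, seed=9),
                                  BaseLearnerSpec("random_tree"), (X, y))
        np.testing.assert_array_equal(a.predict(X), b.predict(X))
        np.testing.assert_allclose(a.predict_proba(X), b.predict_proba(X),
                                   atol=0)


class TestSerialization:
    @pytest.mark.parametrize("method", ["rof", "rsm"])
    def test_round_trip_bitwise(self, tmp_path, blob_data, method):
        X, y = blob_data
        if method == "rof":
            model = train_rotation_forest(
                RotationForestConfig(n_members=3, seed=0),
                BaseLearnerSpec("rep_tree"), (X, y))
        else:
            model = train_random_subspace(
                RandomSubspaceConfig(n_members=3, seed=0),
                BaseLearnerSpec("rep_tree"), (X, y))
        save_model(model, tmp_path / "bundle")
        back = load_model(tmp_path / "bundle")
        rng = np.random.default_rng(3)
        X_test = rng.normal(size=(30, 95))
        np.testing.assert_array_equal(model.predict(X_test),
                                      back.predict(X_test))
        np.testing.assert_array_equal(model.predict_proba(X_test),
                                      back.predict_proba(X_test))
        assert back.method == model.method
        assert back.base_spec == model.base_spec
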