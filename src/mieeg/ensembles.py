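"""Base classifiers and the two committee methods.

Base learners: polynomial-kernel SVM (cubic, C = 100), 1-nearest-neighbour,
random forest (100 trees), plus three entropy trees from :mod:`mieeg.trees`.
Committees: Rotation Forest (blockwise-PCA feature rotation per member,
average of class scores) and Random Subspace (random feature subsets,
majority vote, ties to the lowest label).
"""

from __future__ import annotations

import dataclasses
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .model import FeatureMatrix, ValidationError
from .trees import DecisionTree

__all__ = [
    "BaseLearnerSpec",
    "RotationForestConfig",
    "RandomSubspaceConfig",
    "EnsembleModel",
    "BASE_LEARNER_KINDS",
    "make_base",
    "train_base",
    "train_rotation_forest",
    "train_random_subspace",
    "predict",
    "save_model",
    "load_model",
]

BASE_LEARNER_KINDS = ("svm", "knn", "rf", "c45_like", "rep_tree",
                      "random_tree")

_BUNDLE_VERSION = 1


@dataclass
class BaseLearnerSpec:
    kind: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in BASE_LEARNER_KINDS:
            raise ValidationError(
                f"unknown base learner {self.kind!r}; "
                f"choose from {BASE_LEARNER_KINDS}")


@dataclass
class RotationForestConfig:
    n_members: int = 10
    group_size: int = 3
    class_subset_fraction: float = 0.75
    bootstrap_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if self.n_members < 1:
            raise ValidationError("n_members must be >= 1")
        if self.group_size < 1:
            raise ValidationError("group_size must be >= 1")
        for name in ("class_subset_fraction", "bootstrap_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name} must lie in (0, 1]")


@dataclass
class RandomSubspaceConfig:
    n_members: int = 10
    subspace_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_members < 1:
            raise ValidationError("n_members must be >= 1")
        if not (0.0 < self.subspace_fraction <= 1.0):
            raise ValidationError("subspace_fraction must lie in (0, 1]")


def make_base(spec: BaseLearnerSpec, seed: int):
    """Instantiate an unfitted base learner with the documented defaults."""
    hp = dict(spec.hyperparameters)
    if spec.kind == "svm":
        svc = SVC(kernel="poly",
                  degree=int(hp.pop("degree", 3)),
                  C=float(hp.pop("C", 100.0)),
                  coef0=float(hp.pop("coef0", 0.0)),
                  gamma=hp.pop("gamma", "scale"),
                  random_state=seed, **hp)
        # AUC needs ranking scores: sigmoid link fitted on training folds
        return CalibratedClassifierCV(svc, method="sigmoid", cv=3,
                                      ensemble=False)
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=int(hp.pop("k", 1)), **hp)
    if spec.kind == "rf":
        return RandomForestClassifier(
            n_estimators=int(hp.pop("n_trees", 100)),
            random_state=seed, **hp)
    if spec.kind == "c45_like":
        return DecisionTree(criterion="gain_ratio", pruning="pessimistic",
                            random_state=seed, **hp)
    if spec.kind == "rep_tree":
        return DecisionTree(criterion="info_gain", pruning="reduced_error",
                            random_state=seed, **hp)
    if spec.kind == "random_tree":
        return DecisionTree(criterion="info_gain", pruning=None,
                            max_features="log2plus1", random_state=seed, **hp)
    raise ValidationError(f"unknown base learner {spec.kind!r}")


def _as_xy(features):
    if isinstance(features, FeatureMatrix):
        return features.values, features.labels
    X, y = features
    return np.asarray(X, dtype=float), np.asarray(y)


def _check_trainable(y):
    if len(np.unique(y)) < 2:
        raise ValidationError("training data must contain >= 2 classes")


def train_base(spec: BaseLearnerSpec, features, seed: int = 0):
    """Fit a bare base learner; exposes predict / predict_proba / classes_."""
    X, y = _as_xy(features)
    _check_trainable(y)
    if not np.all(np.isfinite(X)):
        raise ValidationError("features contain missing/non-finite values")
    clf = make_base(spec, seed)
    clf.fit(X, y)
    return clf


@dataclass
class EnsembleModel:
    method: str  # rotation_forest | random_subspace
    members: list
    transforms: list  # rotation matrices or feature-index arrays
    base_spec: BaseLearnerSpec
    classes: np.ndarray
    n_features_in: int
    config: object = None
    feature_groups: list | None = None  # RoF only, per-member group lists

    def _member_inputs(self, X, i):
        if self.method == "rotation_forest":
            return X @ self.transforms[i]
        return X[:, self.transforms[i]]

    def predict_proba(self, X) -> np.ndarray:
        X = self._check_width(X)
        agg = np.zeros((len(X), len(self.classes)))
        for i, member in enumerate(self.members):
            proba = member.predict_proba(self._member_inputs(X, i))
            cols = np.searchsorted(self.classes, member.classes_)
            agg[:, cols] += proba
        agg /= len(self.members)
        return agg

    def predict(self, X) -> np.ndarray:
        X = self._check_width(X)
        if self.method == "random_subspace":
            votes = np.zeros((len(X), len(self.classes)), dtype=int)
            for i, member in enumerate(self.members):
                pred = member.predict(self._member_inputs(X, i))
                votes[np.arange(len(X)),
                      np.searchsorted(self.classes, pred)] += 1
            # argmax takes the first maximum -> ties go to the lowest label
            return self.classes[np.argmax(votes, axis=1)]
        scores = self.predict_proba(X)
        return self.classes[np.argmax(scores, axis=1)]

    def _check_width(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in:
            raise ValidationError(
                f"expected {self.n_features_in} feature columns, "
                f"got {X.shape[1] if X.ndim == 2 else 'non-matrix'}")
        return X


def train_rotation_forest(config: RotationForestConfig,
                          base: BaseLearnerSpec,
                          features) -> EnsembleModel:
    """Rotation Forest per Rodriguez: per member, partition the features
    into groups of ``group_size``, fit PCA (all components) per group on a
    class-subset bootstrap, assemble the blockwise rotation matrix, and
    train the base learner on the rotated data."""
    X, y = _as_xy(features)
    _check_trainable(y)
    n, f = X.shape
    if config.group_size > f:
        raise ValidationError(
            f"group_size {config.group_size} exceeds {f} features")
    classes = np.unique(y)
    rng = np.random.default_rng(config.seed)
    members, transforms, groups_per_member = [], [], []
    for m in range(config.n_members):
        perm = rng.permutation(f)
        groups = [perm[i:i + config.group_size]
                  for i in range(0, f, config.group_size)]
        R = np.zeros((f, f))
        for grp in groups:
            keep = classes[rng.random(len(classes))
                           < config.class_subset_fraction]
            if len(keep) == 0:
                keep = classes[[rng.integers(len(classes))]]
            rows = np.nonzero(np.isin(y, keep))[0]
            size = max(2, int(round(config.bootstrap_fraction * len(rows))))
            size = min(size, len(rows))
            rows = rng.choice(rows, size=size, replace=False)
            if len(rows) < 2:
                rows = np.arange(n)
            sub = X[np.ix_(rows, grp)]
            sub = sub - sub.mean(axis=0)
            cov = sub.T @ sub / (len(sub) - 1)
            eigvals, eigvecs = np.linalg.eigh(cov)
            order = np.argsort(eigvals)[::-1]
            R[np.ix_(grp, grp)] = eigvecs[:, order]  # all components kept
        clf = make_base(base, config.seed + m)
        clf.fit(X @ R, y)
        members.append(clf)
        transforms.append(R)
        groups_per_member.append(groups)
    return EnsembleModel(
        method="rotation_forest", members=members, transforms=transforms,
        base_spec=base, classes=classes, n_features_in=f, config=config,
        feature_groups=groups_per_member)


def train_random_subspace(config: RandomSubspaceConfig,
                          base: BaseLearnerSpec,
                          features) -> EnsembleModel:
    """Random Subspace: each member trains on a random duplicate-free
    feature subset of size floor(fraction x n_features); simple majority
    vote at prediction."""
    X, y = _as_xy(features)
    _check_trainable(y)
    n, f = X.shape
    b = int(np.floor(config.subspace_fraction * f))
    if b < 1:
        raise ValidationError(
            f"subspace_fraction {config.subspace_fraction} yields an empty "
            f"subspace for {f} features")
    rng = np.random.default_rng(config.seed)
    members, transforms = [], []
    for m in range(config.n_members):
        idx = np.sort(rng.choice(f, size=b, replace=False))
        clf = make_base(base, config.seed + m)
        clf.fit(X[:, idx], y)
        members.append(clf)
        transforms.append(idx)
    return EnsembleModel(
        method="random_subspace", members=members, transforms=transforms,
        base_spec=base, classes=np.unique(y), n_features_in=f, config=config)


def predict(model: EnsembleModel, features):
    """(labels, class-score rows summing to 1) for a feature matrix."""
    X = features.values if isinstance(features, FeatureMatrix) \
        else np.asarray(features, dtype=float)
    return model.predict(X), model.predict_proba(X)


# ---------------------------------------------------------------------------
# serialization: JSON manifest + pickled members + npz transforms
# ---------------------------------------------------------------------------

def save_model(model: EnsembleModel, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "bundle_version": _BUNDLE_VERSION,
        "method": model.method,
        "base_spec": dataclasses.asdict(model.base_spec),
        "config": dataclasses.asdict(model.config) if model.config else None,
        "classes": [int(c) for c in model.classes],
        "n_features_in": model.n_features_in,
        "n_members": len(model.members),
    }
    (path / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    arrays = {f"t{i}": t for i, t in enumerate(model.transforms)}
    np.savez(path / "transforms.npz", **arrays)
    with open(path / "members.pkl", "wb") as fh:
        pickle.dump(model.members, fh)
    return path


def load_model(path) -> EnsembleModel:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest["bundle_version"] != _BUNDLE_VERSION:
        raise ValidationError(
            f"unsupported bundle version {manifest['bundle_version']}")
    with open(path / "members.pkl", "rb") as fh:
        members = pickle.load(fh)
    npz = np.load(path / "transforms.npz")
    transforms = [npz[f"t{i}"] for i in range(manifest["n_members"])]
    cfg_cls = (RotationForestConfig if manifest["method"] == "rotation_forest"
               else RandomSubspaceConfig)
    config = cfg_cls(**manifest["config"]) if manifest["config"] else None
    return EnsembleModel(
        method=manifest["method"], members=members, transforms=transforms,
        base_spec=BaseLearnerSpec(**manifest["base_spec"]),
        classes=np.array(manifest["classes"]),
        n_features_in=manifest["n_features_in"], config=config)
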