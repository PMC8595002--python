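"""Confusion-count metrics, ROC AUC, stratified cross-validation, and the
per-subject / pooled experiment grid.

Class 1 (right hand) is the positive class for tp/fp bookkeeping.  Fold
results are aggregated by pooling confusion counts (accuracy, F-measure)
and pooling scores (AUC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .ensembles import (
    BaseLearnerSpec,
    RandomSubspaceConfig,
    RotationForestConfig,
    train_base,
    train_random_subspace,
    train_rotation_forest,
)
from .model import FeatureMatrix, ValidationError

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "accuracy",
    "f_measure",
    "tpr_fpr",
    "auc",
    "confusion_from_predictions",
    "cross_validate",
    "run_experiment_grid",
    "summarize_reports",
]

POSITIVE_LABEL = 1


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)

    def to_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn}


def accuracy(counts: ConfusionCounts) -> float:
    """Percent correct: 100 (tp + tn) / (tp + tn + fp + fn)."""
    if counts.total == 0:
        raise ValidationError("accuracy undefined on empty counts")
    return 100.0 * (counts.tp + counts.tn) / counts.total


def f_measure(counts: ConfusionCounts) -> float:
    """tp / (tp + (fp + fn) / 2); degenerate all-zero case returns 0."""
    denom = counts.tp + 0.5 * (counts.fp + counts.fn)
    if denom == 0:
        warnings.warn("F-measure degenerate (tp = fp = fn = 0); returning 0",
                      stacklevel=2)
        return 0.0
    return counts.tp / denom


def tpr_fpr(counts: ConfusionCounts) -> tuple[float, float]:
    """(tp / (tp + fn), fp / (fp + tn))."""
    if counts.tp + counts.fn == 0:
        raise ValidationError("TPR undefined: no positive instances")
    if counts.fp + counts.tn == 0:
        raise ValidationError("FPR undefined: no negative instances")
    return (counts.tp / (counts.tp + counts.fn),
            counts.fp / (counts.fp + counts.tn))


def auc(scores, labels, positive=POSITIVE_LABEL) -> float:
    """Trapezoidal area under the ROC curve of positive-class scores.

    Tied scores cross their threshold simultaneously, which is equivalent to
    half credit per tied positive-negative pair.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos = int(pos.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    p = pos[order].astype(float)
    # group boundaries where the sorted score strictly drops
    boundary = np.nonzero(np.diff(s) < 0)[0]
    ends = np.append(boundary, len(s) - 1)
    cum_tp = np.cumsum(p)[ends] / n_pos
    cum_fp = np.cumsum(1.0 - p)[ends] / n_neg
    tpr = np.concatenate([[0.0], cum_tp])
    fpr = np.concatenate([[0.0], cum_fp])
    return float(np.sum(np.diff(fpr) * (tpr[1:] + tpr[:-1]) / 2.0))


def confusion_from_predictions(y_true, y_pred,
                               positive=POSITIVE_LABEL) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    is_pos = y_true == positive
    pred_pos = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(is_pos & pred_pos)),
        tn=int(np.sum(~is_pos & ~pred_pos)),
        fp=int(np.sum(~is_pos & pred_pos)),
        fn=int(np.sum(is_pos & ~pred_pos)),
    )


@dataclass
class EvalReport:
    accuracy: float
    f_measure: float
    auc: float
    per_fold: list[ConfusionCounts]
    scheme: str  # per_subject | pooled
    classifier_id: str
    seed: int
    subject: str = "ALL"
    n_instances: int = 0
    skipped: bool = False
    skip_reason: str = ""

    def __post_init__(self):
        if self.skipped:
            return
        pooled = sum(self.per_fold, ConfusionCounts())
        if abs(self.accuracy - accuracy(pooled)) > 1e-9:
            raise ValidationError(
                "report accuracy inconsistent with pooled fold counts")

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "f_measure": self.f_measure,
            "auc": self.auc, "scheme": self.scheme,
            "classifier_id": self.classifier_id, "seed": self.seed,
            "subject": self.subject, "n_instances": self.n_instances,
            "skipped": self.skipped, "skip_reason": self.skip_reason,
            "per_fold": [c.to_dict() for c in self.per_fold],
        }


class _BareWrapper:
    """Adapts a bare base learner to the ensemble predict surface."""

    def __init__(self, clf):
        self.clf = clf

    def predict(self, X):
        return self.clf.predict(X)

    def predict_proba(self, X):
        return self.clf.predict_proba(X)

    @property
    def classes(self):
        return self.clf.classes_


def _train(base_spec, ensemble_config, X, y, seed):
    if ensemble_config is None:
        return _BareWrapper(train_base(base_spec, (X, y), seed))
    cfg_type = type(ensemble_config)
    cfg = cfg_type(**{**ensemble_config.__dict__, "seed": seed})
    if isinstance(cfg, RotationForestConfig):
        return train_rotation_forest(cfg, base_spec, (X, y))
    if isinstance(cfg, RandomSubspaceConfig):
        return train_random_subspace(cfg, base_spec, (X, y))
    raise ValidationError(f"unknown ensemble config {cfg_type.__name__}")


def cross_validate(features: FeatureMatrix,
                   base_spec: BaseLearnerSpec,
                   ensemble_config=None,
                   n_folds: int = 10,
                   seed: int = 0,
                   classifier_id: str | None = None,
                   scheme: str = "pooled",
                   subject: str = "ALL") -> EvalReport:
    """Stratified k-fold CV; pooled confusion counts and pooled-score AUC."""
    X, y = features.values, features.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("cross-validation needs both classes")
    if counts.min() < n_folds:
        raise ValidationError(
            f"smallest class has {counts.min()} instances; cannot stratify "
            f"into {n_folds} folds")
    if classifier_id is None:
        method = ("bare" if ensemble_config is None else
                  "rof" if isinstance(ensemble_config, RotationForestConfig)
                  else "rsm")
        classifier_id = f"{method}+{base_spec.kind}"
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    per_fold = []
    all_scores = np.empty(len(y))
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = _train(base_spec, ensemble_config, X[tr], y[tr], seed + fold)
        pred = model.predict(X[te])
        proba = model.predict_proba(X[te])
        model_classes = model.classes if hasattr(model, "classes") \
            else model.classes_
        pos_col = int(np.nonzero(np.asarray(model_classes)
                                 == POSITIVE_LABEL)[0][0])
        per_fold.append(confusion_from_predictions(y[te], pred))
        all_scores[te] = proba[:, pos_col]
    pooled = sum(per_fold, ConfusionCounts())
    return EvalReport(
        accuracy=accuracy(pooled),
        f_measure=f_measure(pooled),
        auc=auc(all_scores, y),
        per_fold=per_fold,
        scheme=scheme,
        classifier_id=classifier_id,
        seed=seed,
        subject=subject,
        n_instances=len(y),
    )


def run_experiment_grid(features: FeatureMatrix,
                        base_specs: list[BaseLearnerSpec],
                        ensemble_configs: dict,
                        n_folds: int = 10,
                        seed: int = 0) -> list[EvalReport]:
    """One report per (ensemble x base x subject) plus pooled "ALL" rows.

    ``ensemble_configs`` maps a short name (e.g. "rsm", "rof") to a config.
    Subjects too small to stratify yield a skipped placeholder, not an error.
    """
    subjects = sorted(set(features.subject_ids))
    subj_arr = np.array(features.subject_ids)
    reports = []
    for ens_name, ens_cfg in ensemble_configs.items():
        for base in base_specs:
            cid = f"{ens_name}+{base.kind}"
            cells = [(s, features.subset(subj_arr == s), "per_subject")
                     for s in subjects]
            cells.append(("ALL", features, "pooled"))
            for subject, feats, scheme in cells:
                try:
                    reports.append(cross_validate(
                        feats, base, ens_cfg, n_folds=n_folds, seed=seed,
                        classifier_id=cid, scheme=scheme, subject=subject))
                except ValidationError as exc:
                    reports.append(EvalReport(
                        accuracy=float("nan"), f_measure=float("nan"),
                        auc=float("nan"), per_fold=[], scheme=scheme,
                        classifier_id=cid, seed=seed, subject=subject,
                        n_instances=len(feats), skipped=True,
                        skip_reason=str(exc)))
    return reports


def summarize_reports(reports: list[EvalReport]) -> pd.DataFrame:
    """Long-form summary table: one row per (subject, classifier) cell."""
    rows = [{
        "subject": r.subject,
        "classifier": r.classifier_id,
        "scheme": r.scheme,
        "accuracy": r.accuracy,
        "f_measure": r.f_measure,
        "auc": r.auc,
        "n_instances": r.n_instances,
        "skipped": r.skipped,
    } for r in reports]
    df = pd.DataFrame(rows)
    return df.sort_values(["classifier", "subject"]).reset_index(drop=True)
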