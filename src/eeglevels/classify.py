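"""Support-vector classification with the study's resampling protocol.

Protocol: a 25% held-out test split, grid search over SVM hyper-parameters by
10-fold cross-validated accuracy on the training subset only, then evaluation
with accuracy, precision, recall, F1, the confusion matrix, per-class ROC
curves with micro and macro AUC averaging, and learning curves.

Because each subject contributes rows to both classes (one control window,
two on-effect windows), naive row-wise splitting lets the same subject appear
on both sides of the split.  The default split is therefore subject-grouped
(leakage-safe); ``grouping="row"`` reproduces plain stratified row splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import clone
from sklearn.metrics import (accuracy_score, auc, confusion_matrix,
                             precision_recall_fscore_support, roc_curve)
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data import FeatureTable


def default_grid() -> list[dict[str, list[Any]]]:
    """Small logarithmic cost/width grid over linear and radial-basis kernels."""
    return [
        {"svc__kernel": ["linear"], "svc__C": [0.1, 1.0, 10.0]},
        {"svc__kernel": ["rbf"], "svc__C": [0.1, 1.0, 10.0], "svc__gamma": ["scale"]},
    ]


@dataclass
class SplitPlan:
    """How the data is partitioned into train/test and CV folds."""

    test_fraction: float = 0.25
    cv_folds: int = 10
    grouping: str = "subject"  # "subject" (leakage-safe) or "row"
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.grouping not in ("subject", "row"):
            raise ValueError("grouping must be 'subject' or 'row'")


@dataclass
class FittedModel:
    """A fitted scaler+SVM pipeline with its selected hyper-parameters.

    Feature scaling is fitted on training rows only (inside the pipeline), so
    no test-set statistics leak into the model.
    """

    pipeline: Pipeline
    feature_names: list[str]
    best_params: dict[str, Any]
    cv_results: dict[str, Any]
    cv_best_mean_accuracy: float

    def _check(self, table: FeatureTable) -> None:
        if table.feature_names != self.feature_names:
            raise ValueError("feature names of the table do not match the fitted model")

    def predict(self, table: FeatureTable) -> np.ndarray:
        self._check(table)
        return self.pipeline.predict(table.X)

    def decision_scores(self, table: FeatureTable) -> np.ndarray:
        self._check(table)
        return self.pipeline.decision_function(table.X)


def split_data(table: FeatureTable, plan: SplitPlan) -> tuple[FeatureTable, FeatureTable]:
    """Stratified train/test split, subject-grouped by default.

    Under subject grouping, all rows of a subject land on the same side, and
    the number of test subjects is ``round(test_fraction * n_subjects)``.
    """
    classes, counts = np.unique(table.y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 rows per class to split")
    rng = np.random.default_rng(plan.seed)
    if plan.grouping == "subject":
        subjects = np.array(sorted(set(table.groups.tolist())))
        if len(subjects) < 2:
            raise ValueError("subject-grouped split needs >= 2 subjects")
        n_test = max(1, int(round(plan.test_fraction * len(subjects))))
        if n_test >= len(subjects):
            raise ValueError("test_fraction leaves no training subjects")
        test_subjects = set(rng.permutation(subjects)[:n_test].tolist())
        test_mask = np.array([g in test_subjects for g in table.groups])
    else:
        idx = np.arange(table.n_rows)
        _, test_idx = train_test_split(
            idx,
            test_size=plan.test_fraction,
            stratify=table.y if plan.stratified else None,
            random_state=int(rng.integers(2**31)),
        )
        test_mask = np.zeros(table.n_rows, dtype=bool)
        test_mask[test_idx] = True
    train, test = table.subset(~test_mask), table.subset(test_mask)
    for name, part in (("train", train), ("test", test)):
        if len(np.unique(part.y)) < 2:
            raise ValueError(f"{name} subset ended up single-class; adjust the split plan")
    return train, test


def _make_pipeline(class_weight: str | None = "balanced") -> Pipeline:
    return Pipeline([
        ("scaler", StandardScaler()),
        ("svc", SVC(class_weight=class_weight)),
    ])


def grid_search_fit(train: FeatureTable,
                    hyper_grid: list[dict[str, list[Any]]] | None = None,
                    k: int = 10, seed: int = 0,
                    class_weight: str | None = "balanced") -> FittedModel:
    """Select hyper-parameters by mean k-fold CV accuracy on the training rows.

    Ties go to the first grid point in grid order; the winner is refit on all
    training rows.  A grid point that fails to fit is scored NaN and skipped.
    The fold count is capped at the smallest class count so stratified folds
    remain valid on small tables.
    """
    hyper_grid = hyper_grid if hyper_grid is not None else default_grid()
    if not hyper_grid or all(not g for g in hyper_grid):
        raise ValueError("hyper-parameter grid is empty")
    min_class = int(np.unique(train.y, return_counts=True)[1].min())
    k_eff = min(k, min_class)
    if k_eff < 2:
        raise ValueError("not enough rows per class for cross-validation")
    cv = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    search = GridSearchCV(
        _make_pipeline(class_weight),
        hyper_grid,
        scoring="accuracy",
        cv=cv,
        error_score=np.nan,
        refit=True,
    )
    search.fit(train.X, train.y)
    return FittedModel(
        pipeline=search.best_estimator_,
        feature_names=list(train.feature_names),
        best_params=dict(search.best_params_),
        cv_results={key: np.asarray(val).tolist()
                    for key, val in search.cv_results_.items()
                    if key in ("params", "mean_test_score", "std_test_score", "rank_test_score")},
        cv_best_mean_accuracy=float(search.best_score_),
    )


def _roc(y_true: np.ndarray, scores: np.ndarray) -> dict[str, Any]:
    """Per-class ROC plus micro and macro averages from decision scores.

    The binary decision score s favors class 1; class 0 is scored as -s.
    Micro averaging pools the per-class indicator/score pairs; macro averages
    the per-class AUCs with equal weight.
    """
    score_matrix = np.column_stack([-scores, scores])
    onehot = np.column_stack([(y_true == 0), (y_true == 1)]).astype(int)
    out: dict[str, Any] = {"per_class": {}}
    aucs = []
    for cls in (0, 1):
        fpr, tpr, _ = roc_curve(onehot[:, cls], score_matrix[:, cls])
        cls_auc = auc(fpr, tpr)
        aucs.append(cls_auc)
        out["per_class"][str(cls)] = {
            "fpr": fpr.tolist(), "tpr": tpr.tolist(), "auc": float(cls_auc),
        }
    fpr_mi, tpr_mi, _ = roc_curve(onehot.ravel(), score_matrix.ravel())
    out["micro"] = {"fpr": fpr_mi.tolist(), "tpr": tpr_mi.tolist(),
                    "auc": float(auc(fpr_mi, tpr_mi))}
    out["macro"] = {"auc": float(np.mean(aucs))}
    return out


def evaluate(model: FittedModel, table: FeatureTable, subset_tag: str) -> dict[str, Any]:
    """Metric suite for one subset (train or test).

    Precision/recall/F1 are reported for the positive class (class 1, the
    on-effect condition) and macro-averaged; recall is the hit rate on the
    positive rows.
    """
    if len(np.unique(table.y)) < 2:
        raise ValueError(f"{subset_tag} subset is single-class; ROC is undefined")
    y_pred = model.predict(table)
    scores = model.decision_scores(table)
    cm = confusion_matrix(table.y, y_pred, labels=[0, 1])
    prec, rec, f1, _ = precision_recall_fscore_support(
        table.y, y_pred, labels=[0, 1], zero_division=0)
    with np.errstate(invalid="ignore"):
        cm_rates = cm / cm.sum(axis=1, keepdims=True)
    return {
        "subset": subset_tag,
        "n_rows": int(table.n_rows),
        "accuracy": float(accuracy_score(table.y, y_pred)),
        "precision": float(prec[1]),
        "recall": float(rec[1]),
        "f1": float(f1[1]),
        "precision_macro": float(prec.mean()),
        "recall_macro": float(rec.mean()),
        "f1_macro": float(f1.mean()),
        "confusion_matrix": cm.tolist(),
        "confusion_matrix_rates": cm_rates.tolist(),
        "roc": _roc(table.y, scores),
    }


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from raw confusion counts."""
    total = tp + fp + fn + tn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    return {
        "accuracy": (tp + tn) / total,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def learning_curve(train: FeatureTable, test: FeatureTable,
                   model_params: dict[str, Any] | None = None,
                   sizes: list[int] | None = None, n_repeats: int = 5,
                   seed: int = 0,
                   class_weight: str | None = "balanced") -> list[dict[str, Any]]:
    """Train/test accuracy as a function of training-set size.

    For each size, rows are subsampled (stratified) ``n_repeats`` times with
    fresh seeds and a model with fixed hyper-parameters is refit; sizes too
    small to contain both classes are skipped with a note.
    """
    if sizes is None:
        n = train.n_rows
        sizes = sorted({max(4, int(round(f * n))) for f in (0.2, 0.4, 0.6, 0.8, 1.0)})
    if sizes != sorted(sizes):
        raise ValueError("sizes must be increasing")
    if sizes[-1] > train.n_rows:
        raise ValueError("largest size exceeds the training set")
    rng = np.random.default_rng(seed)
    points = []
    for size in sizes:
        accs_train, accs_test = [], []
        for _ in range(n_repeats):
            if size == train.n_rows:
                idx = np.arange(size)
            else:
                idx, _ = train_test_split(
                    np.arange(train.n_rows), train_size=size, stratify=train.y,
                    random_state=int(rng.integers(2**31)))
            sub = train.subset(np.isin(np.arange(train.n_rows), idx))
            if len(np.unique(sub.y)) < 2:
                continue
            pipe = _make_pipeline(class_weight)
            if model_params:
                pipe.set_params(**model_params)
            pipe.fit(sub.X, sub.y)
            accs_train.append(accuracy_score(sub.y, pipe.predict(sub.X)))
            accs_test.append(accuracy_score(test.y, pipe.predict(test.X)))
        if not accs_test:
            points.append({"size": size, "note": "skipped: single-class subsample"})
            continue
        points.append({
            "size": size,
            "train_accuracy": float(np.mean(accs_train)),
            "test_accuracy": float(np.mean(accs_test)),
        })
    return points
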