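"""Scenario classifiers and their cross-validated evaluation.

Three fixed classification pipelines are built, one per input scenario:

* Scenario I (RGB features): gradient-boosted trees (max depth 8, max
  feature subset 0.2, min samples/leaf 4, min samples/split 5);
* Scenario II (tissue-index features): extremely randomized trees
  (bootstrap, max features 0.25, min samples leaf 5, min samples split 20,
  random state 111);
* Scenario III (combined): a stacking step that appends a stochastic-
  gradient-descent linear classifier's outputs as meta-features (alpha 0.0,
  eta0 0.01, no intercept, l1 ratio 0.0, inverse-scaling learning rate,
  modified-Huber loss, elastic-net penalty, power_t 100.0), a zero-count
  feature constructor, and a linear SVC (dual false, L1 penalty, tol 1e-3).
  This pipeline exposes no probability outputs.

The unusual SGD settings (alpha 0, power_t 100) are kept verbatim, with a
logged warning.  Evaluation uses repeated stratified k-fold (8 splits, 30
repetitions) with per-repetition metric traces, plus one-vs-rest ROC/AUC
over a stratified 4-fold split for the probabilistic pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.ensemble import ExtraTreesClassifier, GradientBoostingClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.svm import LinearSVC

__all__ = [
    "SCENARIO_HYPERPARAMETERS",
    "ZeroCount",
    "StackingEstimator",
    "build_pipeline",
    "zero_count_transform",
    "split_train_test",
    "compute_metrics",
    "repeated_cv_evaluate",
    "roc_auc_ovr",
    "feature_importance",
    "EvaluationReport",
]

#: per-scenario classifier hyperparameters (immutable record)
SCENARIO_HYPERPARAMETERS = {
    "I": {
        "classifier": "GradientBoostingClassifier",
        "max_depth": 8,
        "max_features": 0.2,
        "min_samples_leaf": 4,
        "min_samples_split": 5,
    },
    "II": {
        "classifier": "ExtraTreesClassifier",
        "bootstrap": True,
        "max_features": 0.25,
        "min_samples_leaf": 5,
        "min_samples_split": 20,
        "random_state": 111,
    },
    "III": {
        "classifier": "StackingEstimator(SGDClassifier) -> ZeroCount -> LinearSVC",
        "sgd": {
            "alpha": 0.0, "eta0": 0.01, "fit_intercept": False,
            "l1_ratio": 0.0, "learning_rate": "invscaling",
            "loss": "modified_huber", "penalty": "elasticnet",
            "power_t": 100.0,
        },
        "svc": {"dual": False, "penalty": "l1", "tol": 0.001},
    },
}


def zero_count_transform(X: np.ndarray) -> np.ndarray:
    """Append per-row counts of zero and non-zero entries as two columns."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("zero_count_transform requires a finite matrix")
    zeros = np.sum(X == 0, axis=1, keepdims=True).astype(float)
    nonzeros = np.sum(X != 0, axis=1, keepdims=True).astype(float)
    return np.hstack([X, zeros, nonzeros])


class ZeroCount(BaseEstimator, TransformerMixin):
    """Feature constructor appending zero / non-zero counts per sample."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return zero_count_transform(X)


class StackingEstimator(BaseEstimator, TransformerMixin):
    """Append a base classifier's outputs to the feature matrix.

    Follows the AutoML stacking convention: the transformed matrix is the
    original features plus the base estimator's class probabilities (when
    available) and its predicted class.
    """

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y=None, **fit_params):
        self.estimator_ = clone(self.estimator)
        self.estimator_.fit(X, y, **fit_params)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        classes = list(self.estimator_.classes_)
        pred_idx = np.array(
            [classes.index(p) for p in self.estimator_.predict(X)],
            dtype=float,
        )
        extras = [pred_idx.reshape(-1, 1)]
        if hasattr(self.estimator_, "predict_proba"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                proba = self.estimator_.predict_proba(X)
            extras.insert(0, np.nan_to_num(proba, nan=0.0))
        return np.hstack([X] + extras)


def build_pipeline(scenario: str, seed: int = 0):
    """Instantiate the fixed pipeline for a scenario.

    Scenarios I and II expose ``predict_proba``; scenario III does not.
    The scenario II ensemble keeps its fixed random state 111 regardless of
    ``seed``; ``seed`` drives the other stochastic stages.
    """
    if scenario == "I":
        return GradientBoostingClassifier(
            max_depth=8, max_features=0.2, min_samples_leaf=4,
            min_samples_split=5, random_state=seed,
        )
    if scenario == "II":
        return ExtraTreesClassifier(
            n_estimators=100, bootstrap=True, max_features=0.25,
            min_samples_leaf=5, min_samples_split=20, random_state=111,
        )
    if scenario == "III":
        sgd_params = SCENARIO_HYPERPARAMETERS["III"]["sgd"]
        if sgd_params["alpha"] == 0.0 or sgd_params["power_t"] >= 10:
            warnings.warn(
                "scenario III SGD uses alpha=0.0 / power_t=100.0 verbatim; "
                "regularization is effectively off and the learning rate "
                "collapses after the first update",
                stacklevel=2,
            )
        sgd = SGDClassifier(random_state=seed, **sgd_params)
        svc = LinearSVC(dual=False, penalty="l1", tol=0.001,
                        random_state=seed)
        return Pipeline([
            ("stacking", StackingEstimator(sgd)),
            ("zero_count", ZeroCount()),
            ("linear_svc", svc),
        ])
    raise ValueError(f"unknown scenario {scenario!r}")


def is_probabilistic(pipeline) -> bool:
    est = pipeline.steps[-1][1] if isinstance(pipeline, Pipeline) else pipeline
    return hasattr(est, "predict_proba")


def split_train_test(
    X,
    y,
    fraction: float = 0.75,
    seed: int = 0,
    lesion_ids=None,
    group_by_lesion: bool = True,
):
    """Stratified 75/25 split, optionally grouped by lesion.

    With grouping on (the default), whole lesions are assigned to one side,
    so no lesion contributes ROIs to both train and test; because every
    lesion carries one ROI per class, the grouped split is automatically
    stratified.
    """
    y = np.asarray(y)
    n = y.shape[0]
    rng = np.random.default_rng(seed)
    indices = np.arange(n)
    if group_by_lesion and lesion_ids is not None:
        groups = np.asarray(lesion_ids)
        unique = np.unique(groups)
        perm = rng.permutation(unique)
        n_train_groups = int(round(fraction * unique.size))
        train_groups = set(perm[:n_train_groups])
        train_idx = indices[np.isin(groups, list(train_groups))]
        test_idx = indices[~np.isin(groups, list(train_groups))]
    else:
        train_parts, test_parts = [], []
        for cls in np.unique(y):
            cls_idx = rng.permutation(indices[y == cls])
            n_train = int(round(fraction * cls_idx.size))
            train_parts.append(cls_idx[:n_train])
            test_parts.append(cls_idx[n_train:])
        train_idx = np.sort(np.concatenate(train_parts))
        test_idx = np.sort(np.concatenate(test_parts))
    for side, name in ((train_idx, "train"), (test_idx, "test")):
        present = set(y[side])
        if present != set(y):
            raise ValueError(f"infeasible stratification: {name} side is "
                             f"missing classes {set(y) - present}")
    return train_idx, test_idx


def compute_metrics(y_true, y_pred) -> dict:
    """Accuracy plus macro precision/recall/F1/balanced accuracy and
    per-class breakdowns; balanced accuracy equals macro recall."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    cm = confusion_matrix(y_true, y_pred, labels=classes).astype(float)
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    tp = np.diag(cm)
    per_class: dict[str, dict] = {}
    precisions, recalls, f1s = [], [], []
    for idx, cls in enumerate(classes):
        if support[idx] == 0:
            warnings.warn(f"class {cls!r} absent from y_true; excluded from "
                          "macro averages", stacklevel=2)
            per_class[str(cls)] = {"precision": None, "recall": None,
                                   "f1": None, "support": 0}
            continue
        prec = tp[idx] / predicted[idx] if predicted[idx] > 0 else 0.0
        rec = tp[idx] / support[idx]
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        per_class[str(cls)] = {
            "precision": float(prec), "recall": float(rec),
            "f1": float(f1), "support": int(support[idx]),
        }
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
    macro_recall = float(np.mean(recalls))
    return {
        "accuracy": float(np.mean(y_true == y_pred)),
        "precision": float(np.mean(precisions)),
        "recall": macro_recall,
        "f1": float(np.mean(f1s)),
        "balanced_accuracy": macro_recall,
        "per_class": per_class,
    }


_METRIC_KEYS = ("accuracy", "precision", "recall", "f1", "balanced_accuracy")


@dataclass
class EvaluationReport:
    """Repeated-CV metric summary: mean +/- SD plus per-repetition traces."""

    scenario: str
    n_splits: int
    n_repeats: int
    seed: int
    mean: dict[str, float]
    sd: dict[str, float]
    traces: dict[str, list[float]]
    per_class: dict[str, dict]
    roc: dict | None = None
    notes: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "n_splits": self.n_splits,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "mean": self.mean,
            "sd": self.sd,
            "traces": self.traces,
            "per_class": self.per_class,
            "roc": self.roc,
            "notes": self.notes,
        }


def repeated_cv_evaluate(
    pipeline,
    X,
    y,
    n_splits: int = 8,
    n_repeats: int = 30,
    seed: int = 0,
    scenario: str = "",
) -> EvaluationReport:
    """Repeated stratified k-fold evaluation with per-repetition traces.

    Each repetition reshuffles the fold assignment; the out-of-fold
    predictions of one repetition are pooled into a single prediction
    vector before computing that repetition's metrics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_splits:
        raise ValueError(
            f"smallest class has {counts.min()} samples; needs >= {n_splits} "
            f"for {n_splits}-fold stratification"
        )
    rkf = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats,
                                  random_state=seed)
    traces: dict[str, list[float]] = {k: [] for k in _METRIC_KEYS}
    per_class_acc: dict[str, dict[str, list[float]]] = {}
    fold_preds = np.empty(y.shape, dtype=y.dtype)
    for fold_idx, (train, test) in enumerate(rkf.split(X, y)):
        model = clone(pipeline)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[train], y[train])
        fold_preds[test] = model.predict(X[test])
        if (fold_idx + 1) % n_splits == 0:  # repetition complete
            metrics = compute_metrics(y, fold_preds)
            for k in _METRIC_KEYS:
                traces[k].append(metrics[k])
            for cls, vals in metrics["per_class"].items():
                bucket = per_class_acc.setdefault(
                    cls, {"precision": [], "recall": [], "f1": []}
                )
                for m in ("precision", "recall", "f1"):
                    if vals[m] is not None:
                        bucket[m].append(vals[m])
    mean = {k: float(np.mean(v)) for k, v in traces.items()}
    sd = {k: float(np.std(v)) for k, v in traces.items()}
    per_class = {
        cls: {m: {"mean": float(np.mean(v)), "sd": float(np.std(v))}
              for m, v in buckets.items()}
        for cls, buckets in per_class_acc.items()
    }
    return EvaluationReport(
        scenario=scenario, n_splits=n_splits, n_repeats=n_repeats, seed=seed,
        mean=mean, sd=sd, traces=traces, per_class=per_class,
    )


def roc_auc_ovr(pipeline, X, y, k: int = 4, seed: int = 0) -> dict:
    """One-vs-rest ROC per class over stratified k-fold CV.

    The per-class AUC is the mean over the k folds.  Raises for pipelines
    without probability outputs (scenario III).
    """
    if not is_probabilistic(pipeline):
        raise ValueError(
            "ROC/AUC requires class-probability outputs; this pipeline is "
            "non-probabilistic (scenario III)"
        )
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    curves: dict[str, list] = {str(c): [] for c in classes}
    aucs: dict[str, list[float]] = {str(c): [] for c in classes}
    for train, test in skf.split(X, y):
        model = clone(pipeline)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[train], y[train])
        proba = model.predict_proba(X[test])
        model_classes = list(model.classes_)
        for cls in classes:
            scores = proba[:, model_classes.index(cls)]
            truth = (y[test] == cls).astype(int)
            if truth.min() == truth.max():
                continue  # fold without both outcomes
            fpr, tpr, thresholds = roc_curve(truth, scores)
            curves[str(cls)].append(
                {"fpr": fpr.tolist(), "tpr": tpr.tolist(),
                 "thresholds": thresholds.tolist()}
            )
            aucs[str(cls)].append(float(auc(fpr, tpr)))
    return {
        "k": k,
        "auc_mean": {c: float(np.mean(v)) for c, v in aucs.items() if v},
        "auc_per_fold": aucs,
        "curves": curves,
    }


def feature_importance(X, y, feature_names=None, seed: int = 0) -> dict:
    """Impurity-based importances from an extremely randomized trees
    ensemble; non-negative and summing to 1."""
    X = np.asarray(X, dtype=float)
    model = ExtraTreesClassifier(n_estimators=200, random_state=seed)
    model.fit(X, y)
    importances = model.feature_importances_
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    return {str(n): float(v) for n, v in zip(feature_names, importances)}
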