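"""Random-forest training, 10-fold cross-validated evaluation, and importances.

Metrics follow the standard confusion-matrix definitions: accuracy is the
correct fraction, precision TP/(TP+FP), recall TP/(TP+FN), F1 the harmonic
mean of precision and recall. Undefined ratios (zero denominators) are
reported as missing (None), never silently as zero.

Cross-validation shuffles stratified folds frame-wise by default, faithful
to the source protocol; adjacent frames share rolling-window state, so this
leaks temporal context between train and test folds. A grouped fold mode
(``StratifiedGroupKFold`` over caller-supplied group ids) is provided for
leakage-free evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .errors import ClassMissingError, SchemaError
from .labeling import LabeledDataset
from .preprocess import ID_COLUMNS

__all__ = [
    "DEFAULT_HYPERPARAMS",
    "ConfusionMatrix",
    "MetricsReport",
    "ImportanceRanking",
    "CVResult",
    "metrics_from_confusion",
    "confusion_from_predictions",
    "feature_matrix",
    "train_classifier",
    "cross_validate_10fold",
    "evaluate_holdout",
    "feature_importance",
    "plot_importance",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

#: Forest defaults (the source protocol leaves them unstated): 100 trees,
#: unlimited depth, sqrt(p) features per split.
DEFAULT_HYPERPARAMS: dict[str, object] = {
    "n_estimators": 100,
    "max_depth": None,
    "max_features": "sqrt",
}


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
            tn=self.tn + other.tn,
        )

    def as_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy/precision/recall/F1; None where the defining ratio is undefined."""

    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in self.as_dict().items()
        }

    def as_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


@dataclass
class ImportanceRanking:
    """Descending (feature, weight) pairs; weights are non-negative and sum to 1."""

    ranking: list[tuple[str, float]]

    def __post_init__(self) -> None:
        weights = [w for _, w in self.ranking]
        if any(w < 0 for w in weights):
            raise ValueError("importance weights must be non-negative")
        if weights and abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("importance weights must sum to 1")
        if any(weights[i] < weights[i + 1] for i in range(len(weights) - 1)):
            raise ValueError("ranking must be sorted descending")

    def top(self, k: int) -> list[str]:
        return [name for name, _ in self.ranking[:k]]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.ranking, columns=["feature", "importance"]).to_csv(
            path, index=False, lineterminator="\n"
        )


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall and F1 from confusion counts.

    Zero-denominator ratios come back as None; F1 is 0 when precision and
    recall are both defined and both zero.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    accuracy = (cm.tp + cm.tn) / cm.total
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else None
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    if precision is None or recall is None:
        f1 = None
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def feature_matrix(dataset: LabeledDataset) -> tuple[pd.DataFrame, np.ndarray]:
    """Model-ready (X, y) from a labeled dataset (id columns stripped)."""
    cols = [c for c in dataset.features.columns if c not in ID_COLUMNS]
    return dataset.features[cols], dataset.labels.astype(int)


def train_classifier(
    X: pd.DataFrame,
    y: np.ndarray,
    hyper: dict[str, object] | None = None,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit a random forest; deterministic under a fixed seed."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ClassMissingError("training requires both classes present")
    params = dict(DEFAULT_HYPERPARAMS)
    if hyper:
        params.update(hyper)
    model = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    model.fit(X, y)
    return model


@dataclass
class CVResult:
    """Everything a 10-fold cross-validation run produces."""

    fold_matrices: list[ConfusionMatrix]
    fold_metrics: list[MetricsReport]
    pooled_matrix: ConfusionMatrix
    pooled_metrics: MetricsReport
    models: list[RandomForestClassifier]
    feature_names: list[str]
    fold_mode: str = "frame"
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "fold_mode": self.fold_mode,
            "seed": self.seed,
            "pooled_confusion": self.pooled_matrix.as_dict(),
            "pooled_metrics": self.pooled_metrics.as_dict(),
            "pooled_metrics_2dp": self.pooled_metrics.rounded(2),
            "fold_confusions": [m.as_dict() for m in self.fold_matrices],
            "fold_metrics": [m.as_dict() for m in self.fold_metrics],
        }


def cross_validate_10fold(
    dataset: LabeledDataset,
    seed: int = 0,
    n_splits: int = 10,
    fold_mode: str = "frame",
    groups: np.ndarray | None = None,
    hyper: dict[str, object] | None = None,
) -> CVResult:
    """Stratified shuffled k-fold evaluation; each row is tested exactly once.

    The pooled confusion matrix is the element-wise sum of the per-fold test
    confusions, so pooled metric denominators are on the full-dataset scale.
    ``fold_mode="grouped"`` keeps rows sharing a group id in the same fold.
    """
    X, y = feature_matrix(dataset)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_splits:
        raise ValueError(f"need at least {n_splits} rows per class, got {counts.tolist()}")
    if fold_mode == "frame":
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y)
    elif fold_mode == "grouped":
        if groups is None:
            raise ValueError("grouped fold mode requires group ids")
        splitter = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y, groups=groups)
    else:
        raise ValueError(f"unknown fold mode {fold_mode!r}")

    fold_matrices: list[ConfusionMatrix] = []
    fold_metrics: list[MetricsReport] = []
    models: list[RandomForestClassifier] = []
    tested = np.zeros(len(y), dtype=bool)
    for train_idx, test_idx in split_iter:
        model = train_classifier(X.iloc[train_idx], y[train_idx], hyper=hyper, seed=seed)
        pred = model.predict(X.iloc[test_idx])
        cm = confusion_from_predictions(y[test_idx], pred)
        fold_matrices.append(cm)
        fold_metrics.append(metrics_from_confusion(cm))
        models.append(model)
        tested[test_idx] = True
    assert tested.all(), "k-fold split failed to test every row"
    pooled = fold_matrices[0]
    for cm in fold_matrices[1:]:
        pooled = pooled + cm
    return CVResult(
        fold_matrices=fold_matrices,
        fold_metrics=fold_metrics,
        pooled_matrix=pooled,
        pooled_metrics=metrics_from_confusion(pooled),
        models=models,
        feature_names=list(X.columns),
        fold_mode=fold_mode,
        seed=seed,
    )


def evaluate_holdout(
    model: RandomForestClassifier, dataset: LabeledDataset
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Score an already-trained model on a holdout set in a single pass (no refit)."""
    X, y = feature_matrix(dataset)
    if len(X) == 0:
        raise ValueError("holdout dataset is empty")
    expected = list(getattr(model, "feature_names_in_", []))
    if expected and list(X.columns) != expected:
        raise SchemaError(
            "holdout feature columns do not match the model's training schema"
        )
    cm = confusion_from_predictions(y, model.predict(X))
    return cm, metrics_from_confusion(cm)


def feature_importance(
    models: list[RandomForestClassifier], feature_names: list[str]
) -> ImportanceRanking:
    """Impurity importances averaged over fold models, normalized and ranked."""
    if not models:
        raise ValueError("no trained models supplied")
    mats = []
    for model in models:
        if not hasattr(model, "feature_importances_"):
            raise ValueError("model is not trained")
        mats.append(model.feature_importances_)
    mean_imp = np.mean(mats, axis=0)
    total = mean_imp.sum()
    if total > 0:
        mean_imp = mean_imp / total
    order = np.argsort(mean_imp)[::-1]
    return ImportanceRanking(
        ranking=[(feature_names[i], float(mean_imp[i])) for i in order]
    )


def plot_importance(ranking: ImportanceRanking, path: str | Path, top_k: int = 25) -> None:
    """Horizontal bar chart of the top-k importances (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = ranking.ranking[:top_k][::-1]
    names = [p[0] for p in pairs]
    weights = [p[1] for p in pairs]
    fig, ax = plt.subplots(figsize=(8, max(3, 0.3 * len(pairs))))
    ax.barh(names, weights, color="#4878a8")
    ax.set_xlabel("normalized importance")
    ax.set_title("Random-forest feature importance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_model(model: RandomForestClassifier, feature_names: list[str], path: str | Path) -> None:
    joblib.dump(
        {"format_version": MODEL_FORMAT_VERSION, "model": model, "feature_names": feature_names},
        path,
    )


def load_model(path: str | Path) -> tuple[RandomForestClassifier, list[str]]:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise SchemaError("unsupported model file version")
    return payload["model"], payload["feature_names"]
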