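"""SVM-RBF pain-quartile classification and confusion-matrix reporting.

Windows (35 band-power features each) are classified into the four pain
quartiles with a support vector machine using a Gaussian radial-basis
kernel. Hyperparameters (cost C, kernel width gamma) are chosen by an
inner cross-validated grid search on training data only; features are
standardized with statistics from the training folds.

Every window receives exactly one out-of-fold prediction, under one of
two schemes:

* ``window`` (default): stratified k-fold over windows. This mirrors
  the evaluation the target confusion matrix implies (row totals equal
  the full dataset), but windows of one session share a subject, so
  window-level folds leak subject identity and inflate accuracy.
* ``session``: leave-one-session-out; a window's model never saw any
  window of its session. The leakage-safe alternative.

Reports derive from the 4x4 truth-by-prediction confusion matrix:
precision (column-wise), recall (row-wise), F1, and overall accuracy
(trace/total). A class never predicted has undefined precision, which
is reported as None (not zero). Session-level predictions are the
majority vote over a session's 10 windows, ties broken toward the more
severe class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.model_selection import (
    GridSearchCV,
    LeaveOneGroupOut,
    StratifiedKFold,
    cross_val_predict,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import FoldError, LabelError, StatsError
from .pain import CLASS_ORDER, PainQuartile, nrs_to_quartile  # noqa: F401  (re-export)
from .spectral import FeatureDataset

__all__ = [
    "ClassifierConfig",
    "ConfusionMatrix",
    "ClassificationReport",
    "nrs_to_quartile",
    "fit_svm",
    "cross_validated_predictions",
    "confusion_matrix",
    "report_metrics",
    "session_level_predictions",
]


@dataclass
class ClassifierConfig:
    """SVM-RBF training and evaluation parameters."""

    cost_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple = ("scale", 0.01, 0.1, 1.0)
    standardize_features: bool = True
    cv_scheme: str = "window"  # "window" | "session"
    n_folds: int = 10
    inner_folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not self.cost_grid or not all(c > 0 for c in self.cost_grid):
            raise FoldError("cost_grid must be a nonempty sequence of positive reals")
        if not self.gamma_grid:
            raise FoldError("gamma_grid must be nonempty")
        for g in self.gamma_grid:
            if g != "scale" and not (isinstance(g, (int, float)) and g > 0):
                raise FoldError(f"gamma_grid entries must be positive or 'scale', got {g!r}")
        if self.n_folds < 2 or self.inner_folds < 2:
            raise FoldError("n_folds and inner_folds must be >= 2")
        if self.cv_scheme not in ("window", "session"):
            raise FoldError(f"cv_scheme must be 'window' or 'session', got {self.cv_scheme!r}")


def _make_estimator(config: ClassifierConfig) -> GridSearchCV:
    steps = []
    if config.standardize_features:
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", SVC(kernel="rbf", decision_function_shape="ovr", random_state=config.seed)))
    grid = {"svm__C": list(config.cost_grid), "svm__gamma": list(config.gamma_grid)}
    inner = StratifiedKFold(n_splits=config.inner_folds, shuffle=True, random_state=config.seed)
    return GridSearchCV(Pipeline(steps), grid, cv=inner, n_jobs=None)


def fit_svm(features, labels=None, config: ClassifierConfig | None = None):
    """Fit the SVM with inner-CV hyperparameter selection.

    ``features`` may be a FeatureDataset (labels taken from it) or an
    (n, p) array with ``labels`` supplied. Returns the fitted
    GridSearchCV estimator; deterministic for fixed config seed.
    """
    config = config or ClassifierConfig()
    config.validate()
    if isinstance(features, FeatureDataset):
        X, y = features.features, features.labels
    else:
        X, y = np.asarray(features, dtype=float), np.asarray(labels, dtype=object)
    if y is None or len(np.unique(y)) < 2:
        raise StatsError("training data must contain at least two classes")
    if not np.all(np.isfinite(X)):
        raise StatsError("features must be finite")
    return _make_estimator(config).fit(X, y)


def cross_validated_predictions(
    dataset: FeatureDataset, config: ClassifierConfig | None = None
) -> pd.DataFrame:
    """Out-of-fold quartile prediction for every window.

    Returns the dataset's metadata plus a ``prediction`` column; each
    prediction comes from a model that never saw that window (window
    scheme) or that window's whole session (session scheme).
    """
    config = config or ClassifierConfig()
    config.validate()
    X, y = dataset.features, dataset.labels
    if config.cv_scheme == "window":
        _, class_counts = np.unique(y, return_counts=True)
        if class_counts.min() < config.n_folds:
            raise FoldError(
                f"stratified {config.n_folds}-fold needs >= {config.n_folds} windows per "
                f"class; smallest class has {class_counts.min()}"
            )
        splitter = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed
        )
        splits = splitter.split(X, y)
    else:
        splitter = LeaveOneGroupOut()
        splits = splitter.split(X, y, groups=dataset.session_keys)
    predictions = cross_val_predict(_make_estimator(config), X, y, cv=list(splits))
    out = dataset.frame[["subject_id", "phase", "window_index", "nrs", "quartile"]].copy()
    out["prediction"] = predictions
    return out


@dataclass
class ConfusionMatrix:
    """4x4 truth-by-prediction counts in fixed class order."""

    counts: np.ndarray
    class_order: list[str] = field(default_factory=lambda: list(CLASS_ORDER))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise LabelError(f"confusion matrix must be {k}x{k}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise LabelError("confusion matrix entries must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_order, columns=self.class_order)


def confusion_matrix(truth, predicted) -> ConfusionMatrix:
    """Count truth (rows) vs predicted (columns) in fixed class order."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise LabelError(f"truth has {len(truth)} entries but predicted has {len(predicted)}")
    if not truth:
        counts = np.zeros((len(CLASS_ORDER), len(CLASS_ORDER)), dtype=int)
    else:
        counts = skmetrics.confusion_matrix(truth, predicted, labels=CLASS_ORDER)
    return ConfusionMatrix(counts=counts)


@dataclass
class ClassificationReport:
    """Per-class precision/recall/F1 and overall accuracy.

    Metrics for a class that was never predicted (precision) or never
    present (recall) are None, not zero.
    """

    matrix: ConfusionMatrix
    precision: dict[str, float | None]
    recall: dict[str, float | None]
    f1: dict[str, float | None]
    overall_accuracy: float
    n_total: int

    def to_dict(self) -> dict:
        return {
            "class_order": self.matrix.class_order,
            "confusion_matrix": self.matrix.counts.tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "overall_accuracy": self.overall_accuracy,
            "n_total": self.n_total,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, **kwargs)


def report_metrics(matrix: ConfusionMatrix) -> ClassificationReport:
    """Derive precision, recall, F1 and accuracy from a confusion matrix.

    precision(c) = diagonal / column sum; recall(c) = diagonal / row
    sum; F1 is their harmonic mean; accuracy = trace / total.
    """
    counts = matrix.counts
    total = matrix.total
    if total == 0:
        raise LabelError("cannot compute metrics from an all-zero confusion matrix")
    precision: dict[str, float | None] = {}
    recall: dict[str, float | None] = {}
    f1: dict[str, float | None] = {}
    for i, label in enumerate(matrix.class_order):
        col = counts[:, i].sum()
        row = counts[i, :].sum()
        p = counts[i, i] / col if col else None
        r = counts[i, i] / row if row else None
        precision[label], recall[label] = p, r
        if p is None or r is None or (p + r) == 0:
            f1[label] = None
        else:
            f1[label] = 2 * p * r / (p + r)
    return ClassificationReport(
        matrix=matrix,
        precision=precision,
        recall=recall,
        f1=f1,
        overall_accuracy=float(np.trace(counts)) / total,
        n_total=total,
    )


def session_level_predictions(
    window_predictions: pd.DataFrame, expected_windows: int = 10
) -> pd.DataFrame:
    """Majority-vote session predictions from window predictions.

    One row per (subject_id, phase): truth quartile, voted prediction,
    and a discrepancy flag. Ties break toward the more severe class
    (clinically conservative). Sessions missing windows raise.
    """
    required = {"subject_id", "phase", "nrs", "quartile", "prediction"}
    missing = required - set(window_predictions.columns)
    if missing:
        raise LabelError(f"window predictions missing columns: {sorted(missing)}")
    severity = {label: i for i, label in enumerate(CLASS_ORDER)}
    rows = []
    for (subject_id, phase), group in window_predictions.groupby(
        ["subject_id", "phase"], sort=True
    ):
        if expected_windows is not None and len(group) != expected_windows:
            raise LabelError(
                f"session {subject_id}/{phase} has {len(group)} window predictions; "
                f"expected {expected_windows}"
            )
        votes = group["prediction"].value_counts()
        top = votes[votes == votes.max()].index
        vote = max(top, key=severity.get)  # tie-break: most severe
        truth = group["quartile"].iloc[0]
        rows.append(
            {
                "subject_id": subject_id,
                "phase": phase,
                "nrs": int(group["nrs"].iloc[0]),
                "truth": truth,
                "prediction": vote,
                "discrepancy": vote != truth,
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "phase", "nrs", "truth", "prediction", "discrepancy"])
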