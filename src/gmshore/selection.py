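"""Fisher-score / LOOCV consensus feature selection and SVM evaluation.

The three-step procedure:

1. For every leave-one-out fold, Fisher scores of all N features are
   computed on the training subjects only and the features ranked; for
   each cutoff n = 1..N a linear SVM (libsvm SMO, cost C, training-fold
   standardization) classifies the held-out subject.  This yields the
   mean and variance of LOOCV accuracy per n plus one ranking per fold
   (replicated across the N cutoffs, i.e. the N x M tested models).
2. n_opt scans n upward, updating whenever accuracy is greater-or-equal
   AND variance is less-or-equal to the incumbent.
3. The n_opt features occurring most often within the first n_opt ranking
   positions across all folds feed a final LOOCV SVM, reported as a
   confusion matrix with accuracy / sensitivity / specificity / precision
   (positive class RRMS) and a ROC curve with trapezoid AUC.

Everything is deterministic given the feature table: the LOOCV fold
order is the table's row order and tie-breaks are fixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.svm import SVC

__all__ = [
    "DEFAULT_COST",
    "SelectionResult",
    "ClassifierReport",
    "fisher_scores",
    "train_linear_svm",
    "step1_accuracy_curve",
    "step2_select_n_opt",
    "step3_consensus",
    "optimize_cost",
    "cost_grid",
    "final_report",
    "run_selection",
]

log = logging.getLogger(__name__)

#: Published SVM cost used throughout.
DEFAULT_COST = 0.4662

POSITIVE_CLASS = "RRMS"
NEGATIVE_CLASS = "PPMS"


def fisher_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fisher score per feature: between-class over within-class scatter.

    F_j = sum_c n_c (mu_cj - mu_j)^2 / sum_c n_c s2_cj with sample (n-1)
    class variances.  A feature constant within both classes scores 0 if
    the class means also agree, +inf otherwise (ranked first).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("fisher_scores requires both classes present")
    mu = x.mean(axis=0)
    num = np.zeros(x.shape[1])
    den = np.zeros(x.shape[1])
    for c in classes:
        xc = x[y == c]
        if xc.shape[0] < 2:
            raise ValueError("need >= 2 subjects per class")
        num += xc.shape[0] * (xc.mean(axis=0) - mu) ** 2
        den += xc.shape[0] * xc.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = num / den
    scores[(den == 0) & (num == 0)] = 0.0
    scores[(den == 0) & (num > 0)] = np.inf
    return scores


class _Standardizer:
    """Zero-mean unit-variance transform with training statistics only.

    Zero-variance features map to 0 with a warning.
    """

    def __init__(self, x_train: np.ndarray):
        self.mean = x_train.mean(axis=0)
        self.sd = x_train.std(axis=0, ddof=0)
        self._zero = self.sd == 0
        if self._zero.any():
            warnings.warn(
                f"{int(self._zero.sum())} zero-variance feature(s) standardized to 0",
                stacklevel=2,
            )

    def __call__(self, x: np.ndarray) -> np.ndarray:
        out = (x - self.mean) / np.where(self._zero, 1.0, self.sd)
        if self._zero.any():
            out[:, self._zero] = 0.0
        return out


def train_linear_svm(x_train: np.ndarray, y_train: np.ndarray, cost: float = DEFAULT_COST):
    """Soft-margin linear SVM with training-fold standardization.

    Returns a callable with ``predict(x)`` and ``decision(x)`` operating
    on unstandardized inputs; decision values are signed toward the
    positive (RRMS) class.
    """
    if cost <= 0:
        raise ValueError("cost must be positive")
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("training data must contain two classes")
    scale = _Standardizer(x_train)
    svm = SVC(kernel="linear", C=cost)
    svm.fit(scale(x_train), y_train)
    sign = 1.0 if svm.classes_[-1] == POSITIVE_CLASS or POSITIVE_CLASS not in svm.classes_ else -1.0

    class _Model:
        classes_ = svm.classes_

        @staticmethod
        def predict(x):
            return svm.predict(scale(np.asarray(x, dtype=float)))

        @staticmethod
        def decision(x):
            return sign * svm.decision_function(scale(np.asarray(x, dtype=float)))

    return _Model()


@dataclass
class SelectionResult:
    """Step 1-3 outputs: rankings, accuracy curve, n_opt, consensus."""

    rankings: np.ndarray            # (folds, N) feature indices, best first
    feature_names: list[str]
    accuracy: np.ndarray            # mean LOOCV accuracy per n (1-based n)
    variance: np.ndarray            # sample variance of the 0/1 outcomes per n
    n_opt: int = 0
    occurrence_counts: dict = field(default_factory=dict)
    selected: list[str] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        """The N x M accounting of tested models (rankings replicated over n)."""
        return self.rankings.shape[0] * self.accuracy.shape[0]

    def occurrence_counts_replicated(self) -> dict:
        """Counts under the N x M accounting (each fold tally times N)."""
        n = self.accuracy.shape[0]
        return {k: v * n for k, v in self.occurrence_counts.items()}


def _loo_folds(n: int):
    idx = np.arange(n)
    for i in range(n):
        yield np.delete(idx, i), np.array([i])


def step1_accuracy_curve(table, cost: float = DEFAULT_COST,
                         n_max: int | None = None) -> SelectionResult:
    """LOOCV accuracy versus number of top-Fisher features.

    For each fold the Fisher ranking is computed on the training
    subjects; the ranking is independent of the cutoff n, so it is stored
    once per fold.  ``n_max`` caps the sweep for scaled-down runs.
    """
    x, y = table.x, table.y
    names = table.feature_names
    m, n_feat = x.shape
    if m < 4:
        raise ValueError("need at least 4 subjects for LOOCV selection")
    n_sweep = n_feat if n_max is None else min(n_max, n_feat)

    rankings = np.empty((m, n_feat), dtype=int)
    outcomes = np.empty((m, n_sweep))
    for fold, (tr, te) in enumerate(_loo_folds(m)):
        scores = fisher_scores(x[tr], y[tr])
        # stable sort: descending score, ties by column order
        order = np.argsort(-scores, kind="stable")
        rankings[fold] = order
        scale = _Standardizer(x[tr])
        xtr_s = scale(x[tr])
        xte_s = scale(x[te])
        for n in range(1, n_sweep + 1):
            cols = order[:n]
            svm = SVC(kernel="linear", C=cost)
            svm.fit(xtr_s[:, cols], y[tr])
            pred = svm.predict(xte_s[:, cols])
            outcomes[fold, n - 1] = float(pred[0] == y[te][0])
    accuracy = outcomes.mean(axis=0)
    variance = outcomes.var(axis=0, ddof=1)
    return SelectionResult(rankings=rankings, feature_names=list(names),
                           accuracy=accuracy, variance=variance)


def step2_select_n_opt(accuracy: np.ndarray, variance: np.ndarray) -> int:
    """Scan n upward; update on accuracy >= best AND variance <= best."""
    accuracy = np.asarray(accuracy, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if accuracy.size == 0 or accuracy.shape != variance.shape:
        raise ValueError("accuracy and variance curves must be equal-length, non-empty")
    best_acc, best_var = accuracy[0], variance[0]
    n_opt = 1
    for n in range(2, accuracy.size + 1):
        if accuracy[n - 1] >= best_acc and variance[n - 1] <= best_var:
            best_acc, best_var = accuracy[n - 1], variance[n - 1]
            n_opt = n
    return n_opt


def step3_consensus(rankings: np.ndarray, n_opt: int,
                    feature_names: list[str]) -> tuple[list[str], dict]:
    """Most frequent features within the first n_opt ranking positions.

    Ties break toward the better (lower) mean ranking position, then
    lexicographic feature name.  Returns (selected names, counts).
    """
    rankings = np.asarray(rankings)
    n_folds, n_feat = rankings.shape
    if n_folds < 1:
        raise ValueError("need at least one ranking")
    if not 1 <= n_opt <= n_feat:
        raise ValueError(f"n_opt={n_opt} outside [1, {n_feat}]")
    counts = np.zeros(n_feat, dtype=int)
    top = rankings[:, :n_opt]
    np.add.at(counts, top.ravel(), 1)
    # mean ranking position per feature (lower = better)
    positions = np.empty_like(rankings)
    np.put_along_axis(positions, rankings, np.arange(n_feat)[None, :].repeat(n_folds, 0), axis=1)
    mean_pos = positions.mean(axis=0)
    order = sorted(range(n_feat),
                   key=lambda j: (-counts[j], mean_pos[j], feature_names[j]))
    selected = [feature_names[j] for j in order[:n_opt]]
    count_map = {feature_names[j]: int(counts[j]) for j in range(n_feat)}
    return selected, count_map


def cost_grid() -> np.ndarray:
    """100 evenly spaced SVM costs from 0.0005 to 512."""
    return np.linspace(0.0005, 512.0, 100)


def _loocv_outcomes(x, y, cost):
    outcomes = np.empty(len(y))
    decisions = np.empty(len(y))
    for fold, (tr, te) in enumerate(_loo_folds(len(y))):
        model = train_linear_svm(x[tr], y[tr], cost)
        outcomes[fold] = float(model.predict(x[te])[0] == y[te][0])
        decisions[fold] = model.decision(x[te])[0]
    return outcomes, decisions


def optimize_cost(table, grid: np.ndarray | None = None) -> float:
    """Cost maximizing all-feature LOOCV accuracy; ties take the smallest."""
    grid = cost_grid() if grid is None else np.asarray(grid, dtype=float)
    x, y = table.x, table.y
    best_c, best_acc = None, -1.0
    for c in grid:
        acc = _loocv_outcomes(x, y, float(c))[0].mean()
        if acc > best_acc:  # strict: first (smallest) grid value wins ties
            best_acc, best_c = acc, float(c)
    return best_c


@dataclass
class ClassifierReport:
    """LOOCV confusion matrix, headline metrics, and ROC curve."""

    confusion: np.ndarray          # rows true (PPMS, RRMS), cols predicted
    accuracy: float
    sensitivity: float             # RRMS recall
    specificity: float             # PPMS recall
    precision: float               # RRMS precision
    roc: np.ndarray                # (points, 2): FPR, TPR
    auc: float

    @classmethod
    def from_predictions(cls, y_true, y_pred, decision_values) -> "ClassifierReport":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        conf = np.zeros((2, 2), dtype=int)
        for i, true_label in enumerate((NEGATIVE_CLASS, POSITIVE_CLASS)):
            for j, pred_label in enumerate((NEGATIVE_CLASS, POSITIVE_CLASS)):
                conf[i, j] = int(np.sum((y_true == true_label) & (y_pred == pred_label)))
        return cls.from_confusion(conf, y_true=y_true, decision_values=decision_values)

    @classmethod
    def from_confusion(cls, conf, y_true=None, decision_values=None) -> "ClassifierReport":
        conf = np.asarray(conf, dtype=int)
        tn, fp = conf[0]            # true PPMS row
        fn, tp = conf[1]            # true RRMS row
        total = conf.sum()
        accuracy = (tn + tp) / total
        sensitivity = tp / (tp + fn) if tp + fn else float("nan")
        specificity = tn / (tn + fp) if tn + fp else float("nan")
        precision = tp / (tp + fp) if tp + fp else float("nan")
        if y_true is not None and decision_values is not None:
            fpr, tpr, _ = _roc_curve(y_true, decision_values, pos_label=POSITIVE_CLASS)
            roc = np.column_stack([fpr, tpr])
            area = float(_trapezoid_auc(fpr, tpr))
        else:
            roc = np.empty((0, 2))
            area = float("nan")
        return cls(confusion=conf, accuracy=float(accuracy),
                   sensitivity=float(sensitivity), specificity=float(specificity),
                   precision=float(precision), roc=roc, auc=area)


def final_report(table, selected: list[str], cost: float = DEFAULT_COST) -> ClassifierReport:
    """LOOCV evaluation of the SVM restricted to the selected features."""
    if len(selected) < 1:
        raise ValueError("need at least one selected feature")
    missing = [f for f in selected if f not in table.feature_names]
    if missing:
        raise ValueError(f"selected features absent from table: {missing[:5]}")
    x = table.data[selected].to_numpy(dtype=float)
    y = table.y
    preds = np.empty(len(y), dtype=object)
    decisions = np.empty(len(y))
    for fold, (tr, te) in enumerate(_loo_folds(len(y))):
        model = train_linear_svm(x[tr], y[tr], cost)
        preds[fold] = model.predict(x[te])[0]
        decisions[fold] = model.decision(x[te])[0]
    return ClassifierReport.from_predictions(y, preds, decisions)


def run_selection(table, cost: float = DEFAULT_COST,
                  n_max: int | None = None) -> tuple[SelectionResult, ClassifierReport]:
    """The full three-step procedure plus the final classifier report."""
    result = step1_accuracy_curve(table, cost=cost, n_max=n_max)
    result.n_opt = step2_select_n_opt(result.accuracy, result.variance)
    result.selected, result.occurrence_counts = step3_consensus(
        result.rankings, result.n_opt, result.feature_names
    )
    report = final_report(table, result.selected, cost=cost)
    return result, report
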