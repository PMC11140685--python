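"""Network classification from time-series features.

Parcels are classified into networks with a linear maximum-margin
(one-vs-rest) classifier under stratified k-fold cross-validation.
Performance is summarized as balanced accuracy (macro-averaged per-class
recall — the multiclass generalization of the mean of sensitivity and
specificity), assessed against a label-permutation null, and the
row-normalized confusion matrix doubles as a data-driven network
similarity measure: the probability that parcels of one network are
mistaken for another.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

__all__ = [
    "ClassificationResult",
    "cv_classify",
    "balanced_accuracy",
    "permutation_null",
    "confusion_probabilities",
    "misclassification_contrast",
    "feature_subset_curve",
]


@dataclass
class ClassificationResult:
    """Cross-validated predictions in original sample order."""

    y_true: np.ndarray
    y_pred: np.ndarray
    balanced_accuracy: float
    k_folds: int
    null_distribution: np.ndarray | None = None
    p_value: float | None = None


def _make_classifier(C: float = 1.0, seed: int = 0) -> LinearSVC:
    # one-vs-rest linear SVM; features are already in [0, 1] so no
    # re-standardization is applied
    return LinearSVC(C=C, dual="auto", random_state=seed, max_iter=5000)


def balanced_accuracy(y_true, y_pred) -> float:
    """Macro-averaged per-class recall over classes present in y_true."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape[0] == 0 or y_true.shape != y_pred.shape:
        raise ValueError("need equal-length, nonempty label vectors")
    recalls = []
    for cls in np.unique(y_true):
        mask = y_true == cls
        recalls.append(np.mean(y_pred[mask] == cls))
    return float(np.mean(recalls))


def cv_classify(
    X: np.ndarray,
    y: np.ndarray,
    k_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> ClassificationResult:
    """Stratified k-fold CV with a linear one-vs-rest SVM (C = 1).

    Runs of one subject should be concatenated as samples before calling.
    If the smallest class has fewer samples than ``k_folds`` the fold count
    is reduced (with a warning from scikit-learn suppressed into a hard
    reduction here).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("degenerate labels")
    k = int(min(k_folds, counts.min()))
    if k < 2:
        raise ValueError("not enough samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    for fold_idx, (train, test) in enumerate(skf.split(X, y)):
        clf = _make_classifier(C=C, seed=seed)
        clf.fit(X[train], y[train])
        y_pred[test] = clf.predict(X[test])
    return ClassificationResult(
        y_true=y.copy(),
        y_pred=y_pred,
        balanced_accuracy=balanced_accuracy(y, y_pred),
        k_folds=k,
    )


def permutation_null(
    X: np.ndarray,
    y: np.ndarray,
    k_folds: int = 5,
    n_permutations: int = 1000,
    seed: int = 0,
    C: float = 1.0,
) -> ClassificationResult:
    """Label-permutation null for the cross-validated balanced accuracy.

    Labels are shuffled over the pooled samples, the full CV is re-run per
    permutation, and p = (1 + #{null >= observed}) / (1 + n_permutations).
    """
    if n_permutations < 100:
        import warnings

        warnings.warn("fewer than 100 permutations gives an unstable p", stacklevel=2)
    observed = cv_classify(X, y, k_folds=k_folds, seed=seed, C=C)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    y = np.asarray(y)
    for i in range(n_permutations):
        y_perm = rng.permutation(y)
        null[i] = cv_classify(X, y_perm, k_folds=k_folds, seed=seed, C=C).balanced_accuracy
    p = (1.0 + np.sum(null >= observed.balanced_accuracy)) / (1.0 + n_permutations)
    observed.null_distribution = null
    observed.p_value = float(p)
    return observed


def confusion_probabilities(y_true, y_pred, labels=None) -> np.ndarray:
    """Row-normalized K x K confusion matrix (rows = true class).

    Classes with no samples in y_true get NaN rows.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    labels = np.asarray(labels)
    k = labels.size
    counts = np.zeros((k, k))
    index = {lab: i for i, lab in enumerate(labels.tolist())}
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / row_sums
    probs[row_sums[:, 0] == 0] = np.nan
    return probs


def misclassification_contrast(
    confusions: list[np.ndarray], target: int, comparator1: int, comparator2: int
) -> dict:
    """Paired t-test across subjects on P(target -> c1) - P(target -> c2).

    Subjects with a missing target row are excluded pairwise.  Returns a
    stat-table row dict (t, df, p, effect, n).
    """
    diffs = []
    for cm in confusions:
        a = cm[target, comparator1]
        b = cm[target, comparator2]
        if np.isfinite(a) and np.isfinite(b):
            diffs.append(a - b)
    diffs = np.asarray(diffs)
    if diffs.size < 3:
        raise ValueError("need at least 3 subjects with valid confusion rows")
    if np.allclose(diffs.std(), 0.0):
        t = 0.0 if np.allclose(diffs.mean(), 0.0) else np.sign(diffs.mean()) * np.inf
        p = 1.0 if t == 0.0 else 1e-10
    else:
        t, p = stats.ttest_1samp(diffs, 0.0)
    return {
        "contrast": f"P({target}->{comparator1}) - P({target}->{comparator2})",
        "t": float(t),
        "df": int(diffs.size - 1),
        "p": float(p),
        "effect": float(diffs.mean()),
        "n": int(diffs.size),
    }


def feature_subset_curve(
    X: np.ndarray,
    y: np.ndarray,
    subset_sizes: list[int],
    k_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> dict[int, float]:
    """Balanced accuracy as a function of feature-subset size.

    Features are ranked by the summed absolute one-vs-rest weight across
    classes from a full-catalog fit; CV is re-run on each top-k subset.
    """
    X = np.asarray(X, dtype=float)
    if any(s <= 0 for s in subset_sizes):
        raise ValueError("subset sizes must be positive")
    if any(s > X.shape[1] for s in subset_sizes):
        raise ValueError("subset size exceeds feature count")
    clf = _make_classifier(C=C, seed=seed)
    clf.fit(X, np.asarray(y))
    importance = np.abs(np.atleast_2d(clf.coef_)).sum(axis=0)
    order = np.argsort(importance)[::-1]
    curve: dict[int, float] = {}
    for s in subset_sizes:
        cols = np.sort(order[:s]) if s < X.shape[1] else np.arange(X.shape[1])
        res = cv_classify(X[:, cols], y, k_folds=k_folds, seed=seed, C=C)
        curve[int(s)] = res.balanced_accuracy
    return curve
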