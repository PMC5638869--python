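"""Cross-validated scoring of feature subsets.

A candidate subset is scored by stratified, randomly seeded k-fold
cross-validation: for each seed the positive and negative samples are
independently split into k near-equal folds, every registered classifier
is trained on k-1 folds and predicts the held-out fold, confusion counts
are pooled over folds within a run, run-level metrics are averaged over
seeds, and the headline number ``mAcc`` is the maximum averaged accuracy
over the classifier set.

Classifiers are pluggable through :data:`CLASSIFIER_REGISTRY`; the five
stock entries (SVM, KNN, DTree, NBayes, LR) wrap the host ML library
with default hyperparameters.  An additional ``LDA`` entry is a compact
ridge-regularised linear discriminant implemented in numpy — orders of
magnitude faster per fit, intended for the inner search loop where tens
of thousands of subset evaluations are needed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .dataset_io import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "PerformanceReport",
    "FoldAssignment",
    "StratificationError",
    "stratified_kfold",
    "compute_metrics",
    "evaluate_subset",
    "make_subset_evaluator",
    "CLASSIFIER_REGISTRY",
    "DEFAULT_CLASSIFIERS",
]

METRIC_NAMES = ("Sn", "Sp", "Acc", "Precision", "Fscore")


class StratificationError(ValueError):
    """Too few samples in a class for the requested fold count."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    FN: int = 0
    FP: int = 0
    TN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.FP, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FN + other.FN,
            self.FP + other.FP, self.TN + other.TN,
        )


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, precision and F-score.

    Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total,
    Precision = TP/(TP+FP), Fscore = 2*Precision*Sn/(Precision+Sn).
    Degenerate denominators yield 0.
    """
    tp, fn, fp, tn = c.TP, c.FN, c.FP, c.TN
    total = tp + fn + fp + tn
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / total if total else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    fscore = (
        2.0 * precision * sn / (precision + sn) if precision + sn else 0.0
    )
    return {"Sn": sn, "Sp": sp, "Acc": acc, "Precision": precision, "Fscore": fscore}


@dataclass(frozen=True)
class FoldAssignment:
    """Per-sample fold indices (0-based), stratified within each class."""

    fold_of_sample: np.ndarray
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return self._splits()[fold][1]

    def train_indices(self, fold: int) -> np.ndarray:
        return self._splits()[fold][0]

    def _splits(self) -> tuple[tuple[np.ndarray, np.ndarray], ...]:
        # cached (train, test) index pairs; hot path of the search loop
        cached = getattr(self, "_splits_cache", None)
        if cached is None:
            cached = tuple(
                (
                    np.flatnonzero(self.fold_of_sample != fold),
                    np.flatnonzero(self.fold_of_sample == fold),
                )
                for fold in range(self.k)
            )
            object.__setattr__(self, "_splits_cache", cached)
        return cached


def stratified_kfold(labels: np.ndarray, k: int, seed: int) -> FoldAssignment:
    """Split positives and negatives independently into k near-equal folds.

    Within each class the fold sizes differ by at most one.  The
    assignment is a deterministic function of ``(labels, k, seed)``.
    """
    labels = np.asarray(labels, dtype=bool)
    if k < 2:
        raise StratificationError(f"k must be >= 2, got {k}")
    if k == labels.size:
        # leave-one-out: one sample per fold, independent of the seed
        return FoldAssignment(
            fold_of_sample=np.arange(labels.size), k=k, seed=seed
        )
    p, n = int(labels.sum()), int((~labels).sum())
    if min(p, n) < k:
        raise StratificationError(
            f"min(P, N) = {min(p, n)} < k = {k}; use a smaller k"
        )
    rng = np.random.default_rng(seed)
    fold_of_sample = np.empty(labels.size, dtype=int)
    for cls in (True, False):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        # chunk sizes: first (len % k) folds take the extra sample
        fold_ids = np.repeat(np.arange(k), np.diff(
            np.round(np.linspace(0, idx.size, k + 1)).astype(int)))
        fold_of_sample[idx] = fold_ids
    return FoldAssignment(fold_of_sample=fold_of_sample, k=k, seed=seed)


# --------------------------------------------------------------------------
# classifier plug-ins
# --------------------------------------------------------------------------

class _RidgeLDA:
    """Fisher linear discriminant with a ridge-stabilised pooled covariance.

    Pure-numpy train/predict; used as a fast search-phase classifier.
    """

    def __init__(self, alpha: float = 1e-3):
        self.alpha = alpha
        self._w: np.ndarray | None = None
        self._b: float = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_RidgeLDA":
        y = np.asarray(y, dtype=bool)
        X1, X0 = X[y], X[~y]
        mu1, mu0 = X1.mean(axis=0), X0.mean(axis=0)
        d = X.shape[1]
        cov = np.zeros((d, d))
        for Xc, mu in ((X1, mu1), (X0, mu0)):
            centred = Xc - mu
            cov += centred.T @ centred
        cov /= max(X.shape[0] - 2, 1)
        ridge = self.alpha * (np.trace(cov) / d + 1e-12)
        cov[np.diag_indices(d)] += ridge
        self._w = np.linalg.solve(cov, mu1 - mu0)
        self._b = float(self._w @ (mu1 + mu0)) / 2.0
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (X @ self._w > self._b).astype(int)


def _make_svm(seed: int):
    from sklearn.svm import SVC
    return SVC(random_state=seed)


def _make_knn(seed: int):
    from sklearn.neighbors import KNeighborsClassifier
    return KNeighborsClassifier()


def _make_dtree(seed: int):
    from sklearn.tree import DecisionTreeClassifier
    return DecisionTreeClassifier(random_state=seed)


def _make_nbayes(seed: int):
    from sklearn.naive_bayes import GaussianNB
    return GaussianNB()


def _make_lr(seed: int):
    from sklearn.linear_model import LogisticRegression
    return LogisticRegression()


#: name -> factory(seed) -> estimator with fit(X, y)/predict(X)
CLASSIFIER_REGISTRY: dict[str, Callable[[int], object]] = {
    "SVM": _make_svm,
    "KNN": _make_knn,
    "DTree": _make_dtree,
    "NBayes": _make_nbayes,
    "LR": _make_lr,
    "LDA": lambda seed: _RidgeLDA(),
}

#: the five stock classifiers the headline metric is maximised over
DEFAULT_CLASSIFIERS = ("SVM", "KNN", "DTree", "NBayes", "LR")


@dataclass(frozen=True)
class PerformanceReport:
    """Per-classifier metrics averaged over CV runs, plus their maximum."""

    per_classifier: Mapping[str, Mapping[str, float]]
    mAcc: float
    best_classifier: str
    n_runs: int
    n_folds: int

    def to_dict(self) -> dict:
        return {
            "per_classifier": {k: dict(v) for k, v in self.per_classifier.items()},
            "mAcc": self.mAcc,
            "best_classifier": self.best_classifier,
            "n_runs": self.n_runs,
            "n_folds": self.n_folds,
        }


def _check_classifiers(classifiers: Sequence[str]) -> tuple[str, ...]:
    names = tuple(classifiers)
    if not names:
        raise ValueError("classifier set must be non-empty")
    unknown = [c for c in names if c not in CLASSIFIER_REGISTRY]
    if unknown:
        raise ValueError(
            f"unknown classifier(s) {unknown}; registered: "
            f"{sorted(CLASSIFIER_REGISTRY)}"
        )
    return names


def evaluate_subset(
    ds: ExpressionDataset,
    subset: Sequence[int],
    *,
    k: int = 10,
    seeds: Sequence[int] = (0,),
    classifiers: Sequence[str] = DEFAULT_CLASSIFIERS,
    scale: bool = False,
    fold_assignments: Sequence[FoldAssignment] | None = None,
) -> PerformanceReport:
    """Score a feature subset with seeded stratified k-fold CV.

    Within each run (seed), confusion counts are pooled over the k folds
    so that run-level Acc is exactly (sum TP + sum TN) / m; run-level
    metrics are then averaged over seeds.  ``fold_assignments`` may be
    passed to reuse pre-drawn splits (one per seed).
    """
    names = _check_classifiers(classifiers)
    seeds = list(seeds)
    if not seeds:
        raise ValueError("need at least one CV seed")
    X_all = ds.subset(subset).T  # samples x features
    y = ds.labels.astype(int)

    if fold_assignments is None:
        fold_assignments = [stratified_kfold(ds.labels, k, s) for s in seeds]
    elif len(fold_assignments) != len(seeds):
        raise ValueError("fold_assignments must align with seeds")

    sums: dict[str, dict[str, float]] = {
        name: {m: 0.0 for m in METRIC_NAMES} for name in names
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed, fa in zip(seeds, fold_assignments):
            counts = {name: ConfusionCounts() for name in names}
            for fold in range(fa.k):
                test_idx = fa.test_indices(fold)
                train_idx = fa.train_indices(fold)
                X_train, X_test = X_all[train_idx], X_all[test_idx]
                if scale:
                    mu = X_train.mean(axis=0)
                    sd = X_train.std(axis=0)
                    sd[sd == 0] = 1.0
                    X_train = (X_train - mu) / sd
                    X_test = (X_test - mu) / sd
                y_train, y_test = y[train_idx], y[test_idx]
                for name in names:
                    try:
                        model = CLASSIFIER_REGISTRY[name](seed)
                        pred = np.asarray(
                            model.fit(X_train, y_train).predict(X_test)
                        ).astype(int)
                    except Exception as exc:  # noqa: BLE001 - contract: degrade
                        logger.warning(
                            "classifier %s failed on fold %d (%s); "
                            "using majority-class predictions", name, fold, exc
                        )
                        majority = int(y_train.sum() * 2 > y_train.size)
                        pred = np.full(y_test.size, majority, dtype=int)
                    counts[name] += ConfusionCounts(
                        TP=int(((pred == 1) & (y_test == 1)).sum()),
                        FN=int(((pred == 0) & (y_test == 1)).sum()),
                        FP=int(((pred == 1) & (y_test == 0)).sum()),
                        TN=int(((pred == 0) & (y_test == 0)).sum()),
                    )
            for name in names:
                run_metrics = compute_metrics(counts[name])
                for m in METRIC_NAMES:
                    sums[name][m] += run_metrics[m]

    n_runs = len(seeds)
    per_classifier = {
        name: {m: sums[name][m] / n_runs for m in METRIC_NAMES} for name in names
    }
    best = max(names, key=lambda nm: per_classifier[nm]["Acc"])
    return PerformanceReport(
        per_classifier=per_classifier,
        mAcc=per_classifier[best]["Acc"],
        best_classifier=best,
        n_runs=n_runs,
        n_folds=k,
    )


def make_subset_evaluator(
    ds: ExpressionDataset,
    *,
    k: int = 10,
    seeds: Sequence[int] = (0,),
    classifiers: Sequence[str] = DEFAULT_CLASSIFIERS,
    scale: bool = False,
    reuse_folds: bool = True,
) -> Callable[[Sequence[int]], float]:
    """Build ``subset -> mAcc`` with fold splits shared across calls.

    Sharing one :class:`FoldAssignment` per seed across every prefix
    evaluated in a search removes split noise from consecutive-step
    comparisons (and redraws per call when ``reuse_folds=False``).
    """
    _check_classifiers(classifiers)
    shared = (
        [stratified_kfold(ds.labels, k, s) for s in seeds] if reuse_folds else None
    )

    def eval_fn(subset: Sequence[int]) -> float:
        return evaluate_subset(
            ds, subset, k=k, seeds=seeds, classifiers=classifiers,
            scale=scale, fold_assignments=shared,
        ).mAcc

    return eval_fn
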