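"""RBF-SVM with nested cross-validation and two-group evaluation metrics.

The outer loop is leave-one-out cross-validation (LOOCV): each subject in
turn is held out, the entire feature-selection stack runs on the remaining
subjects only, an RBF soft-margin SVM is tuned by an inner stratified
10-fold grid search over (C, sigma) and fitted, and the held-out subject is
scored.  Pooled held-out decision scores yield the confusion metrics
(converters positive), the ROC curve and the AUC.

The RBF kernel is K(x1, x2) = exp(-||x1 - x2||^2 / sigma^2); note sklearn's
``gamma`` equals 1/sigma^2 in this parameterization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import FeatureMatrix
from .selection import (
    SelectionLikelihood,
    StabilityConfig,
    select_features_all_combinations,
    select_top_features,
)

__all__ = [
    "SVMConfig",
    "PredictionSet",
    "ConfusionCounts",
    "rbf_kernel",
    "inner_grid_search",
    "loocv_evaluate",
    "loocv_select",
    "loocv_classify",
    "confusion_metrics",
    "roc_auc",
    "LOOCVResult",
]

logger = logging.getLogger(__name__)


@dataclass
class SVMConfig:
    """Grids and folds for the inner hyperparameter search.

    ``C_grid`` defaults to 2^-5..2^15 (step 2^2).  ``sigma2_grid`` holds
    squared kernel widths; when None it is derived at fit time as
    2^-15..2^3 (step 2^2) scaled by the feature count m, the standard
    dimension-aware RBF search range.  ``class_weight`` may be set to
    ``"balanced"`` for inverse-frequency weighting (off by default).
    """

    C_grid: np.ndarray = field(
        default_factory=lambda: 2.0 ** np.arange(-5, 16, 2, dtype=float)
    )
    sigma2_grid: np.ndarray | None = None
    inner_folds: int = 10
    seed: int = 0
    class_weight: str | None = None

    def __post_init__(self) -> None:
        self.C_grid = np.asarray(self.C_grid, dtype=float)
        if self.C_grid.size == 0 or np.any(self.C_grid <= 0):
            raise ValueError("C_grid must be non-empty and positive")
        if self.sigma2_grid is not None:
            self.sigma2_grid = np.asarray(self.sigma2_grid, dtype=float)
            if self.sigma2_grid.size == 0 or np.any(self.sigma2_grid <= 0):
                raise ValueError("sigma2_grid must be non-empty and positive")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")

    def resolve_sigma2(self, n_features: int) -> np.ndarray:
        if self.sigma2_grid is not None:
            return self.sigma2_grid
        return 2.0 ** np.arange(-15, 4, 2, dtype=float) * n_features


def rbf_kernel(x1: np.ndarray, x2: np.ndarray, sigma: float) -> float:
    """exp(-||x1 - x2||^2 / sigma^2); 1 at zero distance, symmetric."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("x1 and x2 must have equal length")
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise ValueError("inputs must be finite")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    return float(np.exp(-np.sum((x1 - x2) ** 2) / sigma**2))


def _sq_distances(X: np.ndarray, Z: np.ndarray | None = None) -> np.ndarray:
    Z = X if Z is None else Z
    sq = (X**2).sum(axis=1)[:, None] + (Z**2).sum(axis=1)[None, :] - 2.0 * X @ Z.T
    return np.maximum(sq, 0.0)


def inner_grid_search(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: SVMConfig,
) -> tuple[float, float]:
    """(C*, sigma*) maximizing mean stratified inner-CV accuracy.

    Ties go to the smallest C, then the smallest sigma.  If the minority
    class has fewer members than ``inner_folds`` the fold count is reduced
    with a warning.  Kernels are precomputed per sigma so the C sweep reuses
    them.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    classes, cls_counts = np.unique(y_train, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present in the training set")
    n_folds = int(min(config.inner_folds, cls_counts.min()))
    if n_folds < config.inner_folds:
        logger.warning(
            "inner folds reduced from %d to %d (minority class size)",
            config.inner_folds,
            n_folds,
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    splits = list(skf.split(X_train, y_train))
    sigma2s = np.sort(config.resolve_sigma2(X_train.shape[1]))
    Cs = np.sort(config.C_grid)
    d2 = _sq_distances(X_train)

    best = (-np.inf, np.inf, np.inf)  # (accuracy, C, sigma) with min-C/min-sigma ties
    for s2 in sigma2s:
        K = np.exp(-d2 / s2)
        for C in Cs:
            correct = 0
            for tr, te in splits:
                clf = SVC(C=C, kernel="precomputed", class_weight=config.class_weight)
                clf.fit(K[np.ix_(tr, tr)], y_train[tr])
                correct += int(np.sum(clf.predict(K[np.ix_(te, tr)]) == y_train[te]))
            acc = correct / len(y_train)
            if acc > best[0] or (
                acc == best[0] and (C, np.sqrt(s2)) < (best[1], best[2])
            ):
                best = (acc, float(C), float(np.sqrt(s2)))
    return best[1], best[2]


# ---------------------------------------------------------------------------
# Predictions and metrics


@dataclass
class PredictionSet:
    """Pooled held-out LOOCV predictions: one row per cohort subject."""

    subject_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true, dtype=int)
        self.y_pred = np.asarray(self.y_pred, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.subject_ids)
        if not (len(self.y_true) == len(self.y_pred) == len(self.scores) == n):
            raise ValueError("prediction arrays must have one entry per subject")

    def __len__(self) -> int:
        return len(self.subject_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "y_true": self.y_true,
                "y_pred": self.y_pred,
                "score": self.scores,
            }
        )


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positives and negatives; converters (+1) are positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ConfusionMetrics:
    """Accuracy / sensitivity / specificity as percentages, plus the counts."""

    accuracy: float
    sensitivity: float
    specificity: float
    counts: ConfusionCounts


def confusion_metrics(preds: PredictionSet) -> ConfusionMetrics:
    """Accuracy = (TP+TN)/n, Sensitivity = TP/(TP+FN), Specificity = TN/(TN+FP).

    Returned as percentages.  With no positive (or no negative) subjects the
    corresponding rate is NaN, with a warning.
    """
    if len(preds) == 0:
        raise ValueError("empty prediction set")
    yt, yp = preds.y_true, preds.y_pred
    c = ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == -1) & (yp == -1))),
        fp=int(np.sum((yt == -1) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == -1))),
    )
    acc = 100.0 * (c.tp + c.tn) / c.n
    if c.tp + c.fn == 0:
        warnings.warn("no positive subjects: sensitivity undefined")
        sen = float("nan")
    else:
        sen = 100.0 * c.tp / (c.tp + c.fn)
    if c.tn + c.fp == 0:
        warnings.warn("no negative subjects: specificity undefined")
        spe = float("nan")
    else:
        spe = 100.0 * c.tn / (c.tn + c.fp)
    return ConfusionMetrics(acc, sen, spe, c)


def roc_auc(preds: PredictionSet) -> tuple[np.ndarray, float]:
    """ROC points swept over all score thresholds, and the trapezoidal AUC.

    Tied scores cross the threshold simultaneously, which makes the AUC equal
    to the Mann–Whitney statistic with half credit for ties.  Constant scores
    yield AUC 0.5 with a warning.  Returns (points, auc) where points is an
    (k, 3) array of (fpr, tpr, threshold) rows.
    """
    y, s = preds.y_true, preds.scores
    if not np.all(np.isfinite(s)):
        raise ValueError("decision scores must be finite")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for ROC analysis")
    if np.all(s == s[0]):
        warnings.warn("constant decision scores: AUC defaulting to 0.5")

    order = np.argsort(-s, kind="stable")
    ys, ss = y[order], s[order]
    # collapse tied scores into single threshold steps
    distinct = np.r_[np.where(np.diff(ss) != 0)[0], len(ss) - 1]
    tps = np.cumsum(ys == 1)[distinct]
    fps = np.cumsum(ys == -1)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, ss[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    points = np.column_stack([fpr, tpr, thresholds])
    return points, auc


# ---------------------------------------------------------------------------
# Nested cross-validation


def _zscore_train_apply(
    X_train: np.ndarray, X_other: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X_train - mu) / sd, (X_other - mu) / sd


@dataclass
class LOOCVResult:
    """Everything the outer loop produced: predictions, per-fold diagnostics."""

    predictions: PredictionSet
    fold_features: list[list[str]]
    fold_hyperparams: list[tuple[float, float]]
    fold_likelihoods: list[SelectionLikelihood]

    def feature_fold_frequency(self) -> dict[str, float]:
        """Share of outer folds (%) in which each feature made the final top-K.

        Sorted by frequency descending, ties broken by canonical column order.
        """
        n = len(self.fold_features)
        counts: dict[str, int] = {}
        for feats in self.fold_features:
            for f in feats:
                counts[f] = counts.get(f, 0) + 1
        col_order = {f: j for j, f in enumerate(self.fold_likelihoods[0].feature_names)}
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], col_order[kv[0]]))
        return {f: 100.0 * c / n for f, c in ranked}


def _fold_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def loocv_select(
    features: FeatureMatrix,
    stability: StabilityConfig,
    seed: int = 0,
) -> list[SelectionLikelihood]:
    """Run the selection stack inside every LOOCV training set.

    Fold i's training set is every subject but i, standardized on itself;
    the held-out subject never enters selection.  Returns one
    :class:`SelectionLikelihood` per fold (final-K independent, so top-K
    sweeps can reuse them).
    """
    n = features.n_subjects
    if n < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    seeds = _fold_seeds(seed, n)
    out = []
    for i in range(n):
        train = np.arange(n) != i
        y_tr = features.labels[train]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(
                f"fold {i}: training set lost a class; cohort too small/imbalanced"
            )
        fm = FeatureMatrix(
            features.values[train],
            list(features.columns),
            y_tr,
            [sid for j, sid in enumerate(features.subject_ids) if train[j]],
        )
        rng = np.random.default_rng(seeds[i])
        out.append(select_features_all_combinations(fm, stability, seed=rng))
    return out


def loocv_classify(
    features: FeatureMatrix,
    fold_likelihoods: list[SelectionLikelihood],
    top_k: int,
    svm: SVMConfig,
    seed: int = 0,
) -> LOOCVResult:
    """Fit and score the SVM stage of every fold, given per-fold selections."""
    n = features.n_subjects
    if len(fold_likelihoods) != n:
        raise ValueError("need one selection result per subject")
    y = features.labels
    y_pred = np.empty(n, dtype=int)
    scores = np.empty(n)
    fold_features: list[list[str]] = []
    fold_hp: list[tuple[float, float]] = []
    svm_seeds = _fold_seeds(seed ^ 0x5EED, n)
    for i in range(n):
        selected = select_top_features(fold_likelihoods[i], top_k)
        fold_features.append(selected)
        cols = [features.columns.index(f) for f in selected]
        train = np.arange(n) != i
        X_tr, X_te = _zscore_train_apply(
            features.values[np.ix_(train, cols)], features.values[np.ix_(~train, cols)]
        )
        cfg = SVMConfig(
            C_grid=svm.C_grid,
            sigma2_grid=svm.sigma2_grid,
            inner_folds=svm.inner_folds,
            seed=int(svm_seeds[i].generate_state(1)[0] % (2**31)),
            class_weight=svm.class_weight,
        )
        C, sig = inner_grid_search(X_tr, y[train], cfg)
        fold_hp.append((C, sig))
        clf = SVC(C=C, gamma=1.0 / sig**2, class_weight=svm.class_weight)
        clf.fit(X_tr, y[train])
        raw = float(clf.decision_function(X_te)[0])
        # sklearn orients decision_function toward clf.classes_[1]
        score = raw if clf.classes_[1] == 1 else -raw
        scores[i] = score
        y_pred[i] = 1 if score > 0 else -1
        logger.debug(
            "fold %d: C=%g sigma=%g features=%s", i, C, sig, ",".join(selected)
        )
    preds = PredictionSet(list(features.subject_ids), y, y_pred, scores)
    return LOOCVResult(preds, fold_features, fold_hp, fold_likelihoods)


def loocv_evaluate(
    features: FeatureMatrix,
    stability: StabilityConfig,
    svm: SVMConfig,
    top_k: int = 10,
    seed: int = 0,
) -> LOOCVResult:
    """Full nested CV: per-fold feature selection, inner grid search, scoring."""
    fold_likelihoods = loocv_select(features, stability, seed=seed)
    return loocv_classify(features, fold_likelihoods, top_k, svm, seed=seed)
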