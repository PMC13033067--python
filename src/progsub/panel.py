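"""Minimal discriminative gene panels by linear-SVM recursive feature
elimination, plus PCA, per-dataset standardization and the cross-dataset
validation harness.

The selector iteratively fits a linear SVM (C = 5 by default), drops the
feature(s) with the smallest absolute weight, and scores every visited
panel by repeated stratified k-fold cross-validation (7 splits x 7
repeats). The selected panel maximizes mean CV accuracy, preferring the
smallest panel on ties.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    roc_auc_score,
    silhouette_samples,
)
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger("progsub")


@dataclass
class RFEConfig:
    """Knobs of the elimination: SVM regularization C = 5, 7 x 7
    repeated stratified CV, adaptive elimination step."""

    C: float = 5.0
    n_splits: int = 7
    n_repeats: int = 7
    step_small: int = 1
    step_frac: float = 0.10
    step_threshold: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")
        if self.step_small < 1 or not 0 < self.step_frac < 1:
            raise ValueError("invalid elimination step")


@dataclass
class PanelResult:
    ranking: pd.Series  # feature -> rank (1 = retained longest, ties allowed)
    selected: list[str]
    cv_accuracy: dict[int, float]  # panel size -> mean CV accuracy
    best_accuracy: float


class RFEPanelSelector(BaseEstimator):
    """Sklearn-style recursive feature elimination around a linear SVM.

    Panel sizes are scored by nested repeated stratified cross-validation:
    the elimination runs inside every training fold and each visited
    panel size is scored on the held-out fold, so the accuracy curve is
    not biased by feature selection on the evaluation samples. The panel
    size maximizing mean CV accuracy (smallest on ties) is then realized
    by one elimination pass over the full data, which also yields the
    feature ranking. Elimination drops one feature per iteration below
    ``step_threshold`` features and ``step_frac`` of the remainder above
    it, which keeps small problems exact and large ones fast.

    Attributes
    ----------
    ranking_ : ndarray, 1 = retained longest (features eliminated in the
        same batch share a rank)
    support_ : boolean mask of the selected panel
    cv_scores_ : dict, panel size -> mean CV accuracy
    best_score_ : mean CV accuracy at the selected panel size
    """

    def __init__(self, C=5.0, n_splits=7, n_repeats=7, step_small=1,
                 step_frac=0.10, step_threshold=100, random_state=0):
        self.C = C
        self.n_splits = n_splits
        self.n_repeats = n_repeats
        self.step_small = step_small
        self.step_frac = step_frac
        self.step_threshold = step_threshold
        self.random_state = random_state

    def _svm(self):
        return SVC(kernel="linear", C=self.C)

    def _n_drop(self, n_remaining: int) -> int:
        if n_remaining > self.step_threshold:
            n_drop = max(1, int(np.ceil(self.step_frac * n_remaining)))
            return max(1, min(n_drop, n_remaining - self.step_threshold))
        return min(self.step_small, n_remaining - 1)

    def _eliminate(self, X, y, X_test=None, y_test=None):
        """One elimination pass; optionally score every visited size on a
        held-out set (reusing the SVM fitted for the elimination step).

        Returns (ranking, {size: panel}, {size: held-out accuracy}).
        """
        n_features = X.shape[1]
        remaining = list(range(n_features))
        ranking = np.ones(n_features, dtype=int)
        panels: dict[int, list[int]] = {}
        scores: dict[int, float] = {}
        next_rank = n_features
        while remaining:
            panels[len(remaining)] = list(remaining)
            svm = self._svm().fit(X[:, remaining], y)
            if X_test is not None:
                scores[len(remaining)] = accuracy_score(
                    y_test, svm.predict(X_test[:, remaining])
                )
            if len(remaining) == 1:
                break
            weights = np.abs(np.ravel(svm.coef_))
            n_drop = self._n_drop(len(remaining))
            drop_local = np.argsort(weights, kind="mergesort")[:n_drop]
            for local in drop_local:
                ranking[remaining[local]] = next_rank
            next_rank -= n_drop
            drop_set = set(drop_local)
            remaining = [f for i, f in enumerate(remaining) if i not in drop_set]
        return ranking, panels, scores

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("y contains a single class; need two")
        if len(classes) > 2:
            raise ValueError("only two-class problems are supported")
        if np.all(X.std(axis=0) == 0):
            raise ValueError("no informative features: all features are constant")
        n_splits = self.n_splits
        if counts.min() < n_splits:
            n_splits = max(2, int(counts.min()))
            logger.warning(
                "smallest class has %d members; reducing CV splits to %d",
                counts.min(), n_splits,
            )
        cv = RepeatedStratifiedKFold(
            n_splits=n_splits, n_repeats=self.n_repeats,
            random_state=self.random_state,
        )
        fold_scores: dict[int, list[float]] = {}
        for train_idx, test_idx in cv.split(X, y):
            _, _, scores = self._eliminate(
                X[train_idx], y[train_idx], X[test_idx], y[test_idx]
            )
            for size, acc in scores.items():
                fold_scores.setdefault(size, []).append(acc)
        mean_scores = {size: float(np.mean(v)) for size, v in fold_scores.items()}
        best_score = max(mean_scores.values())
        best_size = min(s for s, acc in mean_scores.items() if acc == best_score)

        ranking, panels, _ = self._eliminate(X, y)
        self.n_features_in_ = X.shape[1]
        self.ranking_ = ranking
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[panels[best_size]] = True
        self.cv_scores_ = mean_scores
        self.best_score_ = best_score
        self.n_features_ = best_size
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]

    def get_support(self, indices: bool = False):
        return np.flatnonzero(self.support_) if indices else self.support_


def rfe_select(X: pd.DataFrame, y, cfg: RFEConfig | None = None) -> PanelResult:
    """Run the panel selection on a samples x features frame."""
    cfg = cfg or RFEConfig()
    selector = RFEPanelSelector(
        C=cfg.C, n_splits=cfg.n_splits, n_repeats=cfg.n_repeats,
        step_small=cfg.step_small, step_frac=cfg.step_frac,
        step_threshold=cfg.step_threshold, random_state=cfg.seed,
    ).fit(X.to_numpy(dtype=float), np.asarray(y))
    features = list(X.columns)
    return PanelResult(
        ranking=pd.Series(selector.ranking_, index=features, name="rank"),
        selected=[features[i] for i in selector.get_support(indices=True)],
        cv_accuracy=selector.cv_scores_,
        best_accuracy=selector.best_score_,
    )


def pca_project(X, n_components: int = 2):
    """Column-centered PCA scores and explained-variance fractions."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    if n_components > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError("n_components exceeds min(n_samples - 1, n_features)")
    pca = PCA(n_components=n_components).fit(X)
    return pca.transform(X), pca.explained_variance_ratio_


class DatasetZscorer(BaseEstimator):
    """Per-feature z-scoring within one dataset (sample sd, ddof = 1).

    Constant features are mapped to all zeros with a warning, so
    cross-platform panels with a flat gene degrade gracefully instead of
    emitting NaN.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("z-scoring needs at least 2 samples")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if (self.scale_ == 0).any():
            warnings.warn(
                f"{int((self.scale_ == 0).sum())} constant feature(s) set to zero",
                stacklevel=2,
            )
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        scale = np.where(self.scale_ == 0, 1.0, self.scale_)
        Z = (X - self.mean_) / scale
        Z[:, self.scale_ == 0] = 0.0
        return Z

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def zscore_standardize(X, *, ddof: int = 1):
    """Gene-wise z-score across the samples of one dataset.

    ``X`` is samples x features; constant features become all-zero
    columns (with a warning). Applying the function twice is the same as
    applying it once.
    """
    if ddof == 1:
        return DatasetZscorer().fit_transform(X)
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=ddof)
    if (sd == 0).any():
        warnings.warn(
            f"{int((sd == 0).sum())} constant feature(s) set to zero", stacklevel=2
        )
    scale = np.where(sd == 0, 1.0, sd)
    Z = (X - X.mean(axis=0)) / scale
    Z[:, sd == 0] = 0.0
    return Z


def silhouette_width(X, labels):
    """Euclidean silhouette widths: per-sample, overall mean, per-class means."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    widths = silhouette_samples(X, labels, metric="euclidean")
    per_class = {
        str(c): float(widths[labels == c].mean()) for c in np.unique(labels)
    }
    return widths, float(widths.mean()), per_class


def f1_from_confusion(cm) -> float:
    """F1 of the positive class from a 2x2 confusion matrix
    [[TN, FP], [FN, TP]] (rows = truth, columns = prediction)."""
    cm = np.asarray(cm, dtype=float)
    if cm.shape != (2, 2):
        raise ValueError("expected a 2x2 confusion matrix")
    tn, fp = cm[0]
    fn, tp = cm[1]
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom else 0.0


@dataclass
class ValidationReport:
    confusion: np.ndarray  # rows = truth [negative, positive]
    accuracy: float
    f1: float
    roc_auc: float
    silhouette_mean: float
    silhouette_per_class: dict[str, float] = field(default_factory=dict)
    positive_label: str = ""
    panel: list[str] = field(default_factory=list)


def cross_dataset_validate(
    train_X: pd.DataFrame,
    train_y,
    test_X: pd.DataFrame,
    test_y,
    panel,
    *,
    C: float = 5.0,
    positive_label=None,
) -> ValidationReport:
    """Train once on one cohort, evaluate frozen on an independent one.

    Both cohorts are samples x genes; the panel is intersected with the
    genes present in both (platform differences mean not every gene
    transfers), each dataset is independently gene-wise z-scored, and a
    linear SVM (C = 5) fit on the training cohort is applied to the test
    cohort without retraining. The positive class of F1/AUC defaults to
    the minority class of the training labels (the smaller subtype).
    """
    panel = [g for g in panel if g in train_X.columns and g in test_X.columns]
    if not panel:
        raise ValueError("empty feature intersection between panel and datasets")
    train_y = np.asarray(train_y)
    test_y = np.asarray(test_y)
    if positive_label is None:
        vals, counts = np.unique(train_y, return_counts=True)
        positive_label = vals[np.argmin(counts)]
    Xtr = zscore_standardize(train_X[panel].to_numpy(dtype=float))
    Xte = zscore_standardize(test_X[panel].to_numpy(dtype=float))
    svm = SVC(kernel="linear", C=C).fit(Xtr, train_y)
    pred = svm.predict(Xte)
    scores = svm.decision_function(Xte)
    if svm.classes_[1] != positive_label:
        scores = -scores
    negative_label = [c for c in svm.classes_ if c != positive_label][0]
    order = [negative_label, positive_label]
    cm = confusion_matrix(test_y, pred, labels=order)
    widths, sil_mean, sil_class = silhouette_width(Xte, test_y)
    return ValidationReport(
        confusion=cm,
        accuracy=float(accuracy_score(test_y, pred)),
        f1=float(f1_score(test_y, pred, pos_label=positive_label)),
        roc_auc=float(roc_auc_score(test_y == positive_label, scores)),
        silhouette_mean=sil_mean,
        silhouette_per_class=sil_class,
        positive_label=str(positive_label),
        panel=panel,
    )
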