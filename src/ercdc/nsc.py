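"""Nearest shrunken centroid classification and marker-gene extraction.

The classifier standardizes class-centroid differences per gene,

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),    m_k = sqrt(1/n_k - 1/n),

soft-thresholds them by a shrinkage level Delta,

    d'_ik = sign(d_ik) * max(|d_ik| - Delta, 0),

and classifies by the shrunken-centroid discriminant

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k .

Genes with a nonzero shrunken difference for the target class are its
markers.  The shrinkage level is chosen by stratified cross-validation under
a false-positive-rate constraint (the published marker panel used
Delta = 1.88 with a one-vs-rest false-positive rate below 20%).

``NearestShrunkenCentroids`` is a scikit-learn style estimator operating on
samples x features arrays; the module-level helpers accept the package's
genes x samples frames and stay thin over it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

#: Shrinkage threshold behind the published 61-gene panel (provenance record,
#: not a default: the grid/folds behind it are data-set specific).
PUBLISHED_THRESHOLD = 1.88


class NearestShrunkenCentroids(BaseEstimator, ClassifierMixin):
    """Nearest shrunken centroid classifier (PAM-style).

    Parameters
    ----------
    threshold : float, default=0.0
        Shrinkage level Delta applied at prediction time; ``shrink`` and
        ``predict`` also accept an explicit override so one fit can be
        evaluated over a whole grid.
    priors : array-like of shape (n_classes,), optional
        Class prior probabilities; default is the class proportions.
    s0 : float or "median", default="median"
        Fudge constant added to the pooled within-class SD; the default is
        the median of the pooled SDs.

    Attributes
    ----------
    classes_ : ndarray of class labels, sorted.
    overall_centroid_ : (n_features,) overall feature means.
    centroids_ : (n_classes, n_features) class feature means.
    pooled_sd_ : (n_features,) pooled within-class SD (denominator n - K).
    s0_ : float fudge constant.
    priors_ : (n_classes,) priors.
    mk_ : (n_classes,) the sqrt(1/n_k - 1/n) normalizers.
    d_ : (n_classes, n_features) standardized centroid differences.
    """

    def __init__(self, threshold: float = 0.0, priors=None, s0="median"):
        self.threshold = threshold
        self.priors = priors
        self.s0 = s0

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if hasattr(y, "to_numpy"):
            y = y.to_numpy()
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x features)")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        classes, y_idx = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes")
        counts = np.bincount(y_idx)
        if (counts < 2).any():
            bad = classes[counts < 2]
            raise ValueError(f"each class needs >= 2 samples; offending: {list(bad)}")
        n, g = X.shape
        k = len(classes)

        overall = X.mean(axis=0)
        centroids = np.vstack([X[y_idx == i].mean(axis=0) for i in range(k)])
        ss_within = np.zeros(g)
        for i in range(k):
            ss_within += ((X[y_idx == i] - centroids[i]) ** 2).sum(axis=0)
        pooled_sd = np.sqrt(ss_within / (n - k))
        s0 = float(np.median(pooled_sd)) if self.s0 == "median" else float(self.s0)
        mk = np.sqrt(1.0 / counts - 1.0 / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (centroids - overall) / (mk[:, None] * (pooled_sd + s0)[None, :])
        d = np.nan_to_num(d, nan=0.0, posinf=0.0, neginf=0.0)

        if self.priors is None:
            priors = counts / n
        else:
            priors = np.asarray(self.priors, dtype=float)
            if priors.shape != (k,) or not np.isclose(priors.sum(), 1.0):
                raise ValueError("priors must be one probability per class, summing to 1")

        self.classes_ = classes
        self.class_counts_ = counts
        self.overall_centroid_ = overall
        self.centroids_ = centroids
        self.pooled_sd_ = pooled_sd
        self.s0_ = s0
        self.mk_ = mk
        self.priors_ = priors
        self.d_ = d
        self.n_features_in_ = g
        return self

    def shrink(self, threshold: float | None = None):
        """Soft-threshold the standardized differences.

        Returns ``(d_shrunk, shrunken_centroids)``, both (n_classes,
        n_features).
        """
        check_is_fitted(self, "d_")
        delta = self.threshold if threshold is None else threshold
        if delta < 0:
            raise ValueError(f"shrinkage threshold must be >= 0, got {delta}")
        d_shrunk = np.sign(self.d_) * np.maximum(np.abs(self.d_) - delta, 0.0)
        offsets = self.mk_[:, None] * (self.pooled_sd_ + self.s0_)[None, :] * d_shrunk
        return d_shrunk, self.overall_centroid_[None, :] + offsets

    def decision_scores(self, X, threshold: float | None = None) -> np.ndarray:
        """Discriminant scores (smaller is closer), samples x classes."""
        check_is_fitted(self, "d_")
        X = np.asarray(X, dtype=float)
        _, shrunken = self.shrink(threshold)
        denom_sq = (self.pooled_sd_ + self.s0_) ** 2
        diff = X[:, None, :] - shrunken[None, :, :]
        return (diff ** 2 / denom_sq).sum(axis=2) - 2.0 * np.log(self.priors_)

    def predict(self, X, threshold: float | None = None):
        scores = self.decision_scores(X, threshold)
        return self.classes_[np.argmin(scores, axis=1)]  # ties -> class order


# ---------------------------------------------------------------------------
# genes x samples wrappers and threshold selection


@dataclass
class ShrinkageResult:
    threshold: float
    d_shrunk: pd.DataFrame  # genes x classes
    shrunken_centroids: pd.DataFrame  # genes x classes
    active_genes: dict[str, list[str]]  # per class: genes with d' != 0


@dataclass
class CVResult:
    thresholds: np.ndarray
    classes: np.ndarray
    confusion: np.ndarray  # (n_thresholds, K, K), rows true / cols predicted
    fpr: pd.DataFrame  # thresholds x classes, one-vs-rest false-positive rate
    error_rate: np.ndarray  # (n_thresholds,) overall CV misclassification
    n_active: np.ndarray  # (n_thresholds,) active genes (any class), full fit


def train_centroids(m: pd.DataFrame, labels: pd.Series, priors=None
                    ) -> NearestShrunkenCentroids:
    """Fit the classifier on a genes x samples matrix with per-sample labels."""
    labels = labels.loc[m.columns] if hasattr(labels, "loc") else labels
    model = NearestShrunkenCentroids(priors=priors).fit(m.to_numpy().T, labels)
    model.gene_ids_ = m.index.to_numpy()
    return model


def shrink(model: NearestShrunkenCentroids, threshold: float) -> ShrinkageResult:
    d_shrunk, centroids = model.shrink(threshold)
    genes = pd.Index(model.gene_ids_, name="gene_id")
    d_df = pd.DataFrame(d_shrunk.T, index=genes, columns=model.classes_)
    c_df = pd.DataFrame(centroids.T, index=genes, columns=model.classes_)
    active = {c: list(genes[d_df[c] != 0]) for c in model.classes_}
    return ShrinkageResult(threshold, d_df, c_df, active)


def classify(model: NearestShrunkenCentroids, threshold: float,
             newdata: pd.DataFrame):
    """Predict labels + discriminant scores for a genes x samples matrix."""
    missing = pd.Index(model.gene_ids_).difference(newdata.index)
    if len(missing) > 0:
        raise ValueError(f"new data is missing model genes: {list(missing[:5])}")
    x = newdata.loc[model.gene_ids_].to_numpy().T
    scores = model.decision_scores(x, threshold)
    labels = model.classes_[np.argmin(scores, axis=1)]
    return (
        pd.Series(labels, index=newdata.columns, name="predicted"),
        pd.DataFrame(scores, index=newdata.columns, columns=model.classes_),
    )


def default_threshold_grid(model: NearestShrunkenCentroids, n: int = 30) -> np.ndarray:
    """n evenly spaced shrinkage levels from 0 to max |d_ik|."""
    return np.linspace(0.0, float(np.abs(model.d_).max()), n)


def cross_validate(m: pd.DataFrame, labels: pd.Series,
                   threshold_grid: np.ndarray | None = None,
                   k_folds: int = 10, seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validation of the classifier over a grid.

    Folds are reduced to the smallest class size when necessary.  The
    active-gene counts reported per threshold come from the full-data fit
    (the counts a user would see for the final model).
    """
    labels = pd.Series(labels).loc[m.columns] if hasattr(labels, "loc") else pd.Series(
        labels, index=m.columns)
    y = labels.to_numpy()
    full_model = train_centroids(m, labels)
    if threshold_grid is None:
        threshold_grid = default_threshold_grid(full_model)
    threshold_grid = np.asarray(threshold_grid, dtype=float)

    classes = full_model.classes_
    k = len(classes)
    min_class = int(np.bincount(np.searchsorted(classes, y)).min())
    n_splits = min(k_folds, min_class)
    if n_splits < 2:
        raise ValueError("fewer than 2 cross-validation folds feasible")

    x_all = m.to_numpy().T
    confusion = np.zeros((len(threshold_grid), k, k), dtype=int)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(x_all, y):
        fold = NearestShrunkenCentroids().fit(x_all[train_idx], y[train_idx])
        for t, delta in enumerate(threshold_grid):
            pred = fold.predict(x_all[test_idx], delta)
            for yt, yp in zip(y[test_idx], pred):
                confusion[t, np.searchsorted(classes, yt),
                          np.searchsorted(classes, yp)] += 1

    totals = confusion[0].sum(axis=1)  # per-class sample counts
    fpr = np.empty((len(threshold_grid), k))
    err = np.empty(len(threshold_grid))
    for t in range(len(threshold_grid)):
        for j in range(k):
            non_target = totals.sum() - totals[j]
            false_pos = confusion[t, :, j].sum() - confusion[t, j, j]
            fpr[t, j] = false_pos / non_target
        err[t] = 1.0 - np.trace(confusion[t]) / totals.sum()

    n_active = np.array([
        int((np.abs(full_model.shrink(delta)[0]) > 0).any(axis=0).sum())
        for delta in threshold_grid
    ])
    return CVResult(
        thresholds=threshold_grid,
        classes=classes,
        confusion=confusion,
        fpr=pd.DataFrame(fpr, index=threshold_grid, columns=classes),
        error_rate=err,
        n_active=n_active,
    )


def select_threshold(cv: CVResult, target_class: str, fpr_max: float = 0.20,
                     mode: str = "one_vs_rest") -> float:
    """Pick the shrinkage level: a small, stable gene count with FPR < fpr_max.

    ``mode="one_vs_rest"`` constrains the target class's false-positive rate
    (non-target samples predicted as target); ``mode="overall"`` constrains
    the overall cross-validated misclassification rate.

    Among feasible thresholds the rule prefers a *stable* small panel: the
    active-gene count with the longest run of grid points (the widest
    plateau of the count-vs-threshold curve), breaking plateau-length ties
    toward the smaller count and count ties toward the largest threshold.
    When no count repeats (every plateau has length one) this reduces to
    the plain minimum-count rule.
    """
    if target_class not in cv.fpr.columns:
        raise ValueError(f"target class {target_class!r} not in CV result")
    if mode == "one_vs_rest":
        rates = cv.fpr[target_class].to_numpy()
    elif mode == "overall":
        rates = cv.error_rate
    else:
        raise ValueError(f"unknown mode {mode!r}")
    feasible = rates < fpr_max
    if not feasible.any():
        raise ValueError(
            f"no threshold achieves {mode} rate < {fpr_max}; extend the grid "
            "or relax fpr_max"
        )
    counts = cv.n_active[feasible]
    thresholds = cv.thresholds[feasible]
    uniq, freq = np.unique(counts, return_counts=True)
    best = int(uniq[np.lexsort((uniq, -freq))][0])  # widest plateau, then smallest
    candidates = np.flatnonzero(counts == best)
    return float(thresholds[candidates[-1]])  # largest threshold among ties


def extract_markers(model: NearestShrunkenCentroids, threshold: float,
                    target_class: str) -> pd.DataFrame:
    """Marker genes of the target class at a shrinkage level.

    Returns a frame with columns ``direction`` ({up, down}) and
    ``magnitude`` (|d'|), sorted by magnitude descending (ties by gene id
    order), indexed by gene id.  Empty when no gene survives shrinkage.
    """
    result = shrink(model, threshold)
    if target_class not in result.d_shrunk.columns:
        raise ValueError(f"unknown class {target_class!r}")
    d = result.d_shrunk[target_class]
    d = d[d != 0]
    markers = pd.DataFrame({
        "direction": np.where(d > 0, "up", "down"),
        "magnitude": d.abs(),
    }, index=d.index)
    markers = markers.sort_values("magnitude", ascending=False, kind="stable")
    if markers.empty:
        import warnings

        warnings.warn(f"no marker genes for {target_class!r} at "
                      f"threshold {threshold}", stacklevel=2)
    return markers
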