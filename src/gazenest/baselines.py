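"""Classical comparison models: PCA/KAR/FOU descriptors with NB/SVM/KNN.

Each subject contributes 24 heatmaps (12 images x 2 viewings, flattened to
768-dim vectors in fixed image-then-viewing order). A descriptor reduces
each heatmap, and the 24 reduced vectors are concatenated into one subject
feature vector -- view identity is preserved, mirroring the multi-view
framing of the main model. Descriptor fits (PCA/KAR) use training folds
only.

Descriptors:

* PCA / KAR -- principal-component (Karhunen-Loeve) projection of the
  768-dim heatmaps; the two names are kept distinct to mirror the field's
  descriptor pairing, but KAR is definitionally the same projection.
* FOU -- magnitudes of the lowest-spatial-frequency 2-D DFT coefficients in
  a fixed zigzag (frequency-ordered) sequence; translation-invariant by
  construction.

Classifiers are the scikit-learn implementations: Gaussian Naive Bayes,
RBF-kernel SVM (C=1, gamma='scale') and KNN (k=5, Euclidean).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from sklearn.decomposition import PCA
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .heatmap import GRID_COLS, GRID_ROWS, SubjectViews

__all__ = [
    "stack_heatmaps",
    "PcaDescriptor",
    "KarDescriptor",
    "pca_features",
    "kar_features",
    "fou_features",
    "fou_subject_features",
    "fit_classifier",
    "BaselineModel",
]

N_CELLS = GRID_ROWS * GRID_COLS  # 768


def stack_heatmaps(views: list[SubjectViews]) -> np.ndarray:
    """(n_subjects, 24, 768) heatmap matrix in image-then-viewing order."""
    return np.stack([v.maps.reshape(-1, N_CELLS) for v in views])


class PcaDescriptor:
    """Per-heatmap PCA projection, fit on training heatmaps only."""

    def __init__(self, m: int):
        if not 1 <= m <= N_CELLS:
            raise ValueError(f"m={m} outside 1..{N_CELLS}")
        self.m = m
        self._pca: PCA | None = None

    def fit(self, views: list[SubjectViews]) -> "PcaDescriptor":
        flat = stack_heatmaps(views).reshape(-1, N_CELLS)
        if self.m > len(flat):
            raise ValueError(f"m={self.m} exceeds {len(flat)} training heatmaps")
        self._pca = PCA(n_components=self.m, svd_solver="full").fit(flat)
        return self

    def transform(self, views: list[SubjectViews], m: int | None = None) -> np.ndarray:
        """Project and concatenate each subject's 24 heatmaps -> (n, 24*m).

        ``m`` may truncate to a prefix of the fitted components (the nested-
        projection property of an orthogonal basis).
        """
        if self._pca is None:
            raise RuntimeError("descriptor not fitted")
        m = self.m if m is None else m
        if m > self.m:
            raise ValueError("cannot request more components than fitted")
        stacked = stack_heatmaps(views)
        n = len(stacked)
        proj = self._pca.transform(stacked.reshape(-1, N_CELLS))[:, :m]
        return proj.reshape(n, -1)


class KarDescriptor(PcaDescriptor):
    """Karhunen-Loeve coefficients; identical projection to PCA."""


def pca_features(
    train_views: list[SubjectViews], views: list[SubjectViews], m: int
) -> np.ndarray:
    """Fit PCA on the training heatmaps, project+concatenate ``views``."""
    return PcaDescriptor(m).fit(train_views).transform(views)


def kar_features(
    train_views: list[SubjectViews], views: list[SubjectViews], m: int
) -> np.ndarray:
    return KarDescriptor(m).fit(train_views).transform(views)


@lru_cache(maxsize=4)
def _zigzag_order(rows: int, cols: int) -> np.ndarray:
    """Flat cell indices of the DFT grid ordered by increasing spatial
    frequency (aliased frequency sum, then row/col frequency, then index)."""
    keys = []
    for u in range(rows):
        fu = min(u, rows - u)
        for v in range(cols):
            fv = min(v, cols - v)
            keys.append((fu + fv, fu, fv, u, v))
    order = sorted(range(rows * cols), key=lambda i: keys[i])
    return np.array(order)


def fou_features(heatmap: np.ndarray, k: int) -> np.ndarray:
    """Magnitudes of the k lowest-frequency 2-D DFT coefficients."""
    hm = np.asarray(heatmap, dtype=float).reshape(GRID_ROWS, GRID_COLS)
    if not 1 <= k <= N_CELLS:
        raise ValueError(f"k={k} outside 1..{N_CELLS}")
    mags = np.abs(np.fft.fft2(hm)).ravel()
    return mags[_zigzag_order(GRID_ROWS, GRID_COLS)[:k]]


def fou_subject_features(views: list[SubjectViews], k: int) -> np.ndarray:
    """Concatenated FOU descriptors of each subject's 24 heatmaps."""
    return np.stack(
        [
            np.concatenate([fou_features(hm, k) for hm in v.maps.reshape(-1, N_CELLS)])
            for v in views
        ]
    )


def fit_classifier(features: np.ndarray, labels: np.ndarray, kind: str, **hyper):
    """Fit one of the comparison classifiers; returns (clf, score_fn).

    ``score_fn(X)`` yields per-subject decision scores usable for ROC
    (decision function for SVM, positive-class probability otherwise).
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required in the training fold")
    if kind == "naive_bayes":
        clf = GaussianNB(**hyper).fit(features, y)
        return clf, lambda X: clf.predict_proba(X)[:, 1]
    if kind == "svm":
        hyper.setdefault("kernel", "rbf")
        hyper.setdefault("C", 1.0)
        hyper.setdefault("gamma", "scale")
        clf = SVC(**hyper).fit(features, y)
        return clf, lambda X: clf.decision_function(X)
    if kind == "knn":
        hyper.setdefault("n_neighbors", 5)
        clf = KNeighborsClassifier(**hyper).fit(features, y)
        return clf, lambda X: clf.predict_proba(X)[:, 1]
    raise ValueError(f"unknown classifier kind {kind!r}")


class BaselineModel:
    """Descriptor + classifier pipeline with the cross-validation interface
    of the main model (fit on views, predict probabilities/scores)."""

    def __init__(self, descriptor: str, classifier: str, m: int = 100, k: int = 64, **hyper):
        if descriptor not in ("pca", "kar", "fou"):
            raise ValueError(f"unknown descriptor {descriptor!r}")
        self.descriptor = descriptor
        self.classifier = classifier
        self.m, self.k = m, k
        self.hyper = hyper
        self._desc = None
        self._score_fn = None

    def _features(self, views: list[SubjectViews]) -> np.ndarray:
        if self.descriptor == "fou":
            return fou_subject_features(views, self.k)
        return self._desc.transform(views)

    def fit(self, views: list[SubjectViews]) -> "BaselineModel":
        if self.descriptor in ("pca", "kar"):
            cls = PcaDescriptor if self.descriptor == "pca" else KarDescriptor
            self._desc = cls(self.m).fit(views)
        X = self._features(views)
        y = np.array([v.label for v in views])
        _, self._score_fn = fit_classifier(X, y, self.classifier, **self.hyper)
        return self

    def predict_proba(self, views: list[SubjectViews]) -> np.ndarray:
        """Decision scores (monotone in P(PwAD); true probabilities for
        probabilistic classifiers)."""
        if self._score_fn is None:
            raise RuntimeError("model not fitted")
        return np.asarray(self._score_fn(self._features(views)), dtype=float)

    def predict(self, views: list[SubjectViews]) -> np.ndarray:
        scores = self.predict_proba(views)
        thresh = 0.5 if self.classifier in ("naive_bayes", "knn") else 0.0
        return (scores >= thresh).astype(int)
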