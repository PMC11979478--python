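"""K-means subtyping, prediction-strength selection of k, and cluster quality.

K-means (Lloyd iterations, k-means++ seeding, best of ``n_restarts``) groups
patient vectors in Euclidean space; TF-IDF vectors arrive unit-normalised so
Euclidean distance is monotone in cosine distance there.

The number of clusters is chosen with *prediction strength*: under k-fold
cross-validation, cluster the training part and the test part independently,
classify the test points with the training-side centroids, and for each
test-side cluster measure the proportion of its point pairs that the training
centroids also co-assign.  The fold score is the minimum over test clusters
(singletons count 1 vacuously); ps(1) = 1 by definition.  The chosen k* is the
largest k whose fold-mean prediction strength clears the threshold (default
0.8, the lower end of the range Tibshirani & Walther recommend).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn import metrics as _skm
from sklearn.cluster import KMeans
from sklearn.model_selection import KFold


@dataclass
class KMeansModel:
    k: int
    centroids: np.ndarray
    inertia: float
    seed: int


@dataclass
class PSCurve:
    """Prediction-strength values per candidate k: per-fold scores and means."""

    fold_scores: dict[int, list[float]] = field(default_factory=dict)
    threshold: float = 0.8

    def mean(self, k: int) -> float:
        return float(np.mean(self.fold_scores[k]))

    @property
    def ks(self) -> list[int]:
        return sorted(self.fold_scores)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"k": k, "fold": i, "prediction_strength": s}
            for k in self.ks
            for i, s in enumerate(self.fold_scores[k])
        ]
        return pd.DataFrame(rows)


@dataclass
class ClusterQuality:
    silhouette: float
    calinski_harabasz: float


class DegenerateClusteringError(ValueError):
    """Raised when a quality score is undefined (k = 1 or zero scatter)."""


def fit_kmeans(
    vectors: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10
) -> KMeansModel:
    """Fit k-means with k-means++ seeding, keeping the best of ``n_restarts``
    restarts by inertia.  Deterministic for a given seed."""
    x = np.asarray(vectors, dtype=np.float64)
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = len(np.unique(x, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct vectors")
    if k == 1:
        centroid = x.mean(0, keepdims=True)
        inertia = float(((x - centroid) ** 2).sum())
        return KMeansModel(1, centroid, inertia, seed)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    km.fit(x)
    return KMeansModel(k, km.cluster_centers_.copy(), float(km.inertia_), seed)


def assign(model: KMeansModel, vectors: np.ndarray) -> np.ndarray:
    """Label each vector by its nearest centroid (Euclidean); exact ties go to
    the lowest cluster index."""
    x = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    if x.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"vector dimension {x.shape[1]} != centroid dimension "
            f"{model.centroids.shape[1]}"
        )
    return cdist(x, model.centroids).argmin(axis=1)


def _pair_agreement(members_other_labels: np.ndarray) -> float:
    """Fraction of unordered pairs within one test cluster that share a label
    under the training-side assignment."""
    n = len(members_other_labels)
    total = n * (n - 1) / 2
    if total == 0:
        return 1.0
    _, counts = np.unique(members_other_labels, return_counts=True)
    same = (counts * (counts - 1) / 2).sum()
    return float(same / total)


def prediction_strength(
    vectors: np.ndarray,
    k: int,
    n_folds: int = 5,
    seed: int = 0,
    n_restarts: int = 10,
) -> list[float]:
    """Per-fold prediction strength of k on the derivation vectors.

    Each fold clusters training and test parts independently; the score is the
    minimum over test-side clusters of the within-cluster pair proportion that
    the training-side centroids co-assign.
    """
    x = np.asarray(vectors, dtype=np.float64)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if k == 1:
        return [1.0] * n_folds
    scores = []
    folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for f, (train_idx, test_idx) in enumerate(folds.split(x)):
        if k > len(test_idx) or k > len(train_idx):
            raise ValueError(f"k={k} exceeds a fold's size")
        train_model = fit_kmeans(x[train_idx], k, seed=seed + f, n_restarts=n_restarts)
        test_model = fit_kmeans(x[test_idx], k, seed=seed + f, n_restarts=n_restarts)
        own = assign(test_model, x[test_idx])
        by_train = assign(train_model, x[test_idx])
        cluster_scores = [
            _pair_agreement(by_train[own == j]) for j in range(k)
        ]
        scores.append(min(cluster_scores))
    return scores


def ps_curve(
    vectors: np.ndarray,
    k_max: int,
    n_folds: int = 5,
    seed: int = 0,
    threshold: float = 0.8,
    n_restarts: int = 10,
) -> PSCurve:
    """Prediction strength over the contiguous candidate range 1..k_max."""
    curve = PSCurve(threshold=threshold)
    for k in range(1, k_max + 1):
        curve.fold_scores[k] = prediction_strength(
            vectors, k, n_folds=n_folds, seed=seed, n_restarts=n_restarts
        )
    return curve


def select_optimal_k(curve: PSCurve, threshold: float | None = None) -> int:
    """Largest k whose fold-mean prediction strength clears the threshold.

    Falls back to k = 1 (with a warning) when no larger k qualifies."""
    if not curve.fold_scores:
        raise ValueError("empty prediction-strength curve")
    thr = curve.threshold if threshold is None else threshold
    qualifying = [k for k in curve.ks if curve.mean(k) >= thr]
    k_star = max(qualifying) if qualifying else 1
    if k_star == 1:
        warnings.warn(
            "only k = 1 clears the prediction-strength threshold; "
            "no multi-cluster structure detected",
            stacklevel=2,
        )
    return k_star


def _check_labels(vectors: np.ndarray, labels: np.ndarray) -> None:
    if len(set(labels.tolist())) < 2:
        raise DegenerateClusteringError(
            "quality scores are undefined for a single cluster"
        )


def silhouette(vectors: np.ndarray, labels) -> float:
    """Mean silhouette score: per-point (b - a)/max(a, b) with a the mean
    intra-cluster distance and b the smallest mean distance to another
    cluster; singleton points score 0.  Range [-1, 1]."""
    x = np.asarray(vectors, dtype=np.float64)
    labels = np.asarray(labels)
    _check_labels(x, labels)
    return float(_skm.silhouette_score(x, labels))


def calinski_harabasz(vectors: np.ndarray, labels) -> float:
    """Calinski-Harabasz variance-ratio score:
    [tr(B)/(k-1)] / [tr(W)/(n-k)]."""
    x = np.asarray(vectors, dtype=np.float64)
    labels = np.asarray(labels)
    _check_labels(x, labels)
    within = sum(
        float(((x[labels == c] - x[labels == c].mean(0)) ** 2).sum())
        for c in np.unique(labels)
    )
    if within == 0.0:
        raise DegenerateClusteringError(
            "zero within-cluster scatter: variance ratio is infinite"
        )
    return float(_skm.calinski_harabasz_score(x, labels))


def cluster_quality(vectors: np.ndarray, labels) -> ClusterQuality:
    return ClusterQuality(
        silhouette=silhouette(vectors, labels),
        calinski_harabasz=calinski_harabasz(vectors, labels),
    )
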