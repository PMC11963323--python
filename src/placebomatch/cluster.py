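"""k-means clustering of standardized granule colors with k-selection.

Granule colors form distinct light and dark populations, so a single
regression from color to pigment doses fits poorly; clustering first and
regressing per cluster captures the color trends much better. The number
of clusters is chosen by scanning k over a range (default 2-11) and
jointly inspecting the within-cluster sum of squares (SSE, the elbow
curve) and the mean silhouette coefficient. The silhouette peak decides;
the elbow (largest second difference of SSE) is reported as a diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .dataio import Standardizer

__all__ = ["ClusterModel", "KScanReport", "kmeans_fit", "sse", "mean_silhouette", "scan_k", "assign"]


@dataclass
class ClusterModel:
    """A fitted k-means solution in standardized color space."""

    k: int
    centroids: np.ndarray  # (k, 3), standardized units
    labels: np.ndarray  # training assignments
    sse: float  # within-cluster sum of squared distances
    mean_silhouette: float | None
    seed: int

    def to_jsonable(self) -> dict:
        return {
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "sse": self.sse,
            "mean_silhouette": self.mean_silhouette,
            "seed": self.seed,
        }


@dataclass
class KScanReport:
    """SSE / silhouette diagnostics over candidate cluster counts."""

    k_values: list[int]
    sse: list[float]
    silhouette: list[float]
    chosen_k: int
    elbow_k: int | None
    rationale: str

    def to_jsonable(self) -> dict:
        return {
            "k_values": self.k_values,
            "sse": self.sse,
            "silhouette": self.silhouette,
            "chosen_k": self.chosen_k,
            "elbow_k": self.elbow_k,
            "rationale": self.rationale,
        }


def kmeans_fit(
    features: np.ndarray,
    k: int,
    seed: int = 42,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> ClusterModel:
    """Lloyd's algorithm from k-means++ seeding, best of ``n_init``
    restarts by SSE."""
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, max_iter=max_iter, tol=tol, random_state=seed)
    with warnings.catch_warnings():
        # duplicate points can make fewer distinct centers than k; that
        # degeneracy is handled, the warning is noise here
        warnings.simplefilter("ignore")
        labels = km.fit_predict(X)
    sil = None
    n_found = len(np.unique(labels))
    if 2 <= n_found <= n - 1:  # silhouette undefined for k=1 and k=n
        sil = mean_silhouette(X, labels)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_.copy(),
        labels=labels,
        sse=float(km.inertia_),
        mean_silhouette=sil,
        seed=seed,
    )


def sse(model: ClusterModel, features: np.ndarray) -> float:
    """Sum over points of the squared distance to the centroid of the
    point's assigned (nearest) cluster."""
    X = np.asarray(features, dtype=float)
    d2 = cdist(X, model.centroids, metric="sqeuclidean")
    return float(d2.min(axis=1).sum())


def mean_silhouette(features: np.ndarray, labels: np.ndarray) -> float:
    """Mean over points of s = (b - a) / max(a, b), where a is the mean
    distance to the point's own cluster and b the smallest mean distance
    to another cluster. Singleton clusters contribute s = 0."""
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    return float(silhouette_score(X, labels, metric="euclidean"))


def scan_k(
    features: np.ndarray,
    k_range: "range | list[int]" = range(2, 12),
    seed: int = 42,
    **kmeans_kwargs,
) -> KScanReport:
    """Fit every candidate k, record SSE and mean silhouette, and choose
    the silhouette argmax (ties break toward smaller k)."""
    X = np.asarray(features, dtype=float)
    ks = [int(k) for k in k_range]
    feasible = [k for k in ks if 2 <= k <= X.shape[0] - 1]
    if feasible != ks:
        warnings.warn(
            f"k range truncated to {feasible} (need 2 <= k <= n-1 for silhouettes)",
            stacklevel=2,
        )
    if not feasible:
        raise ValueError("no feasible k in range for this sample count")

    sses, sils = [], []
    for k in feasible:
        m = kmeans_fit(X, k, seed=seed, **kmeans_kwargs)
        sses.append(m.sse)
        sils.append(m.mean_silhouette if m.mean_silhouette is not None else -1.0)

    best = int(np.argmax(sils))  # argmax takes the first (smallest k) on ties
    chosen = feasible[best]
    elbow = None
    if len(sses) >= 3:
        second_diff = np.diff(sses, 2)  # positive where the curve flattens
        elbow = feasible[int(np.argmax(second_diff)) + 1]
    rationale = (
        f"mean silhouette peaks at k={chosen} ({sils[best]:.4f}); "
        f"elbow diagnostic suggests k={elbow}" if elbow is not None else
        f"mean silhouette peaks at k={chosen} ({sils[best]:.4f})"
    )
    return KScanReport(
        k_values=feasible,
        sse=sses,
        silhouette=sils,
        chosen_k=chosen,
        elbow_k=elbow,
        rationale=rationale,
    )


def assign(model: ClusterModel, colors, standardizer: Standardizer | None = None) -> np.ndarray:
    """Nearest-centroid labels for new colors.

    If a standardizer is given, raw RGB colors are standardized with the
    *training* statistics first; otherwise the input is assumed to be in
    standardized space already. Ties go to the lowest centroid index.
    """
    if standardizer is not None:
        Z = standardizer.transform(colors)
    else:
        Z = np.atleast_2d(np.asarray(colors, dtype=float))
    d2 = cdist(Z, model.centroids, metric="sqeuclidean")
    return d2.argmin(axis=1)  # argmin returns the first minimum: lowest index
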