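"""k-means construction of psychosis biotypes on the bio-factor scores.

A vectorized Lloyd's algorithm with k-means++ starts and a best-of-restarts
policy builds the proband subgroups.  Cluster indices coming out of k-means
are arbitrary, so a deterministic canonical relabeling maps them onto the
field's naming convention: biotype 1 is the cluster with the lowest
ERP-magnitude composite (mean centroid over the paired-stimuli ERP, oddball
ERP and intrinsic-EEG factors), biotype 2 the remaining cluster with the
higher intrinsic/ongoing-activity composite, biotype 3 the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import kmeans_plusplus

__all__ = ["ClusterSolution", "LloydKMeans", "kmeans", "canonical_labels"]

#: factors entering the ERP-magnitude composite used for canonical labeling
ERP_MAGNITUDE_FACTORS = ("ps_erp", "ob_erp", "iea")
#: factors entering the intrinsic/ongoing-activity composite
ONGOING_FACTORS = ("ps_ongoing", "ob_ongoing", "iea")


@dataclass
class ClusterSolution:
    """A labeled k-means fit."""

    k: int
    centroids: np.ndarray
    labels: np.ndarray  # 1-based cluster labels per subject
    inertia: float
    n_iter: int
    seed: int | None
    n_init: int
    factor_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.centroids).all():
            raise ValueError("centroids must be finite")
        present = np.unique(self.labels)
        if present.min() < 1 or present.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        if len(present) != self.k:
            raise ValueError("every cluster must be non-empty")

    def relabel(self, mapping: dict[int, int]) -> "ClusterSolution":
        new_labels = np.array([mapping[l] for l in self.labels])
        order = np.argsort([mapping[c + 1] for c in range(self.k)])
        return ClusterSolution(
            k=self.k,
            centroids=self.centroids[order],
            labels=new_labels,
            inertia=self.inertia,
            n_iter=self.n_iter,
            seed=self.seed,
            n_init=self.n_init,
            factor_labels=self.factor_labels,
        )


def _lloyd_single(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    check_monotone: bool = False,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    n = X.shape[0]
    centers, _ = kmeans_plusplus(
        X, n_clusters=k, random_state=int(rng.integers(2**31 - 1))
    )
    x_sq = (X**2).sum(axis=1)
    prev_inertia = np.inf
    for it in range(1, max_iter + 1):
        d2 = x_sq[:, None] - 2 * X @ centers.T + (centers**2).sum(axis=1)
        labels = np.argmin(d2, axis=1)
        # reseed empty clusters at the farthest point from its centroid
        for c in range(k):
            if not np.any(labels == c):
                far = int(np.argmax(np.take_along_axis(d2, labels[:, None], 1)))
                centers[c] = X[far]
                labels[far] = c
        inertia = float(((X - centers[labels]) ** 2).sum())
        if check_monotone and inertia > prev_inertia + 1e-8:
            raise AssertionError("inertia increased across Lloyd iterations")
        prev_inertia = inertia
        new_centers = np.empty_like(centers)
        counts = np.bincount(labels, minlength=k).astype(float)
        for j in range(X.shape[1]):
            new_centers[:, j] = np.bincount(labels, weights=X[:, j], minlength=k) / counts
        shift = float(np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max())
        centers = new_centers
        if shift < tol:
            break
    d2 = x_sq[:, None] - 2 * X @ centers.T + (centers**2).sum(axis=1)
    labels = np.argmin(d2, axis=1)
    inertia = float(((X - centers[labels]) ** 2).sum())
    return centers, labels, inertia, it


class LloydKMeans(BaseEstimator, ClusterMixin):
    """Lloyd's k-means with k-means++ starts, best of ``n_init`` restarts.

    Empty clusters are reseeded at the point farthest from its current
    centroid.  A fixed ``random_state`` (plus fixed ``n_init``) reproduces
    the solution exactly.
    """

    def __init__(
        self,
        n_clusters: int = 3,
        n_init: int = 50,
        max_iter: int = 300,
        tol: float = 1e-6,
        random_state: int | None = None,
        check_monotone: bool = False,
    ):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.check_monotone = check_monotone

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("input contains missing values")
        n = X.shape[0]
        k = self.n_clusters
        if k > n:
            raise ValueError(f"k={k} exceeds the number of points n={n}")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init):
            centers, labels, inertia, n_iter = _lloyd_single(
                X, k, rng, self.max_iter, self.tol, self.check_monotone
            )
            if best is None or inertia < best[2] - 1e-12:
                best = (centers, labels, inertia, n_iter)
        self.cluster_centers_, self.labels_, self.inertia_, self.n_iter_ = best
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        d2 = (
            (X**2).sum(axis=1)[:, None]
            - 2 * X @ self.cluster_centers_.T
            + (self.cluster_centers_**2).sum(axis=1)
        )
        return np.argmin(d2, axis=1)


def kmeans(
    X,
    k: int,
    n_init: int = 50,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
    factor_labels: list[str] | None = None,
) -> ClusterSolution:
    """Fit k-means and wrap the result as a :class:`ClusterSolution`."""
    if factor_labels is None and isinstance(X, pd.DataFrame):
        factor_labels = list(X.columns)
    est = LloydKMeans(
        n_clusters=k, n_init=n_init, max_iter=max_iter, tol=tol, random_state=seed
    ).fit(X)
    return ClusterSolution(
        k=k,
        centroids=est.cluster_centers_,
        labels=est.labels_ + 1,
        inertia=est.inertia_,
        n_iter=est.n_iter_,
        seed=seed,
        n_init=n_init,
        factor_labels=factor_labels or [],
    )


def canonical_labels(solution: ClusterSolution) -> ClusterSolution:
    """Deterministically relabel a 3-cluster solution as biotypes 1/2/3.

    BT1 = lowest ERP-magnitude composite; BT2 = of the remaining clusters,
    the one with the higher ongoing/intrinsic-activity composite; BT3 = the
    remainder.  Composite ties break by cluster size, then index.  For k
    other than 3 the clusters are simply ordered by their first centroid
    coordinate (with a warning).
    """
    import warnings

    labels = solution.factor_labels
    has_composites = any(f in labels for f in ERP_MAGNITUDE_FACTORS) and any(
        f in labels for f in ONGOING_FACTORS
    )
    if solution.k != 3 or not has_composites:
        warnings.warn("canonical biotype labeling requires k=3 with factor labels; "
                      "ordering clusters by first centroid coordinate")
        order = np.argsort(solution.centroids[:, 0], kind="stable")
        mapping = {int(c) + 1: rank + 1 for rank, c in enumerate(order)}
        return solution.relabel(mapping)

    def composite(names) -> np.ndarray:
        idx = [labels.index(f) for f in names if f in labels]
        if not idx:
            raise ValueError(f"no composite factors found among {labels}")
        return solution.centroids[:, idx].mean(axis=1)

    erp = composite(ERP_MAGNITUDE_FACTORS)
    ongoing = composite(ONGOING_FACTORS)
    sizes = np.bincount(solution.labels - 1, minlength=3)

    # sort key: composite value, then -size, then index (for ties)
    def keyed(vals):
        return sorted(range(3), key=lambda c: (vals[c], -sizes[c], c))

    bt1 = keyed(erp)[0]
    rest = [c for c in range(3) if c != bt1]
    bt2 = max(rest, key=lambda c: (ongoing[c], sizes[c], -c))
    bt3 = next(c for c in rest if c != bt2)
    mapping = {bt1 + 1: 1, bt2 + 1: 2, bt3 + 1: 3}
    return solution.relabel(mapping)
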