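"""Cluster-number estimation: gap statistic and a validity-index ensemble.

The gap statistic compares the log within-cluster dispersion of the data
with its expectation under a uniform reference distribution drawn over the
per-feature bounding box, choosing the smallest k whose gap is within one
simulation standard error of the next one.  A panel of ten classical
validity indices (Calinski-Harabasz, Hartigan, silhouette, Davies-Bouldin,
Dunn, C-index, Krzanowski-Lai, Ball-Hall, Ratkowsky-Lance, gap) each cast a
vote for their preferred k, and a majority rule — ties resolving to the
most parsimonious k — picks the winner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .biotype import ClusterSolution, LloydKMeans, kmeans

__all__ = [
    "GapCurve",
    "VoteTable",
    "gap_statistic",
    "validity_indices",
    "majority_rule",
    "INDEX_PANEL",
]

INDEX_PANEL = (
    "calinski_harabasz",
    "hartigan",
    "silhouette",
    "davies_bouldin",
    "dunn",
    "c_index",
    "krzanowski_lai",
    "ball_hall",
    "ratkowsky_lance",
    "gap",
)


@dataclass
class GapCurve:
    k_values: np.ndarray
    W: np.ndarray            # within-cluster dispersion per k
    log_W: np.ndarray
    ref_log_W: np.ndarray    # mean reference log dispersion per k
    gap: np.ndarray
    s: np.ndarray            # simulation SE, sd * sqrt(1 + 1/B)
    B: int

    def __post_init__(self) -> None:
        if np.any(self.W <= 0):
            raise ValueError("within-cluster dispersion must be positive "
                             "(degenerate clustering, e.g. k = n)")
        if np.any(self.s < 0):
            raise ValueError("simulation SE must be non-negative")

    @property
    def chosen_k(self) -> int:
        """Smallest k with Gap(k) >= Gap(k+1) - s_{k+1}."""
        g, s = self.gap, self.s
        for i in range(len(g) - 1):
            if g[i] >= g[i + 1] - s[i + 1]:
                return int(self.k_values[i])
        return int(self.k_values[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            dict(k=self.k_values, W=self.W, log_W=self.log_W,
                 ref_log_W=self.ref_log_W, gap=self.gap, s=self.s)
        )


def _dispersion_curve(
    X: np.ndarray, kmax: int, rng: np.random.Generator, n_init: int,
    tol: float = 1e-6,
) -> np.ndarray:
    """W_k for k = 1..kmax (sum of within-cluster squared distances)."""
    W = np.empty(kmax)
    W[0] = float(((X - X.mean(axis=0)) ** 2).sum())
    for k in range(2, kmax + 1):
        est = LloydKMeans(
            n_clusters=k, n_init=n_init, tol=tol,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(X)
        W[k - 1] = est.inertia_
    return W


def gap_statistic(
    X,
    kmax: int = 8,
    B: int = 100,
    seed: int | None = None,
    n_init: int = 10,
    ref_n_init: int = 2,
) -> GapCurve:
    """Gap statistic of Tibshirani et al. with uniform bounding-box references."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= kmax:
        raise ValueError("need more points than kmax")
    if B < 10:
        raise ValueError("need at least 10 reference data sets")
    rng = np.random.default_rng(seed)

    W = _dispersion_curve(X, kmax, rng, n_init)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ref_logs = np.empty((B, kmax))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=(n, p))
        # looser convergence for references: only log W enters an average
        ref_logs[b] = np.log(
            _dispersion_curve(ref, kmax, rng, ref_n_init, tol=1e-3)
        )

    ref_mean = ref_logs.mean(axis=0)
    sd = ref_logs.std(axis=0, ddof=0)
    return GapCurve(
        k_values=np.arange(1, kmax + 1),
        W=W,
        log_W=np.log(W),
        ref_log_W=ref_mean,
        gap=ref_mean - np.log(W),
        s=sd * np.sqrt(1 + 1.0 / B),
        B=B,
    )


# ---------------------------------------------------------------------------
# validity indices
# ---------------------------------------------------------------------------

def _cluster_stats(X: np.ndarray, labels: np.ndarray):
    ks = np.unique(labels)
    centroids = np.stack([X[labels == c].mean(axis=0) for c in ks])
    sizes = np.array([(labels == c).sum() for c in ks])
    wgss = sum(
        float(((X[labels == c] - centroids[i]) ** 2).sum())
        for i, c in enumerate(ks)
    )
    return ks, centroids, sizes, wgss


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    n = len(X)
    ks, centroids, sizes, wgss = _cluster_stats(X, labels)
    k = len(ks)
    tss = float(((X - X.mean(axis=0)) ** 2).sum())
    bgss = tss - wgss
    return (bgss / (k - 1)) / (wgss / (n - k))


def silhouette_mean(X: np.ndarray, labels: np.ndarray, D: np.ndarray | None = None) -> float:
    """Mean silhouette width; singleton clusters contribute 0."""
    if D is None:
        D = squareform(pdist(X))
    ks = np.unique(labels)
    onehot = (labels[:, None] == ks[None, :]).astype(float)
    sizes = onehot.sum(axis=0)
    sums = D @ onehot  # n x k: total distance from each point to each cluster
    own = (labels[:, None] == ks[None, :])
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        c = np.flatnonzero(own[i])[0]
        if sizes[c] <= 1:
            continue
        a = sums[i, c] / (sizes[c] - 1)
        b = np.min([sums[i, j] / sizes[j] for j in range(len(ks)) if j != c])
        s[i] = (b - a) / max(a, b)
    return float(s.mean())


def davies_bouldin(X: np.ndarray, labels: np.ndarray) -> float:
    ks, centroids, sizes, _ = _cluster_stats(X, labels)
    k = len(ks)
    S = np.array(
        [
            float(np.sqrt(((X[labels == c] - centroids[i]) ** 2).sum(axis=1)).mean())
            for i, c in enumerate(ks)
        ]
    )
    M = squareform(pdist(centroids))
    ratios = np.zeros(k)
    for i in range(k):
        with np.errstate(divide="ignore"):
            r = np.array([(S[i] + S[j]) / M[i, j] for j in range(k) if j != i])
        ratios[i] = r.max()
    return float(ratios.mean())


def dunn_index(X: np.ndarray, labels: np.ndarray, D: np.ndarray | None = None) -> float:
    if D is None:
        D = squareform(pdist(X))
    ks = np.unique(labels)
    diam = max(
        float(D[np.ix_(labels == c, labels == c)].max()) for c in ks
    )
    if diam == 0:
        raise ValueError("zero cluster diameter")
    min_between = min(
        float(D[np.ix_(labels == a, labels == b)].min())
        for i, a in enumerate(ks)
        for b in ks[i + 1:]
    )
    return min_between / diam


def c_index(X: np.ndarray, labels: np.ndarray, d_sorted: np.ndarray | None = None) -> float:
    d = pdist(X)
    if d_sorted is None:
        d_sorted = np.sort(d)
    same_m = (labels[:, None] == labels[None, :]).astype(float)
    np.fill_diagonal(same_m, 0.0)
    same = squareform(same_m, checks=False).astype(bool)
    S = float(d[same].sum())
    n_w = int(same.sum())
    s_min = float(d_sorted[:n_w].sum())
    s_max = float(d_sorted[-n_w:].sum())
    if s_max == s_min:
        raise ValueError("degenerate distance distribution")
    return (S - s_min) / (s_max - s_min)


def ratkowsky_lance(X: np.ndarray, labels: np.ndarray) -> float:
    ks, centroids, sizes, _ = _cluster_stats(X, labels)
    k = len(ks)
    grand = X.mean(axis=0)
    bgss_j = (sizes[:, None] * (centroids - grand) ** 2).sum(axis=0)
    tss_j = ((X - grand) ** 2).sum(axis=0)
    cbar = float(np.sqrt(bgss_j / tss_j).mean())
    return cbar / np.sqrt(k)


@dataclass
class VoteTable:
    votes: dict[str, int | None]
    kmax: int
    abstained: list[str] = field(default_factory=list)

    @property
    def tally(self) -> dict[int, int]:
        t: dict[int, int] = {}
        for v in self.votes.values():
            if v is not None:
                t[v] = t.get(v, 0) + 1
        return t

    @property
    def winner(self) -> int:
        return majority_rule(self)


def majority_rule(votes: VoteTable) -> int:
    """k with the most votes; ties resolve to the smallest (most
    parsimonious) k."""
    tally = votes.tally
    if not tally:
        raise ValueError("all indices abstained; no votes to tally")
    best = max(tally.values())
    return min(k for k, v in tally.items() if v == best)


def validity_indices(
    X,
    solutions: dict[int, ClusterSolution],
    gap_curve: GapCurve | None = None,
    seed: int | None = None,
    gap_B: int = 50,
) -> VoteTable:
    """Cast one best-k vote per validity index.

    ``solutions`` maps k (2..kmax) to fitted cluster solutions on the same
    data.  An index that is undefined for some k (singleton clusters,
    degenerate distances) abstains for that k; an index undefined for all k
    abstains entirely and is logged in ``abstained``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    k_range = sorted(solutions)
    kmax = max(k_range)
    labels = {k: solutions[k].labels - 1 for k in k_range}
    W = {k: solutions[k].inertia for k in k_range}
    W[1] = float(((X - X.mean(axis=0)) ** 2).sum())

    D = squareform(pdist(X))
    d_sorted = np.sort(squareform(D, checks=False))

    def argbest(scores: dict[int, float], mode: str) -> int | None:
        clean = {k: v for k, v in scores.items() if np.isfinite(v)}
        if not clean:
            return None
        best = (max if mode == "max" else min)(clean.values())
        return min(k for k, v in clean.items() if v == best)

    votes: dict[str, int | None] = {}
    abstained: list[str] = []

    def per_k(fn, mode, name, **kw):
        scores = {}
        for k in k_range:
            try:
                scores[k] = fn(X, labels[k], **kw)
            except Exception as e:  # undefined for this k -> abstain there
                warnings.warn(f"{name} undefined for k={k}: {e}")
        votes[name] = argbest(scores, mode)
        if votes[name] is None:
            abstained.append(name)

    per_k(calinski_harabasz, "max", "calinski_harabasz")
    per_k(silhouette_mean, "max", "silhouette", D=D)
    per_k(davies_bouldin, "min", "davies_bouldin")
    per_k(dunn_index, "max", "dunn", D=D)
    per_k(c_index, "min", "c_index", d_sorted=d_sorted)
    per_k(ratkowsky_lance, "max", "ratkowsky_lance")

    # Hartigan: smallest k with H(k) <= 10, H(k) = (W_k/W_{k+1} - 1)(n-k-1)
    hart = None
    for k in [1] + k_range:
        if k + 1 not in W:
            continue
        H = (W[k] / W[k + 1] - 1.0) * (n - k - 1)
        if H <= 10:
            hart = k
            break
    votes["hartigan"] = hart if hart is not None else kmax
    if hart == 1:
        votes["hartigan"] = 1

    # Krzanowski-Lai: KL(k) = |DIFF_k| / |DIFF_{k+1}|
    def diff(k):
        return (k - 1) ** (2.0 / p) * W[k - 1] - k ** (2.0 / p) * W[k]

    kl_scores = {}
    for k in k_range:
        if (k - 1 in W or k == 2) and k + 1 in W:
            d_next = diff(k + 1)
            if d_next != 0:
                kl_scores[k] = abs(diff(k)) / abs(d_next)
    votes["krzanowski_lai"] = argbest(kl_scores, "max")
    if votes["krzanowski_lai"] is None:
        abstained.append("krzanowski_lai")

    # Ball-Hall: largest drop of W_k / k between successive k
    bh = {k: W[k] / k for k in [1] + k_range}
    drops = {k: bh[k - 1] - bh[k] for k in k_range if k - 1 in bh}
    votes["ball_hall"] = argbest(drops, "max")

    # gap statistic
    if gap_curve is None:
        gap_curve = gap_statistic(X, kmax=kmax, B=gap_B, seed=seed)
    votes["gap"] = gap_curve.chosen_k

    return VoteTable(votes=votes, kmax=kmax, abstained=abstained)


def solutions_for_range(
    X, k_range=range(2, 9), n_init: int = 10, seed: int | None = None
) -> dict[int, ClusterSolution]:
    """Fit k-means solutions for every k in ``k_range`` on the same data."""
    rng = np.random.default_rng(seed)
    return {
        k: kmeans(X, k, n_init=n_init, seed=int(rng.integers(2**31 - 1)))
        for k in k_range
    }
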