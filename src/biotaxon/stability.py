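"""Bootstrap membership-consistency of the k-means solution.

Random subsamples of the probands (without replacement, a range of sizes)
are re-standardized, re-clustered, and compared with the full-sample
solution restricted to the sampled subjects, using the unadjusted Rand
index and the Hubert-Arabie adjusted Rand index as the least and most
conservative agreement estimates.  Per size the experiment reports the
replicate means, 99% normal-approximation confidence half-widths, and the
40th/60th percentile band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biotype import ClusterSolution, kmeans

__all__ = [
    "PartitionPair",
    "ConsistencyCurve",
    "rand_index",
    "adjusted_rand_index",
    "subsample_experiment",
]


@dataclass
class PartitionPair:
    """Contingency counts between two labelings of the same subjects."""

    table: np.ndarray

    @classmethod
    def from_labels(cls, labels_a, labels_b) -> "PartitionPair":
        a = np.asarray(labels_a)
        b = np.asarray(labels_b)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("labelings must be 1-d and of equal length")
        if a.size < 2:
            raise ValueError("need at least 2 subjects")
        _, ai = np.unique(a, return_inverse=True)
        _, bi = np.unique(b, return_inverse=True)
        table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
        np.add.at(table, (ai, bi), 1)
        return cls(table=table)

    @property
    def n(self) -> int:
        return int(self.table.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.table.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.table.sum(axis=0)


def _comb2(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x * (x - 1) / 2.0


def rand_index(labels_a, labels_b) -> float:
    """Unadjusted Rand index: concordant pairs / all pairs."""
    pair = PartitionPair.from_labels(labels_a, labels_b)
    n = pair.n
    total = _comb2(n)
    sum_nij = _comb2(pair.table).sum()
    sum_a = _comb2(pair.row_sums).sum()
    sum_b = _comb2(pair.col_sums).sum()
    # together-in-both + apart-in-both
    concordant = total + 2 * sum_nij - sum_a - sum_b
    return float(concordant / total)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert-Arabie adjusted Rand index from the contingency table."""
    pair = PartitionPair.from_labels(labels_a, labels_b)
    sum_nij = _comb2(pair.table).sum()
    sum_a = _comb2(pair.row_sums).sum()
    sum_b = _comb2(pair.col_sums).sum()
    expected = sum_a * sum_b / _comb2(pair.n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        # both labelings trivial (e.g. single cluster each): identical partitions
        return 1.0
    return float((sum_nij - expected) / (max_index - expected))


@dataclass
class ConsistencyCurve:
    """Rand / adjusted-Rand consistency versus subsample size."""

    sizes: np.ndarray
    n_reps: int
    summary: pd.DataFrame
    ri_reps: dict[int, np.ndarray] = field(default_factory=dict)
    ari_reps: dict[int, np.ndarray] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)


def subsample_experiment(
    scores,
    full: ClusterSolution,
    sizes,
    n_reps: int = 1000,
    seed: int | None = None,
    n_init: int = 10,
    restandardize: bool = True,
) -> ConsistencyCurve:
    """Rand/ARI of subsample k-means solutions against the full solution.

    Per replicate: draw ``m`` probands without replacement, re-z-score the
    subsample, run k-means with the full solution's k (fresh k-means++
    starts, no warm start), and compare against the full-sample labels
    restricted to the drawn subjects.
    """
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    sizes = sorted(int(m) for m in sizes)
    k = full.k
    for m in sizes:
        if m > n:
            raise ValueError(f"subsample size {m} exceeds n={n}")
        if m < 3 * k:
            raise ValueError(f"subsample size {m} too small for k={k}")
    if len(full.labels) != n:
        raise ValueError("full solution must be fitted on all probands")
    rng = np.random.default_rng(seed)

    rows = []
    ri_reps: dict[int, np.ndarray] = {}
    ari_reps: dict[int, np.ndarray] = {}
    z = 2.5758293035489004  # 99% two-sided normal quantile
    for m in sizes:
        ri = np.empty(n_reps)
        ari = np.empty(n_reps)
        for r in range(n_reps):
            idx = rng.choice(n, size=m, replace=False)
            sub = X[idx]
            if restandardize:
                sd = sub.std(axis=0, ddof=1)
                sd[sd == 0] = 1.0
                sub = (sub - sub.mean(axis=0)) / sd
            sol = kmeans(
                sub, k, n_init=n_init, seed=int(rng.integers(2**31 - 1))
            )
            ri[r] = rand_index(sol.labels, full.labels[idx])
            ari[r] = adjusted_rand_index(sol.labels, full.labels[idx])
        ri_reps[m], ari_reps[m] = ri, ari
        rows.append(
            dict(
                size=m,
                mean_RI=ri.mean(),
                mean_ARI=ari.mean(),
                ci99_RI=z * ri.std(ddof=1) / np.sqrt(n_reps),
                ci99_ARI=z * ari.std(ddof=1) / np.sqrt(n_reps),
                p40_RI=np.percentile(ri, 40),
                p60_RI=np.percentile(ri, 60),
                p40_ARI=np.percentile(ari, 40),
                p60_ARI=np.percentile(ari, 60),
            )
        )
    return ConsistencyCurve(
        sizes=np.array(sizes),
        n_reps=n_reps,
        summary=pd.DataFrame(rows),
        ri_reps=ri_reps,
        ari_reps=ari_reps,
    )
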