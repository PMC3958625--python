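"""K-means clustering of user vectors, with profiling and recovery metrics.

This is a from-scratch Lloyd implementation because the clustering *is*
the analysis: users are grouped by Euclidean proximity of their
normalized vectors, iterating assignment and centroid updates until no
membership changes.  Initialization is a deterministic farthest-point
heuristic (first centroid = the point nearest the grand mean, each next
centroid = the point farthest from the already-chosen set), which guards
against bad random placements; additional restarts use seeded random
initialization and the best run by within-cluster SSE wins.

Within-cluster SSE (the k-means objective) strictly decreases on every
membership change, so membership-stability termination is guaranteed on
finite data; ``max_iter`` is only a safeguard.  An emptied cluster is
reseeded to the point currently farthest from its centroid, keeping k
fixed.  Assignment ties break to the lowest cluster index.

Recovery of planted labels is scored by exhaustive best-permutation
agreement (k <= 8) and the adjusted Rand index.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureMatrix

__all__ = [
    "ClusteringConfig",
    "ClusteringResult",
    "ClusterProfile",
    "kmeans",
    "internal_metrics",
    "profile",
    "match_clusters",
    "adjusted_rand_index",
    "silhouette",
]


@dataclass(frozen=True)
class ClusteringConfig:
    k: int = 6
    max_iter: int = 300
    n_restarts: int = 20
    seed: int = 0
    init: str = "heuristic"  # heuristic | random

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.init not in ("heuristic", "random"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class ClusteringResult:
    assignments: np.ndarray  # row -> cluster index
    centroids: np.ndarray  # (k, d)
    iterations: int
    within_sse: float
    converged: bool
    sse_trace: list[float] = field(default_factory=list)
    users: list[str] | None = None

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)


def _sq_dists(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, (n, k)."""
    return ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)


def _heuristic_init(X: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-point seeding.

    Start from the point nearest the grand mean; repeatedly add the
    point maximizing its minimum distance to the chosen set (ties to the
    lowest row index).
    """
    grand = X.mean(axis=0)
    first = int(np.argmin(((X - grand) ** 2).sum(axis=1)))
    chosen = [first]
    min_d = ((X - X[first]) ** 2).sum(axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(min_d))
        chosen.append(nxt)
        min_d = np.minimum(min_d, ((X - X[nxt]) ** 2).sum(axis=1))
    return X[chosen].copy()


def _lloyd(X: np.ndarray, centroids: np.ndarray, max_iter: int):
    n, _ = X.shape
    k = centroids.shape[0]
    assign = np.full(n, -1, dtype=int)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = _sq_dists(X, centroids)
        new_assign = np.argmin(d2, axis=1)  # argmin ties -> lowest index
        # reseed emptied clusters to the worst-fit point
        for c in range(k):
            if not (new_assign == c).any():
                worst = int(np.argmax(d2[np.arange(n), new_assign]))
                new_assign[worst] = c
                centroids[c] = X[worst]
                d2 = _sq_dists(X, centroids)
        sse = float(d2[np.arange(n), new_assign].sum())
        trace.append(sse)
        if (new_assign == assign).all():
            converged = True
            break
        assign = new_assign
        for c in range(k):
            centroids[c] = X[assign == c].mean(axis=0)
    final_sse = float(_sq_dists(X, centroids)[np.arange(n), assign].sum())
    return assign, centroids, it, final_sse, trace, converged


def kmeans(matrix: FeatureMatrix, config: ClusteringConfig) -> ClusteringResult:
    """Best-of-restarts Lloyd clustering of the matrix rows.

    With heuristic init, the first restart is the deterministic
    farthest-point seeding and the remaining restarts are seeded random
    row draws; the run with the lowest within-cluster SSE is returned.
    Deterministic given ``config.seed``.
    """
    X = matrix.values()
    n = X.shape[0]
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    if config.k > n:
        raise ValueError(f"k={config.k} exceeds number of rows n={n}")
    rng = np.random.default_rng(config.seed)
    best: ClusteringResult | None = None
    for r in range(config.n_restarts):
        if config.init == "heuristic" and r == 0:
            C0 = _heuristic_init(X, config.k)
        else:
            C0 = X[rng.choice(n, size=config.k, replace=False)].copy()
        assign, C, iters, sse, trace, conv = _lloyd(X, C0.copy(), config.max_iter)
        if best is None or sse < best.within_sse - 1e-12:
            best = ClusteringResult(
                assignments=assign,
                centroids=C,
                iterations=iters,
                within_sse=sse,
                converged=conv,
                sse_trace=trace,
                users=matrix.users,
            )
    return best


# ---------------------------------------------------------------------------
# Internal evaluation


def silhouette(X: np.ndarray, assign: np.ndarray) -> float:
    """Mean silhouette coefficient under Euclidean distance.

    NaN when k == 1 (undefined); singleton points score 0 by convention.
    """
    labels = np.unique(assign)
    if labels.size < 2:
        return float("nan")
    D = np.sqrt(_sq_dists(X, X))
    n = X.shape[0]
    s = np.zeros(n)
    for i in range(n):
        own = assign == assign[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(
            D[i, assign == c].mean() for c in labels if c != assign[i]
        )
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean())


def internal_metrics(matrix: FeatureMatrix, result: ClusteringResult) -> dict:
    X = matrix.values()
    sse = float(
        _sq_dists(X, result.centroids)[np.arange(X.shape[0]), result.assignments].sum()
    )
    return {"within_sse": sse, "mean_silhouette": silhouette(X, result.assignments)}


# ---------------------------------------------------------------------------
# Profiling


@dataclass
class ClusterProfile:
    """Per-cluster summaries feeding the radar charts.

    ``minmax_means`` rescales each feature's cluster means to [0, 1]
    across clusters; ``unit_sums`` (preference clustering only) is each
    cluster's member-vector sum rescaled to a unit vector.
    """

    sizes: np.ndarray
    raw_means: pd.DataFrame
    minmax_means: pd.DataFrame
    unit_sums: pd.DataFrame | None = None
    constant_features: list[str] = field(default_factory=list)


def profile(
    matrix_raw: FeatureMatrix,
    result: ClusteringResult,
    preference: bool = False,
) -> ClusterProfile:
    if matrix_raw.users != result.users:
        raise ValueError("profile rows do not match clustering rows")
    X = matrix_raw.values()
    k = result.k
    cols = list(matrix_raw.data.columns)
    means = np.vstack([X[result.assignments == c].mean(axis=0) for c in range(k)])
    lo, hi = means.min(axis=0), means.max(axis=0)
    span = hi - lo
    constant = [cols[j] for j in np.flatnonzero(span == 0)]
    span_safe = np.where(span == 0, 1.0, span)
    mm = (means - lo) / span_safe
    mm[:, span == 0] = 0.0
    idx = pd.RangeIndex(k, name="cluster")
    unit_sums = None
    if preference:
        sums = np.vstack([X[result.assignments == c].sum(axis=0) for c in range(k)])
        norms = np.linalg.norm(sums, axis=1)
        norms = np.where(norms == 0, 1.0, norms)
        unit_sums = pd.DataFrame(sums / norms[:, None], index=idx, columns=cols)
    return ClusterProfile(
        sizes=result.sizes(),
        raw_means=pd.DataFrame(means, index=idx, columns=cols),
        minmax_means=pd.DataFrame(mm, index=idx, columns=cols),
        unit_sums=unit_sums,
        constant_features=constant,
    )


# ---------------------------------------------------------------------------
# Recovery metrics


def adjusted_rand_index(a, b) -> float:
    """ARI from the contingency table (standard permutation-model form)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def match_clusters(planted, recovered) -> tuple[float, float]:
    """(best-permutation agreement rate, ARI) between two labelings.

    Agreement is maximized over all permutations of the recovered
    cluster indices onto planted labels; exhaustive up to 8 clusters.
    """
    planted = np.asarray(planted)
    recovered = np.asarray(recovered)
    if planted.shape != recovered.shape:
        raise ValueError("planted and recovered labelings differ in length")
    _, pi = np.unique(planted, return_inverse=True)
    _, ri = np.unique(recovered, return_inverse=True)
    kp, kr = int(pi.max()) + 1, int(ri.max()) + 1
    if max(kp, kr) > 8:
        raise ValueError("exhaustive permutation matching limited to 8 clusters")
    table = np.zeros((kp, kr), dtype=np.int64)
    np.add.at(table, (pi, ri), 1)
    n = planted.size
    best = 0
    # injectively map the smaller index set into the larger; agreement is
    # the sum of the matched contingency cells
    if kr <= kp:
        for perm in itertools.permutations(range(kp), kr):
            best = max(best, sum(table[perm[r], r] for r in range(kr)))
    else:
        for perm in itertools.permutations(range(kr), kp):
            best = max(best, sum(table[p, perm[p]] for p in range(kp)))
    return best / n, adjusted_rand_index(planted, recovered)
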