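import itertools

import numpy as np
import pandas as pd
import pytest

from forumminer import (
    ClusteringConfig,
    FeatureMatrix,
    adjusted_rand_index,
    internal_metrics,
    kmeans,
    match_clusters,
    profile,
)
from forumminer.cluster import silhouette


def _matrix(arr):
    return FeatureMatrix(
        data=pd.DataFrame(
            np.asarray(arr, dtype=float),
            index=[f"u{i}" for i in range(len(arr))],
            columns=[f"f{j}" for j in range(np.asarray(arr).shape[1])],
        )
    )


def exhaustive_min_sse(X: np.ndarray) -> float:
    """Exhaustive-partition SSE optimum for k=2 (fixing row 0's side)."""
    n = X.shape[0]
    best = np.inf
    for mask in range(1, 2 ** (n - 1)):
        side = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        sse = 0.0
        for part in (X[side], X[~side]):
            if len(part) == 0:
                sse = np.inf
                break
            sse += ((part - part.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return float(best)


def _blobs(rng, n_per=20, sep=10.0, d=2, spread=1.0):
    a = rng.normal(scale=spread, size=(n_per, d))
    b = rng.normal(scale=spread, size=(n_per, d)) + sep
    X = np.vstack([a, b])
    labels = np.array([0] * n_per + [1] * n_per)
    return X, labels


class TestKMeans:
    def test_two_blobs_recovered_and_optimal(self):
        rng = np.random.default_rng(0)
        X, planted = _blobs(rng, n_per=4, sep=10.0)
        res = kmeans(_matrix(X), ClusteringConfig(k=2, seed=0, n_restarts=10))
        agree, ari = match_clusters(planted, res.assignments)
        assert agree == 1.0 and ari == 1.0
        assert res.within_sse == pytest.approx(exhaustive_min_sse(X))

    def test_n_equals_k_zero_sse(self):
        X = np.array([[0.0, 0], [5, 0], [0, 5], [5, 5]])
        res = kmeans(_matrix(X), ClusteringConfig(k=4, seed=1))
        assert res.within_sse == pytest.approx(0.0)
        assert len(set(res.assignments.tolist())) == 4

    def test_identical_points_k1(self):
        X = np.ones((5, 3))
        res = kmeans(_matrix(X), ClusteringConfig(k=1, seed=0, n_restarts=1))
        np.testing.assert_allclose(res.centroids, [[1, 1, 1]])
        assert res.within_sse == 0.0
        assert res.converged

    def test_sse_trace_non_increasing(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 4))
        res = kmeans(_matrix(X), ClusteringConfig(k=5, seed=3, n_restarts=1, init="random"))
        trace = np.array(res.sse_trace)
        assert (np.diff(trace) <= 1e-9).all()

    def test_k_exceeding_n_is_error(self):
        with pytest.raises(ValueError):
            kmeans(_matrix(np.zeros((3, 2))), ClusteringConfig(k=4))

    def test_non_finite_is_error(self):
        X = np.zeros((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            kmeans(_matrix(X), ClusteringConfig(k=2))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        r1 = kmeans(_matrix(X), ClusteringConfig(k=4, seed=11))
        r2 = kmeans(_matrix(X), ClusteringConfig(k=4, seed=11))
        assert (r1.assignments == r2.assignments).all()
        np.testing.assert_array_equal(r1.centroids, r2.centroids)

    def test_no_empty_clusters(self):
        # an outlier far away tempts centroids to collapse onto the bulk
        X = np.vstack([np.zeros((10, 2)), [[100.0, 100.0]]])
        res = kmeans(_matrix(X), ClusteringConfig(k=3, seed=2))
        assert (res.sizes() > 0).all()

    def test_matches_sklearn_objective(self):
        """Independent cross-check: our optimum is as good as scikit-learn's."""
        from sklearn.cluster import KMeans as SkKMeans

        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 5))
        ours = kmeans(_matrix(X), ClusteringConfig(k=4, seed=7, n_restarts=20))
        sk = SkKMeans(n_clusters=4, n_init=20, random_state=7).fit(X)
        assert ours.within_sse <= sk.inertia_ * 1.01


class TestInternalMetrics:
    def test_separated_blobs_high_silhouette(self):
        # silhouette ~ 1 - E[intra-pair distance]/separation: ~0.88 at a
        # 10-sigma gap (frozen from simulation), above 0.9 at 30 sigma
        rng = np.random.default_rng(0)
        X, planted = _blobs(rng, n_per=25, sep=10.0, spread=1.0)
        m = _matrix(X)
        res = kmeans(m, ClusteringConfig(k=2, seed=0))
        assert internal_metrics(m, res)["mean_silhouette"] > 0.85
        X2, _ = _blobs(rng, n_per=25, sep=30.0, spread=1.0)
        m2 = _matrix(X2)
        res2 = kmeans(m2, ClusteringConfig(k=2, seed=0))
        assert internal_metrics(m2, res2)["mean_silhouette"] > 0.9

    def test_random_assignment_scores_lower(self):
        rng = np.random.default_rng(1)
        X, planted = _blobs(rng, n_per=25, sep=10.0)
        good = silhouette(X, planted)
        bad = silhouette(X, rng.integers(0, 2, size=len(X)))
        assert bad < good

    def test_k1_silhouette_undefined(self):
        X = np.zeros((5, 2))
        assert np.isnan(silhouette(X, np.zeros(5, dtype=int)))

    def test_silhouette_agrees_with_sklearn(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3))
        labels = rng.integers(0, 3, size=30)
        assert silhouette(X, labels) == pytest.approx(
            silhouette_score(X, labels), abs=1e-10
        )


class TestProfile:
    def test_minmax_of_cluster_means(self):
        X = np.array([[2.0], [2.0], [4.0], [4.0], [6.0], [6.0]])
        m = _matrix(X)
        res = kmeans(m, ClusteringConfig(k=3, seed=0))
        prof = profile(m, res)
        assert sorted(prof.minmax_means["f0"].tolist()) == [0.0, 0.5, 1.0]
        assert sorted(prof.raw_means["f0"].tolist()) == [2.0, 4.0, 6.0]

    def test_single_cluster_constant_feature(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0]])
        m = _matrix(X)
        res = kmeans(m, ClusteringConfig(k=1, seed=0, n_restarts=1))
        prof = profile(m, res)
        assert (prof.minmax_means.to_numpy() == 0).all()
        assert set(prof.constant_features) == {"f0", "f1"}

    def test_preference_unit_sum(self):
        X = np.zeros((2, 8))
        X[0, 0] = 1.0
        X[1, 1] = 1.0
        m = _matrix(X)
        res = kmeans(m, ClusteringConfig(k=1, seed=0, n_restarts=1))
        prof = profile(m, res, preference=True)
        np.testing.assert_allclose(
            prof.unit_sums.to_numpy()[0, :2], [0.70710678, 0.70710678]
        )

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 3))
        m = _matrix(X)
        res = kmeans(m, ClusteringConfig(k=3, seed=4))
        prof = profile(m, res)
        # permute cluster indices and re-profile
        perm = np.array([2, 0, 1])
        res2 = type(res)(
            assignments=perm[res.assignments],
            centroids=res.centroids[np.argsort(perm)],
            iterations=res.iterations,
            within_sse=res.within_sse,
            converged=res.converged,
            users=res.users,
        )
        prof2 = profile(m, res2)
        for c in range(3):
            np.testing.assert_allclose(
                prof.raw_means.to_numpy()[c], prof2.raw_means.to_numpy()[perm[c]]
            )


class TestMatchClusters:
    def test_identical_partitions(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        agree, ari = match_clusters(labels, labels)
        assert agree == 1.0 and ari == 1.0

    def test_identical_up_to_relabeling(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        b = np.array([2, 2, 0, 0, 1, 1])
        agree, ari = match_clusters(a, b)
        assert agree == 1.0 and ari == 1.0

    def test_one_flip(self):
        a = np.array([0] * 5 + [1] * 5)
        b = a.copy()
        b[0] = 1
        agree, _ = match_clusters(a, b)
        assert agree == pytest.approx(9 / 10)

    def test_string_planted_labels(self):
        a = ["x", "x", "y", "y"]
        b = [1, 1, 0, 0]
        agree, ari = match_clusters(a, b)
        assert agree == 1.0 and ari == 1.0

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            match_clusters([0, 1], [0, 1, 2])

    def test_ari_near_zero_for_independent_partitions(self):
        rng = np.random.default_rng(0)
        aris = [
            adjusted_rand_index(
                rng.integers(0, 4, size=1000), rng.integers(0, 4, size=1000)
            )
            for _ in range(20)
        ]
        assert max(abs(a) for a in aris) < 0.05

    def test_ari_agrees_with_sklearn(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(9)
        for _ in range(5):
            a = rng.integers(0, 4, size=50)
            b = rng.integers(0, 3, size=50)
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )
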