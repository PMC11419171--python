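import numpy as np
import pytest

from endosubtypes.cluster import (MethodParams, affinity_matrix,
                                  baseline_cluster, distortion_score,
                                  evenness_score, model_sweep, select_model,
                                  silhouette_score, spectral_cluster)


def _two_blobs(rng, n=40, sep=10.0):
    a = rng.normal(0, 0.3, (n, 3))
    b = rng.normal(sep, 0.3, (n, 3))
    return np.vstack([a, b]), np.r_[np.zeros(n, int), np.ones(n, int)]


def _same_partition(a, b):
    """True iff two labelings induce the same partition."""
    a, b = np.asarray(a), np.asarray(b)
    pairs_a = {tuple(sorted(np.flatnonzero(a == lab))) for lab in np.unique(a)}
    pairs_b = {tuple(sorted(np.flatnonzero(b == lab))) for lab in np.unique(b)}
    return pairs_a == pairs_b


class TestAffinity:
    def test_block_diagonal_for_far_groups(self, rng):
        X = np.vstack([np.zeros((5, 2)), np.full((5, 2), 100.0)])
        A = affinity_matrix(X, affinity_neighbors=3)
        assert (A[:5, 5:] == 0).all()
        # duplicated rows form a complete subgraph
        assert (A[:5, :5] + np.eye(5) == 1).all()

    def test_permutation_equivariance(self, rng):
        X, _ = _two_blobs(rng, n=15)
        perm = rng.permutation(len(X))
        A = affinity_matrix(X, 4)
        Ap = affinity_matrix(X[perm], 4)
        assert np.array_equal(Ap, A[np.ix_(perm, perm)])

    def test_full_neighbors_complete_graph(self, rng):
        X = rng.normal(size=(12, 3))
        A = affinity_matrix(X, affinity_neighbors=11)
        assert (A + np.eye(12) == 1).all()

    def test_symmetric_nonnegative(self, rng):
        X, _ = _two_blobs(rng, n=10)
        A = affinity_matrix(X, 3)
        assert np.array_equal(A, A.T) and (A >= 0).all()
        assert np.diag(A).sum() == 0


class TestSpectral:
    def test_labels_equal_connected_components(self, rng):
        """Brute-force graph-component oracle: when the affinity graph has
        exactly K components, spectral labels recover them."""
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        sizes = [7, 5, 9]
        n = sum(sizes)
        A = np.zeros((n, n))
        start = 0
        for s in sizes:
            A[start:start + s, start:start + s] = 1.0
            start += s
        np.fill_diagonal(A, 0)
        perm = rng.permutation(n)
        A = A[np.ix_(perm, perm)]
        _, comp = connected_components(csr_matrix(A), directed=False)
        run, _ = spectral_cluster(np.eye(n), MethodParams(K=3), affinity=A)
        assert _same_partition(run.labels, comp)

    def test_duplicate_rows_co_assigned(self, rng):
        X, truth = _two_blobs(rng, n=20)
        X2 = np.repeat(X, 2, axis=0)
        run, _ = spectral_cluster(X2, MethodParams(K=2, affinity_neighbors=5))
        assert (run.labels[::2] == run.labels[1::2]).all()

    def test_k_exceeding_n_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            spectral_cluster(rng.normal(size=(4, 2)), MethodParams(K=9))

    def test_embedding_shape(self, rng):
        X, _ = _two_blobs(rng)
        run, emb = spectral_cluster(X, MethodParams(K=2, affinity_neighbors=6))
        assert emb.shape == (len(X), 2)
        assert run.n_clusters_found == 2


class TestBaselines:
    def test_kmeans_two_masses_brute_force(self, rng):
        """SSE of the K=2 k-means split equals the best over all 2-partitions."""
        from itertools import combinations

        X = np.r_[rng.normal(0, 0.2, (6, 1)), rng.normal(8, 0.2, (6, 1))]
        run = baseline_cluster(X, MethodParams(method="kmeans", K=2, seed=1))
        best = np.inf
        idx = range(len(X))
        for r in range(1, len(X) // 2 + 1):
            for left in combinations(idx, r):
                lab = np.isin(idx, left).astype(int)
                best = min(best, distortion_score(X, lab))
        assert run.distortion == pytest.approx(best)
        assert _same_partition(run.labels, np.r_[np.zeros(6), np.ones(6)])

    def test_hierarchical_singletons_zero_distortion(self, rng):
        X = rng.normal(size=(8, 2))
        run = baseline_cluster(X, MethodParams(method="hierarchical", K=8))
        assert run.n_clusters_found == 8
        assert run.distortion == 0.0

    def test_dbscan_single_mass_no_noise(self, rng):
        X = rng.normal(0, 0.05, (30, 2))
        run = baseline_cluster(X, MethodParams(method="dbscan", eps=1.0,
                                               min_samples=3))
        assert run.n_clusters_found == 1
        assert (run.labels == 0).all()

    def test_dbscan_all_noise_reported_not_raised(self, rng):
        X, _ = _two_blobs(rng, n=10)
        run = baseline_cluster(X, MethodParams(method="dbscan", eps=1e-6,
                                               min_samples=3))
        assert run.n_clusters_found == 0
        assert (run.labels == -1).all()


class TestMetrics:
    def test_silhouette_perfect_separation(self):
        X = np.r_[np.zeros((4, 2)), np.full((4, 2), 50.0)]
        labels = np.r_[np.zeros(4, int), np.ones(4, int)]
        assert silhouette_score(X, labels) == pytest.approx(1.0)

    def test_silhouette_matches_textbook_oracle(self, rng):
        """Independent implementation (scikit-learn) on random labelings."""
        from sklearn.metrics import silhouette_score as sk_sil

        X = rng.normal(size=(30, 4))
        for _ in range(5):
            labels = rng.integers(0, 3, 30)
            if len(np.unique(labels)) < 2:
                continue
            ours = silhouette_score(X, labels)
            ref = sk_sil(X, labels, metric="manhattan")
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_silhouette_random_labels_near_zero(self, rng):
        X = rng.random((200, 5))
        labels = rng.integers(0, 4, 200)
        assert abs(silhouette_score(X, labels)) < 0.05

    def test_silhouette_single_cluster_undefined(self):
        with pytest.raises(ValueError):
            silhouette_score(np.zeros((5, 2)), np.zeros(5, int))

    def test_distortion_hand_example(self):
        # one cluster {0, 1} in 1-D: centroid 0.5, SSE = 0.5
        assert distortion_score(np.array([[0.0], [1.0]]),
                                [0, 0]) == pytest.approx(0.5)
        assert distortion_score(np.array([[0.0], [1.0]]), [0, 1]) == 0.0

    def test_distortion_nonincreasing_in_k(self, rng):
        X = rng.normal(size=(60, 3))
        prev = np.inf
        for K in range(2, 9):
            run = baseline_cluster(X, MethodParams(method="kmeans", K=K,
                                                   seed=0, n_restarts=20))
            assert run.distortion <= prev + 1e-9
            prev = run.distortion

    def test_evenness_arithmetic(self):
        sizes = {0: 441, 1: 686, 2: 1151, 3: 796, 4: 1004}
        labels = np.concatenate([np.full(n, lab) for lab, n in sizes.items()])
        assert evenness_score(labels) == pytest.approx((1151 - 441) / 4078,
                                                       abs=1e-12)
        assert evenness_score([0, 0, 1, 1]) == 0.0
        assert evenness_score(np.zeros(10, int)) == 0.0  # single cluster

    def test_metrics_invariant_to_relabeling(self, rng):
        X, labels = _two_blobs(rng, n=25)
        flipped = 1 - labels
        assert silhouette_score(X, labels) == pytest.approx(
            silhouette_score(X, flipped))
        assert distortion_score(X, labels) == distortion_score(X, flipped)
        assert evenness_score(labels) == evenness_score(flipped)


class TestSweepAndSelection:
    def test_row_counting_and_determinism(self, rng):
        X, _ = _two_blobs(rng, n=20)
        sweep = model_sweep(X, methods=["kmeans"], K_range=[2, 3], seed=5)
        assert len(sweep) == 2
        again = model_sweep(X, methods=["kmeans"], K_range=[2, 3], seed=5)
        assert sweep.equals(again)

    def test_dbscan_contributes_single_row(self, rng):
        X, _ = _two_blobs(rng, n=15)
        sweep = model_sweep(X, methods=["dbscan"], K_range=range(2, 6))
        assert len(sweep) == 1

    def test_local_minimum_rule_by_construction(self):
        import pandas as pd

        sweep = pd.DataFrame({
            "method": ["m"] * 5, "K": [2, 3, 4, 5, 6],
            "n_clusters_found": [2, 3, 4, 5, 6],
            "silhouette": [0.1] * 5,
            "distortion": [10.0, 8.0, 9.0, 7.0, 7.5],  # minima at K=3, K=5
            "evenness": [0.1] * 5,
        })
        sel = select_model(sweep)
        assert (sel.method, sel.K) == ("m", 3)  # smallest local minimum
        assert sel.rule == "distortion_local_minimum"

    def test_excessive_cluster_count_excluded(self):
        import pandas as pd

        sweep = pd.DataFrame({
            "method": ["dbscan", "kmeans", "kmeans", "kmeans"],
            "K": [131, 2, 3, 4], "n_clusters_found": [131, 2, 3, 4],
            "silhouette": [0.9, 0.3, 0.5, 0.2],
            "distortion": [1.0, 9.0, 5.0, 6.0],
            "evenness": [0.0, 0.2, 0.2, 0.2],
        })
        sel = select_model(sweep, max_clusters=20)
        assert sel.method == "kmeans" and sel.K == 3
        assert any("excluded dbscan" in j for j in sel.justification)

    def test_no_survivor_raises(self):
        import pandas as pd

        sweep = pd.DataFrame({"method": ["dbscan"], "K": [131],
                              "n_clusters_found": [131], "silhouette": [0.9],
                              "distortion": [1.0], "evenness": [0.0]})
        with pytest.raises(ValueError, match="no method survives"):
            select_model(sweep, max_clusters=20)
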