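import itertools

import numpy as np
import pandas as pd
import pytest

from stemfactor.multivariate import (
    DistanceMatrix,
    cut_clusters,
    pca_svd,
    pearson_distance,
    rand_index,
    upgma_cluster,
)


def brute_force_upgma_heights(d):
    """Oracle: recompute every cross-pair average from the original matrix."""
    n = d.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            pairs = [(a, b) for a in clusters[i] for b in clusters[j]]
            avg = np.mean([d[a, b] for a, b in pairs])
            if best is None or avg < best[0]:
                best = (avg, i, j)
        h, i, j = best
        heights.append(h)
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return np.array(heights)


class TestPearsonDistance:
    def test_identical_rows_distance_zero(self):
        m = pd.DataFrame([[1.0, 2, 3], [1.0, 2, 3]], index=["a", "b"])
        d = pearson_distance(m)
        assert d.d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_antiproportional_rows_distance_two(self):
        x = np.array([1.0, 2.0, 3.0])
        y = -(x - x.mean()) + 10
        d = pearson_distance(pd.DataFrame([x, y], index=["a", "b"]))
        assert d.d[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_hand_computed_correlation(self):
        m = pd.DataFrame([[1.0, 2, 3], [1.0, 2, 4]], index=["a", "b"])
        d = pearson_distance(m)
        # r = 9/sqrt(84)
        assert d.d[0, 1] == pytest.approx(1 - 9 / np.sqrt(84), abs=1e-12)

    def test_constant_row_rejected_by_name(self):
        m = pd.DataFrame([[1.0, 1, 1], [1.0, 2, 3]], index=["flat", "b"])
        with pytest.raises(ValueError, match="flat"):
            pearson_distance(m)

    def test_affine_invariance_per_row(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 6)))
        scaled = m.mul(rng.uniform(0.5, 3, 5), axis=0).add(
            rng.normal(size=5), axis=0
        )
        d0 = pearson_distance(m)
        d1 = pearson_distance(scaled)
        assert np.allclose(d0.d, d1.d, atol=1e-10)


class TestUpgma:
    def test_two_samples_single_merge(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 0.3], [0.3, 0.0]]))
        dend = upgma_cluster(d)
        assert dend.merges.shape == (1, 4)
        assert dend.merges[0, 2] == pytest.approx(0.3)

    def test_three_sample_hand_case(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]]),
        )
        dend = upgma_cluster(d)
        assert dend.merges[0, 2] == pytest.approx(0.1)
        assert dend.merges[1, 2] == pytest.approx(0.5)
        assert set(dend.merges[0, :2]) == {0, 1}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        raw = rng.uniform(0.1, 2.0, (n, n))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0.0)
        dend = upgma_cluster(DistanceMatrix([f"s{i}" for i in range(n)], d))
        assert np.allclose(dend.merges[:, 2], brute_force_upgma_heights(d), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_average_linkage(self, seed):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(100 + seed)
        n = 8
        raw = rng.uniform(0.1, 2.0, (n, n))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0.0)
        dend = upgma_cluster(DistanceMatrix([f"s{i}" for i in range(n)], d))
        ref = linkage(squareform(d), method="average")
        assert np.allclose(np.sort(dend.merges[:, 2]), np.sort(ref[:, 2]), atol=1e-10)

    def test_permutation_equivariance(self, rng):
        n = 6
        raw = rng.uniform(0.1, 2.0, (n, n))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"s{i}" for i in range(n)]
        perm = rng.permutation(n)
        d_perm = d[np.ix_(perm, perm)]
        dend = upgma_cluster(DistanceMatrix(labels, d))
        dend_p = upgma_cluster(
            DistanceMatrix([labels[i] for i in perm], d_perm)
        )
        for k in range(2, n + 1):
            part = cut_clusters(dend, k)
            part_p = cut_clusters(dend_p, k)
            assert rand_index(
                [part[l] for l in labels], [part_p[l] for l in labels]
            ) == pytest.approx(1.0)

    def test_newick_is_well_formed(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]]),
        )
        nwk = upgma_cluster(d).to_newick()
        assert nwk.endswith(";")
        assert nwk.count("(") == 2
        for label in "ABC":
            assert label in nwk


class TestCutClusters:
    def setup_method(self):
        d = np.array(
            [
                [0, 0.1, 0.9, 0.95],
                [0.1, 0, 0.92, 0.9],
                [0.9, 0.92, 0, 0.15],
                [0.95, 0.9, 0.15, 0],
            ]
        )
        self.dend = upgma_cluster(
            DistanceMatrix(["a", "b", "c", "d"], d)
        )

    def test_k1_all_together(self):
        part = cut_clusters(self.dend, 1)
        assert len(set(part.values())) == 1

    def test_kn_singletons(self):
        part = cut_clusters(self.dend, 4)
        assert len(set(part.values())) == 4

    def test_k2_natural_split(self):
        part = cut_clusters(self.dend, 2)
        assert part["a"] == part["b"]
        assert part["c"] == part["d"]
        assert part["a"] != part["c"]

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            cut_clusters(self.dend, 0)
        with pytest.raises(ValueError):
            cut_clusters(self.dend, 5)


class TestPcaSvd:
    def test_rank_one_matrix_pc1_explains_everything(self):
        u = np.array([1.0, 2.0, 3.0])
        v = np.array([0.5, -1.0])
        m = pd.DataFrame(np.outer(u, v))
        res = pca_svd(m, center=False)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_explained_fractions_sum_to_one_and_decrease(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 5)))
        res = pca_svd(m)
        frac = res.explained_variance_ratio
        assert frac.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(frac) <= 1e-12)
        assert np.all(frac >= 0)

    def test_matches_covariance_eigendecomposition(self):
        m = pd.DataFrame([[1.0, 2.0], [3.0, 1.0], [5.0, 7.0]])
        res = pca_svd(m, center=True)
        cov = np.cov(m.to_numpy().T, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(
            res.explained_variance_ratio, eig / eig.sum(), atol=1e-10
        )

    def test_matches_sklearn_on_complete_matrix(self, rng):
        from sklearn.decomposition import PCA

        m = pd.DataFrame(rng.normal(size=(12, 5)))
        res = pca_svd(m)
        ref = PCA().fit(m.to_numpy())
        assert np.allclose(
            res.explained_variance_ratio, ref.explained_variance_ratio_, atol=1e-10
        )
        assert res.n_imputation_iterations == 0

    def test_loadings_orthonormal(self, rng):
        m = pd.DataFrame(rng.normal(size=(8, 4)))
        res = pca_svd(m)
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_imputation_recovers_low_rank_entry(self, rng):
        # rank-2 matrix with one missing cell: imputation should land close
        A = rng.normal(size=(10, 2))
        B = rng.normal(size=(2, 5))
        m = A @ B
        truth = m[3, 2]
        m_miss = m.copy()
        m_miss[3, 2] = np.nan
        res = pca_svd(pd.DataFrame(m_miss), rank=2)
        assert res.completed.iloc[3, 2] == pytest.approx(truth, abs=0.05)

    def test_all_missing_row_rejected(self):
        m = pd.DataFrame([[np.nan, np.nan], [1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            pca_svd(m)


class TestRandIndex:
    def test_identical_partitions(self):
        assert rand_index([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0

    def test_opposite_partition(self):
        # 4 samples split 2/2 vs all-singletons
        assert rand_index([0, 0, 1, 1], [0, 1, 2, 3]) == pytest.approx(4 / 6)
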