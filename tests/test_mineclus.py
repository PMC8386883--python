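import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from omsubtype.mineclus import (
    MineClusParams,
    _best_subset_exhaustive,
    _best_subset_mining,
    _bit_tuple,
    best_cluster_for_medoid,
    default_w_grid,
    kmeans_baseline,
    mineclus_cluster,
    mu_quality,
    select_params,
    truncate_clustering,
)
from omsubtype.synthetic import generate_projected_clusters


class TestQualityFunction:
    def test_direct_formula(self):
        assert mu_quality(100, 2, 0.25) == 1600
        assert mu_quality(7, 0, 0.3) == 7

    @pytest.mark.parametrize("beta", [0.1, 0.25, 0.5, 0.9])
    def test_monotone_in_support(self, beta):
        assert mu_quality(50, 3, beta) < mu_quality(100, 3, beta)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            mu_quality(-1, 2, 0.25)


class TestBestClusterForMedoid:
    def test_recovers_planted_dimension_set(self):
        X, labels, _ = generate_projected_clusters(
            100, 8, [(60, (1, 3), 50.0, 0.2)], noise_n=40, seed=1
        )
        medoid = int(np.flatnonzero(labels == 0)[0])
        members, dims, quality = best_cluster_for_medoid(
            X, medoid, MineClusParams(w=1.0)
        )
        assert dims == (1, 3)
        assert set(np.flatnonzero(labels == 0)) <= set(members)

    def test_identical_points_take_all_dimensions(self):
        X = np.ones((20, 5))
        members, dims, quality = best_cluster_for_medoid(
            X, 0, MineClusParams(w=0.5)
        )
        assert dims == (0, 1, 2, 3, 4)
        assert len(members) == 20
        assert quality == mu_quality(20, 5, 0.25)

    def test_isolated_medoid_fails_support(self):
        X = np.arange(20, dtype=float)[:, None] * 100
        assert best_cluster_for_medoid(X, 0, MineClusParams(w=1.0)) is None

    def test_exhaustive_equals_mining(self, rng):
        """Exact search over the subset lattice and the branch-and-bound
        itemset miner agree on quality, support and dimension set."""
        for _ in range(15):
            n = int(rng.integers(20, 100))
            m = int(rng.integers(2, 13))
            pts = rng.uniform(0, 10, size=(n, m))
            close = np.abs(pts - pts[int(rng.integers(0, n))]) <= rng.uniform(0.5, 4)
            min_support = float(rng.uniform(0.05, 0.3)) * n
            beta = float(rng.choice([0.15, 0.25, 0.4]))
            a = _best_subset_exhaustive(close, min_support, beta)
            b = _best_subset_mining(close, min_support, beta)
            assert (a is None) == (b is None)
            if a is not None:
                assert a[0] == pytest.approx(b[0])
                assert _bit_tuple(a[1]) == _bit_tuple(b[1])


class TestMineClusCluster:
    def fixture(self, seed):
        spec = [(300, (0, 2), 20.0, 2.0), (150, (1, 4, 6), 70.0, 2.0)]
        return generate_projected_clusters(500, 8, spec, noise_n=50, seed=seed)

    def test_recovers_planted_clusters_and_dims(self):
        X, truth, dims = self.fixture(seed=4)
        clustering = mineclus_cluster(X, MineClusParams(w=5.0, k_max=2, seed=0))
        assert adjusted_rand_score(truth, clustering.labels) >= 0.9
        assert sorted(c.dims for c in clustering.clusters) == sorted(
            [(0, 2), (1, 4, 6)]
        )

    def test_width_containment_invariant(self):
        X, _, _ = self.fixture(seed=5)
        for w in (3.0, 5.0, 10.0):
            clustering = mineclus_cluster(X, MineClusParams(w=w, k_max=4, seed=0))
            for c in clustering.clusters:
                gap = np.abs(X[np.ix_(c.members, list(c.dims))]
                             - c.medoid[list(c.dims)])
                assert gap.max() <= w + 1e-12

    def test_quality_non_increasing_over_iterations(self):
        X, _, _ = self.fixture(seed=6)
        clustering = mineclus_cluster(X, MineClusParams(w=5.0, k_max=6, seed=0))
        qualities = [c.quality for c in clustering.clusters]
        assert all(a >= b for a, b in zip(qualities, qualities[1:]))

    def test_k_max_one_leaves_remainder_as_outliers(self):
        X, truth, _ = self.fixture(seed=7)
        clustering = mineclus_cluster(X, MineClusParams(w=5.0, k_max=1, seed=0))
        assert clustering.n_clusters == 1
        assert clustering.n_outliers == 500 - len(clustering.clusters[0].members)

    def test_deterministic(self):
        X, _, _ = self.fixture(seed=8)
        a = mineclus_cluster(X, MineClusParams(w=5.0, k_max=3, seed=1))
        b = mineclus_cluster(X, MineClusParams(w=5.0, k_max=3, seed=1))
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_truncation_matches_smaller_k_max(self):
        X, _, _ = self.fixture(seed=9)
        full = mineclus_cluster(X, MineClusParams(w=5.0, k_max=4, seed=2))
        direct = mineclus_cluster(X, MineClusParams(w=5.0, k_max=2, seed=2))
        np.testing.assert_array_equal(
            truncate_clustering(full, 2).labels, direct.labels
        )


class TestKMeansBaseline:
    def test_separable_blobs_fully_recovered(self, rng):
        X = np.vstack([rng.standard_normal((80, 3)),
                       rng.standard_normal((40, 3)) + 20])
        truth = np.r_[np.zeros(80), np.ones(40)]
        clustering = kmeans_baseline(X, 2, seed=0)
        assert adjusted_rand_score(truth, clustering.labels) == 1.0
        assert clustering.n_outliers == 0
        assert all(c.dims == (0, 1, 2) for c in clustering.clusters)
        assert clustering.sizes() == [80, 40]  # ordered by size

    def test_k_one(self, rng):
        X = rng.standard_normal((30, 2))
        clustering = kmeans_baseline(X, 1, seed=0)
        assert clustering.sizes() == [30]

    def test_duplicate_points(self):
        X = np.ones((10, 2))
        clustering = kmeans_baseline(X, 2, seed=0)
        assert clustering.n_clusters == 2
        assert sum(clustering.sizes()) == 10  # zero inertia, one box empty

    def test_k_exceeding_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_baseline(rng.standard_normal((5, 2)), 6, seed=0)


class TestSelectParams:
    def test_recovers_85_15_split(self):
        dims = tuple(range(8))
        spec = [(425, dims, 30.0, 10.0), (75, dims, 75.0, 8.0)]
        X, truth, _ = generate_projected_clusters(500, 8, spec, 0, seed=10)
        result = select_params(X, k_range=range(2, 6), seed=0)
        assert not result.k1_verdict
        assert result.chosen.n_clusters == 2
        mask = result.chosen.labels >= 0
        assert adjusted_rand_score(truth[mask], result.chosen.labels[mask]) >= 0.9

    def test_table_covers_full_grid(self, rng):
        X = rng.standard_normal((80, 4))
        grid = [0.5, 1.0, 2.0]
        result = select_params(X, w_grid=grid, k_range=range(2, 5), seed=0)
        assert len(result.table) == len(grid) * 3
        assert result.table["chosen"].sum() <= 1

    def test_degenerate_identical_points_yield_k1_verdict(self):
        X = np.ones((40, 3))
        result = select_params(X, w_grid=[0.5], k_range=range(2, 4), seed=0)
        assert result.k1_verdict and result.chosen is None

    def test_outlier_heavy_candidates_excluded_when_alternatives_exist(self):
        dims = tuple(range(8))
        spec = [(425, dims, 30.0, 10.0), (75, dims, 75.0, 8.0)]
        X, truth, _ = generate_projected_clusters(500, 8, spec, 0, seed=12)
        result = select_params(X, k_range=range(2, 6), seed=0)
        chosen = result.chosen
        assert chosen.n_outliers <= 0.10 * len(X)


def test_default_w_grid_positive_and_sorted(rng):
    X = rng.standard_normal((100, 5))
    grid = default_w_grid(X, seed=0)
    assert all(w > 0 for w in grid)
    assert grid == sorted(grid)
    assert len(grid) == 11  # deciles + 95% + 99%
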