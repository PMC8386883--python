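import numpy as np
import pytest
from scipy.spatial.distance import cdist

from omsubtype.cluster_eval import (
    connectedness,
    gap_statistic,
    normalized_jaccard,
    silhouette,
    stability_resampling,
    within_dispersion,
)
from omsubtype.mineclus import kmeans_baseline


def brute_silhouette(points, labels):
    """Independent O(n^2) silhouette straight from the definition."""
    dist = cdist(points, points)
    uniq = sorted(set(labels))
    s = []
    for i in range(len(points)):
        same = [j for j in range(len(points)) if labels[j] == labels[i] and j != i]
        if not same:
            s.append(0.0)
            continue
        a = np.mean([dist[i, j] for j in same])
        b = min(
            np.mean([dist[i, j] for j in range(len(points)) if labels[j] == c])
            for c in uniq if c != labels[i]
        )
        s.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return np.asarray(s)


def brute_connectedness(points, labels, L):
    dist = cdist(points, points)
    n = len(points)
    raw = 0.0
    for i in range(n):
        order = sorted(range(n), key=lambda j: (dist[i, j], j))
        order = [j for j in order if j != i][:L]
        for rank, j in enumerate(order, start=1):
            if labels[j] != labels[i]:
                raw += 1.0 / rank
    h = sum(1.0 / r for r in range(1, L + 1))
    return 1.0 - raw / (n * h)


class TestSilhouette:
    def test_two_pairs_hand_computation(self):
        # a=1 within each pair, b = mean distance to the far pair; the exact
        # brute-force value for this geometry is 0.9293 (approximately the
        # back-of-envelope (10-1)/10 = 0.9)
        pts = np.array([[0, 0], [0, 1], [10, 10], [10, 11]], dtype=float)
        report = silhouette(pts, [0, 0, 1, 1])
        assert report.overall == pytest.approx(
            brute_silhouette(pts, np.array([0, 0, 1, 1])).mean(), abs=1e-12
        )
        assert report.overall == pytest.approx(0.93, abs=0.01)

    def test_identical_points_score_zero(self):
        pts = np.zeros((6, 2))
        report = silhouette(pts, [0, 0, 0, 1, 1, 1])
        assert report.overall == 0.0

    def test_single_cluster_is_undefined(self, rng):
        with pytest.raises(ValueError, match="undefined"):
            silhouette(rng.standard_normal((10, 2)), [0] * 10)

    def test_singleton_cluster_contributes_zero(self, rng):
        pts = np.vstack([rng.standard_normal((5, 2)), [[50.0, 50.0]]])
        report = silhouette(pts, [0, 0, 0, 0, 0, 1])
        assert report.per_cluster[1] == 0.0

    def test_outliers_excluded(self, rng):
        pts = np.vstack([rng.standard_normal((10, 2)),
                         rng.standard_normal((10, 2)) + 8])
        labels = np.r_[np.zeros(10), np.ones(10)].astype(int)
        with_out = np.r_[labels, [-1]]
        pts_out = np.vstack([pts, [[1000.0, 1000.0]]])
        a = silhouette(pts, labels)
        b = silhouette(pts_out, with_out)
        assert a.overall == pytest.approx(b.overall)
        assert b.n_outliers == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 80))
        pts = rng.standard_normal((n, 3))
        labels = rng.integers(0, 3, n)
        if len(set(labels)) < 2:
            labels[0] = (labels[0] + 1) % 3
        report = silhouette(pts, labels)
        ref = brute_silhouette(pts, labels)
        assert report.overall == pytest.approx(ref.mean(), abs=1e-12)
        for c, value in report.per_cluster.items():
            assert value == pytest.approx(ref[labels == c].mean(), abs=1e-12)


class TestConnectedness:
    def test_separated_blobs_are_perfectly_connected(self, rng):
        pts = np.vstack([rng.standard_normal((30, 2)),
                         rng.standard_normal((30, 2)) + 100])
        labels = np.r_[np.zeros(30), np.ones(30)].astype(int)
        assert connectedness(pts, labels, L=10) == 1.0

    def test_random_labels_score_about_half(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((600, 2))
        labels = np.r_[np.zeros(300), np.ones(300)].astype(int)
        rng.shuffle(labels)
        assert connectedness(pts, labels, L=10) == pytest.approx(0.5, abs=0.05)

    def test_single_cluster_scores_one(self, rng):
        assert connectedness(rng.standard_normal((20, 2)), [0] * 20) == 1.0

    def test_neighbor_count_must_be_small(self, rng):
        with pytest.raises(ValueError):
            connectedness(rng.standard_normal((5, 2)), [0, 0, 1, 1, 1], L=5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(25, 70))
        pts = rng.standard_normal((n, 3))
        labels = rng.integers(0, 3, n)
        if len(set(labels)) < 2:
            labels[0] = (labels[0] + 1) % 3
        L = int(rng.integers(3, 12))
        assert connectedness(pts, labels, L=L) == pytest.approx(
            brute_connectedness(pts, labels, L), abs=1e-12
        )


class TestNormalizedJaccard:
    def test_identity(self):
        assert normalized_jaccard({1, 2, 3}, {1, 2, 3}) == 1.0

    def test_containment_attains_maximum(self):
        assert normalized_jaccard({1, 2}, {1, 2, 3, 4}) == 1.0

    def test_disjoint(self):
        assert normalized_jaccard({1, 2}, {3, 4}) == 0.0

    def test_symmetric_and_equal_to_plain_jaccard_for_equal_sizes(self, rng):
        for _ in range(20):
            a = set(rng.choice(50, size=10, replace=False).tolist())
            b = set(rng.choice(50, size=10, replace=False).tolist())
            ab, ba = normalized_jaccard(a, b), normalized_jaccard(b, a)
            assert ab == pytest.approx(ba)
            assert ab == pytest.approx(len(a & b) / len(a | b))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            normalized_jaccard(set(), {1})


class TestGapStatistic:
    def test_dispersion_non_increasing_in_k(self, rng):
        pts = rng.standard_normal((150, 4))
        _, curve = gap_statistic(pts, k_range=range(1, 6), B=10, seed=0)
        assert (np.diff(curve["log_w"]) <= 1e-9).all()

    def test_single_blob_prefers_one_cluster(self):
        hits = 0
        for seed in range(5):
            pts = np.random.default_rng(seed).standard_normal((200, 4))
            k, _ = gap_statistic(pts, k_range=range(1, 5), B=10, seed=seed)
            hits += k == 1
        assert hits >= 4

    def test_three_blobs_found(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pts = np.vstack([rng.standard_normal((60, 3)) + c
                             for c in (0, 15, 30)])
            k, _ = gap_statistic(pts, k_range=range(1, 6), B=10, seed=seed)
            hits += k == 3
        assert hits >= 4

    def test_reference_count_floor(self, rng):
        with pytest.raises(ValueError):
            gap_statistic(rng.standard_normal((40, 2)), B=5)

    def test_within_dispersion_definition(self):
        pts = np.array([[0.0], [2.0], [10.0]])
        assert within_dispersion(pts, [0, 0, 1]) == pytest.approx(2.0)


class TestStability:
    @staticmethod
    def two_blob_fn(points, seed):
        return kmeans_baseline(points, 2, seed=seed).labels

    def test_identity_resample_is_perfectly_stable(self, rng):
        pts = np.vstack([rng.standard_normal((30, 2)),
                         rng.standard_normal((30, 2)) + 50])
        result = stability_resampling(pts, self.two_blob_fn, R=1,
                                      fraction=1.0, seed=0)
        assert (result == 1.0).all()

    def test_separated_blobs_are_stable(self, rng):
        pts = np.vstack([rng.standard_normal((60, 2)),
                         rng.standard_normal((30, 2)) + 50])
        result = stability_resampling(pts, self.two_blob_fn, R=20,
                                      fraction=0.8, seed=0)
        assert (result >= 0.9).all()

    def test_forced_split_of_noise_less_stable_than_real_clusters(self):
        rng = np.random.default_rng(3)
        noise = rng.standard_normal((200, 8))
        blobs = np.vstack([rng.standard_normal((140, 8)),
                           rng.standard_normal((60, 8)) + 10])
        noise_stab = stability_resampling(noise, self.two_blob_fn, R=30,
                                          fraction=0.8, seed=0).mean()
        blob_stab = stability_resampling(blobs, self.two_blob_fn, R=30,
                                         fraction=0.8, seed=0).mean()
        assert noise_stab < 0.9 < blob_stab
        assert noise_stab < blob_stab - 0.1
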