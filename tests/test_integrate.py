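import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from omsubtype.datatypes import Clustering, ProjectedCluster
from omsubtype.dimred import Embedding
from omsubtype.integrate import (
    concat_embeddings,
    contrast_group_associations,
    post_cluster_combine,
    pre_cluster_integrate,
)

from conftest import make_clinical


def embedding(subjects, coords, method="pca"):
    coords = np.asarray(coords, dtype=float)
    return Embedding(method, list(subjects), coords.shape[1], coords)


def binary_clustering(subjects, labels):
    labels = np.asarray(labels, dtype=int)
    clusters = [
        ProjectedCluster(members=np.flatnonzero(labels == c), dims=(0,),
                         medoid=np.zeros(1), quality=float("nan"))
        for c in sorted(set(labels[labels >= 0]))
    ]
    return Clustering(labels=labels, clusters=clusters,
                      subject_ids=list(subjects))


class TestConcatEmbeddings:
    def test_two_omics_at_eight_dims_make_sixteen(self, rng):
        subs = [f"S{i}" for i in range(40)]
        embs = [embedding(subs, rng.standard_normal((40, 8))) for _ in range(2)]
        joined = concat_embeddings(embs)
        assert joined.m == 16
        assert joined.coordinates.shape == (40, 16)

    def test_three_omics_make_twentyfour(self, rng):
        subs = [f"S{i}" for i in range(30)]
        embs = [embedding(subs, rng.standard_normal((30, 8))) for _ in range(3)]
        assert concat_embeddings(embs).m == 24

    def test_unequal_widths_rejected(self, rng):
        subs = [f"S{i}" for i in range(30)]
        embs = [embedding(subs, rng.standard_normal((30, 8))),
                embedding(subs, rng.standard_normal((30, 4)))]
        with pytest.raises(ValueError, match="equal-length"):
            concat_embeddings(embs)

    def test_empty_intersection_rejected(self, rng):
        a = embedding([f"A{i}" for i in range(10)], rng.standard_normal((10, 2)))
        b = embedding([f"B{i}" for i in range(10)], rng.standard_normal((10, 2)))
        with pytest.raises(ValueError, match="shared"):
            concat_embeddings([a, b])

    def test_blocks_standardized_over_shared_subjects(self, rng):
        subs = [f"S{i}" for i in range(50)]
        embs = [embedding(subs, 100 * rng.standard_normal((50, 3))),
                embedding(subs, 0.01 * rng.standard_normal((50, 3)))]
        joined = concat_embeddings(embs)
        np.testing.assert_allclose(joined.coordinates.std(axis=0, ddof=1),
                                   1.0, atol=1e-10)

    def test_intersection_respects_first_embedding_order(self, rng):
        a = embedding(["S3", "S1", "S2"], rng.standard_normal((3, 2)))
        b = embedding(["S1", "S2", "S3", "S4"], rng.standard_normal((4, 2)))
        joined = concat_embeddings([a, b])
        assert joined.subject_ids == ["S3", "S1", "S2"]


class TestPreClusterIntegrate:
    def shared_signal_embeddings(self, seed):
        """Three blocks, each carrying the same 12% subtype on 2 of 4 dims."""
        rng = np.random.default_rng(seed)
        n = 400
        subs = [f"S{i}" for i in range(n)]
        y = np.zeros(n, dtype=int)
        y[rng.permutation(n)[:48]] = 1
        embs = []
        for _ in range(3):
            coords = rng.uniform(-1.7, 1.7, size=(n, 4))
            coords[:, :2] += 8.0 * y[:, None]
            coords += 0.1 * rng.standard_normal((n, 4))
            embs.append(embedding(subs, coords, method="autoencoder"))
        return embs, y

    def test_shared_signal_recovered(self):
        embs, y = self.shared_signal_embeddings(seed=0)
        result, joined = pre_cluster_integrate(embs, k_range=range(2, 5), seed=1)
        assert joined.m == 12
        assert not result.k1_verdict
        mask = result.chosen.labels >= 0
        assert adjusted_rand_score(y[mask], result.chosen.labels[mask]) >= 0.8

    def test_signal_in_one_layer_diluted(self):
        """Early integration underperforms the signal layer alone when the
        other layers carry only noise."""
        rng = np.random.default_rng(2)
        n = 400
        subs = [f"S{i}" for i in range(n)]
        y = np.zeros(n, dtype=int)
        y[rng.permutation(n)[:48]] = 1
        signal = rng.uniform(-1.7, 1.7, size=(n, 4))
        signal[:, :2] += 8.0 * y[:, None]
        embs = [embedding(subs, signal)] + [
            embedding(subs, rng.uniform(-1.7, 1.7, size=(n, 4)))
            for _ in range(2)
        ]

        def ari_of(result):
            if result.k1_verdict:
                return 0.0
            mask = result.chosen.labels >= 0
            return adjusted_rand_score(y[mask], result.chosen.labels[mask])

        single, _ = pre_cluster_integrate(embs[:1], k_range=range(2, 4), seed=3)
        combined, _ = pre_cluster_integrate(embs, k_range=range(2, 4), seed=3)
        assert ari_of(combined) < ari_of(single)

    def test_single_embedding_is_identity_path(self, rng):
        embs, y = self.shared_signal_embeddings(seed=4)
        result, joined = pre_cluster_integrate(embs[:1], k_range=range(2, 4),
                                               seed=5)
        assert joined is embs[0]


class TestPostClusterCombine:
    def three_way(self):
        subs = [f"S{i}" for i in range(8)]
        # subject i gets the binary expansion of i as its (L=0/S=1) pattern
        labels = [[(i >> b) & 1 for i in range(8)] for b in (2, 1, 0)]
        return [binary_clustering(subs, lab) for lab in labels]

    def test_all_patterns_give_eight_subtypes(self):
        # make cluster 0 the majority in every omic so 0 codes L
        subs = [f"S{i}" for i in range(16)]
        labels = []
        for b in (2, 1, 0):
            lab = [(i >> b) & 1 if i < 8 else 0 for i in range(16)]
            labels.append(binary_clustering(subs, lab))
        result = post_cluster_combine(labels, ["t", "p", "m"])
        assert result.combination.nunique() == 8

    def test_membership_pattern(self):
        subs = [f"S{i}" for i in range(10)]
        t = binary_clustering(subs, [0] * 9 + [1])
        p = binary_clustering(subs, [0] * 9 + [1])
        m = binary_clustering(subs, [0, 1, 0, 0, 0, 0, 0, 0, 0, 1])
        result = post_cluster_combine([t, p, m], ["t", "p", "m"])
        assert result.combination["S1"] == "L-L-S"
        assert "S1" in result.contrast_groups["small_m_only"]
        assert "S0" in result.contrast_groups["all_large"]

    def test_two_clusterings_bounded_by_four(self):
        subs = [f"S{i}" for i in range(12)]
        a = binary_clustering(subs, [0] * 8 + [1] * 4)
        b = binary_clustering(subs, [0, 1] * 6)
        result = post_cluster_combine([a, b], ["a", "b"])
        assert result.combination.nunique() <= 4
        small_groups = [k for k in result.contrast_groups if k != "all_large"]
        assert len(small_groups) == 2

    def test_outlier_in_any_omic_excluded(self):
        subs = [f"S{i}" for i in range(10)]
        a = binary_clustering(subs, [0] * 5 + [1] * 4 + [-1])
        b = binary_clustering(subs, [0] * 9 + [1])
        result = post_cluster_combine([a, b], ["a", "b"])
        assert result.n_excluded_outliers == 1
        assert "S9" not in result.subject_ids

    def test_combination_refines_inputs(self, rng):
        subs = [f"S{i}" for i in range(60)]
        a = binary_clustering(subs, rng.integers(0, 2, 60))
        b = binary_clustering(subs, rng.integers(0, 2, 60))
        result = post_cluster_combine([a, b], ["a", "b"])
        assert result.combination.nunique() <= 4
        joined = pd.Series(result.combination)
        for clustering, name in ((a, "a"), (b, "b")):
            lab = pd.Series(clustering.labels, index=subs)[joined.index]
            # within one combination subtype, the per-omic label is constant
            assert (joined.groupby(joined).apply(
                lambda g, lab=lab: lab[g.index].nunique()) == 1).all()

    def test_non_binary_clustering_rejected(self):
        subs = [f"S{i}" for i in range(9)]
        tri = binary_clustering(subs, [0, 0, 0, 1, 1, 1, 2, 2, 2])
        bi = binary_clustering(subs, [0] * 6 + [1] * 3)
        with pytest.raises(ValueError, match="exactly 2"):
            post_cluster_combine([tri, bi], ["x", "y"])


class TestContrastGroupAssociations:
    def setup_result(self, rng, n=240):
        subs = [f"S{i}" for i in range(n)]
        # omic 3 smalls: 30 subjects; omics 1-2 smalls: other 30 each
        lab1 = np.zeros(n, dtype=int); lab1[:30] = 1
        lab2 = np.zeros(n, dtype=int); lab2[30:60] = 1
        lab3 = np.zeros(n, dtype=int); lab3[60:90] = 1
        clusterings = [binary_clustering(subs, lab)
                       for lab in (lab1, lab2, lab3)]
        return subs, post_cluster_combine(clusterings, ["t", "p", "m"])

    def test_planted_variable_detected(self, rng):
        subs, result = self.setup_result(rng)
        marker = rng.standard_normal(len(subs))
        in_m = np.isin(subs, result.contrast_groups["small_m_only"])
        marker[in_m] += 4.0
        clinical = make_clinical(
            subs,
            marker=("continuous", {"test"}, marker),
            noise=("continuous", {"test"}, rng.standard_normal(len(subs))),
        )
        table = contrast_group_associations(result, clinical)
        small_rows = table[table["contrast"] == "small_in_exactly_one"]
        assert small_rows.iloc[0]["variable"] == "marker"
        assert small_rows.iloc[0]["p_adj"] < 0.05

    @pytest.mark.parametrize("seed", range(3))
    def test_null_variables_controlled(self, seed):
        rng = np.random.default_rng(seed)
        subs, result = self.setup_result(rng)
        cols = {
            f"v{j}": ("continuous", {"test"}, rng.standard_normal(len(subs)))
            for j in range(30)
        }
        clinical = make_clinical(subs, **cols)
        table = contrast_group_associations(result, clinical)
        assert table["significant"].sum() <= 2

    def test_small_group_sizes_accepted(self, rng):
        subs = [f"S{i}" for i in range(120)]
        lab1 = np.zeros(120, dtype=int); lab1[:18] = 1
        lab2 = np.zeros(120, dtype=int); lab2[18:27] = 1
        lab3 = np.zeros(120, dtype=int); lab3[27:44] = 1
        result = post_cluster_combine(
            [binary_clustering(subs, lab) for lab in (lab1, lab2, lab3)],
            ["t", "p", "m"],
        )
        sizes = {k: len(v) for k, v in result.contrast_groups.items()
                 if k != "all_large"}
        assert sorted(sizes.values()) == [9, 17, 18]
        clinical = make_clinical(
            subs, v=("continuous", {"test"}, rng.standard_normal(120))
        )
        table = contrast_group_associations(result, clinical)
        assert not table.empty
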