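import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode
from skbio.diversity import beta_diversity

from conftest import random_tree
from nemacore.data_model import FeatureTable, ValidationError, relative_abundance
from nemacore.diversity import (alpha_diversity, biplot_loadings, faith_pd,
                                pcoa, unifrac)


def brute_force_unifrac(tree, table, mode, normalized=False):
    """Independent oracle: iterate every branch, tally tip presence/mass."""
    rel = table.data.div(table.data.sum(axis=1), axis=0)
    branches = []  # (length, tip name set)
    for node in tree.postorder(include_self=False):
        tips = {t.name for t in node.tips()} or {node.name}
        branches.append((node.length or 0.0, tips))
    S = table.sample_ids
    out = np.zeros((len(S), len(S)))
    for i, si in enumerate(S):
        for j, sj in enumerate(S):
            if j <= i:
                continue
            num = den = 0.0
            for length, tips in branches:
                cols = [c for c in table.feature_ids if c in tips]
                if mode == "unweighted":
                    a = any(table.data.loc[si, c] > 0 for c in cols)
                    b = any(table.data.loc[sj, c] > 0 for c in cols)
                    if a != b:
                        num += length
                    if a or b:
                        den += length
                else:
                    pa = sum(rel.loc[si, c] for c in cols)
                    pb = sum(rel.loc[sj, c] for c in cols)
                    num += length * abs(pa - pb)
                    den += length * (pa + pb)
            if mode == "unweighted" or normalized:
                d = num / den if den > 0 else 0.0
            else:
                d = num
            out[i, j] = out[j, i] = d
    return out


def random_table(rng, sample_ids, feature_ids, sparsity=0.4):
    while True:
        counts = rng.integers(0, 30, size=(len(sample_ids), len(feature_ids)))
        counts[rng.random(counts.shape) < sparsity] = 0
        if (counts.sum(axis=1) > 0).all():
            return FeatureTable(pd.DataFrame(counts, index=sample_ids,
                                             columns=feature_ids))


class TestAlpha:
    def test_uniform_eight_asvs_closed_form(self):
        t = FeatureTable(pd.DataFrame([[10] * 8], index=["s"],
                                      columns=[f"a{i}" for i in range(8)]))
        a = alpha_diversity(t)
        assert a.loc["s", "observed"] == 8
        assert a.loc["s", "shannon"] == pytest.approx(3.0)
        assert a.loc["s", "pielou"] == pytest.approx(1.0)

    def test_single_asv_entropy_zero_evenness_undefined(self):
        t = FeatureTable(pd.DataFrame([[7, 0]], index=["s"], columns=["a", "b"]))
        a = alpha_diversity(t)
        assert a.loc["s", "shannon"] == 0.0
        assert np.isnan(a.loc["s", "pielou"])

    def test_faith_pd_spans_whole_tree_when_all_leaves_observed(self, cherry_tree):
        t = FeatureTable(pd.DataFrame([[1, 1, 1, 1]], index=["s"],
                                      columns=["a1", "a2", "a3", "a4"]))
        total = sum(n.length or 0.0 for n in cherry_tree.traverse())
        assert faith_pd(t, cherry_tree)["s"] == pytest.approx(total)

    def test_faith_pd_monotone_under_added_feature(self, cherry_tree):
        t1 = FeatureTable(pd.DataFrame([[1, 0, 1, 0]], index=["s"],
                                       columns=["a1", "a2", "a3", "a4"]))
        t2 = FeatureTable(pd.DataFrame([[1, 1, 1, 0]], index=["s"],
                                       columns=["a1", "a2", "a3", "a4"]))
        assert faith_pd(t2, cherry_tree)["s"] >= faith_pd(t1, cherry_tree)["s"]

    def test_missing_leaf_raises(self, cherry_tree):
        t = FeatureTable(pd.DataFrame([[1, 1]], index=["s"],
                                      columns=["a1", "zz"]))
        with pytest.raises(ValidationError, match="zz"):
            faith_pd(t, cherry_tree)


class TestUniFrac:
    def test_identical_communities_distance_zero(self, cherry_tree):
        t = FeatureTable(pd.DataFrame([[3, 1, 2, 5], [3, 1, 2, 5]],
                                      index=["x", "y"],
                                      columns=["a1", "a2", "a3", "a4"]))
        for mode in ("unweighted", "weighted"):
            assert unifrac(t, cherry_tree, mode)["x", "y"] == pytest.approx(0.0)

    def test_disjoint_cherries_unweighted_is_one(self, cherry_tree):
        t = FeatureTable(pd.DataFrame([[2, 3, 0, 0], [0, 0, 4, 1]],
                                      index=["x", "y"],
                                      columns=["a1", "a2", "a3", "a4"]))
        assert unifrac(t, cherry_tree, "unweighted")["x", "y"] == pytest.approx(1.0)

    @pytest.mark.parametrize("mode,normalized", [("unweighted", False),
                                                 ("weighted", False),
                                                 ("weighted", True)])
    def test_matches_branch_enumeration_oracle(self, mode, normalized):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n_leaves = int(rng.integers(4, 13))
            tree = random_tree(rng, n_leaves)
            leaves = [t.name for t in tree.tips()]
            table = random_table(rng, [f"s{i}" for i in range(6)], leaves)
            ours = unifrac(table, tree, mode, normalized=normalized)
            oracle = brute_force_unifrac(tree, table, mode, normalized)
            assert np.abs(np.asarray(ours.data) - oracle).max() < 1e-12

    def test_unweighted_invariant_to_abundance_rescaling(self, cherry_tree):
        t1 = FeatureTable(pd.DataFrame([[1, 0, 2, 0], [0, 3, 0, 1]],
                                       index=["x", "y"],
                                       columns=["a1", "a2", "a3", "a4"]))
        t2 = FeatureTable((t1.data * 17))
        d1 = unifrac(t1, cherry_tree, "unweighted")
        d2 = unifrac(t2, cherry_tree, "unweighted")
        assert np.allclose(d1.data, d2.data)

    def test_weighted_normalized_bounded_by_one(self):
        rng = np.random.default_rng(3)
        tree = random_tree(rng, 10)
        table = random_table(rng, [f"s{i}" for i in range(5)],
                             [t.name for t in tree.tips()])
        d = np.asarray(unifrac(table, tree, "weighted", normalized=True).data)
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()

    def test_agrees_with_skbio_reference(self):
        rng = np.random.default_rng(12)
        tree = random_tree(rng, 9)
        leaves = [t.name for t in tree.tips()]
        table = random_table(rng, [f"s{i}" for i in range(5)], leaves)
        ours = unifrac(table, tree, "unweighted")
        ref = beta_diversity("unweighted_unifrac", table.data.to_numpy(),
                             ids=table.sample_ids, taxa=leaves, tree=tree)
        assert np.abs(np.asarray(ours.data) - np.asarray(ref.data)).max() < 1e-10

    def test_triangle_inequality_spot_check(self):
        rng = np.random.default_rng(21)
        tree = random_tree(rng, 8)
        table = random_table(rng, [f"s{i}" for i in range(6)],
                             [t.name for t in tree.tips()])
        for mode in ("unweighted", "weighted"):
            d = np.asarray(unifrac(table, tree, mode).data)
            n = d.shape[0]
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-10


class TestPcoa:
    def test_three_equidistant_points(self):
        from skbio import DistanceMatrix
        dm = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]],
                                     dtype=float), ids=list("abc"))
        res = pcoa(dm)
        assert len(res.eigenvalues) == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
        coords = res.coordinates.to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(1.0)

    def test_recovers_points_on_a_line(self):
        from skbio import DistanceMatrix
        x = np.array([0.0, 1.0, 3.0, 6.0])
        dm = DistanceMatrix(np.abs(x[:, None] - x[None, :]),
                            ids=[f"s{i}" for i in range(4)])
        res = pcoa(dm)
        axis1 = res.coordinates["PC1"].to_numpy()
        centered = x - x.mean()
        assert (np.allclose(axis1, centered, atol=1e-9)
                or np.allclose(axis1, -centered, atol=1e-9))
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_zero_matrix_gives_no_positive_eigenvalues(self):
        from skbio import DistanceMatrix
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = pcoa(dm)
        assert len(res.eigenvalues) == 0

    def test_euclidean_distances_reproduced_from_coordinates(self):
        from skbio import DistanceMatrix
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(7, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(DistanceMatrix(d, ids=[f"s{i}" for i in range(7)]))
        coords = res.coordinates.to_numpy()
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.abs(d - d2).max() < 1e-9

    def test_non_symmetric_rejected(self):
        class Fake:
            data = np.array([[0, 1], [2, 0]], dtype=float)
            ids = ("a", "b")
        with pytest.raises(ValidationError, match="symmetric"):
            pcoa(Fake())


class TestBiplot:
    def _ordination(self):
        from skbio import DistanceMatrix
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        return pcoa(DistanceMatrix(d, ids=["s1", "s2", "s3", "s4"]))

    def test_feature_in_one_sample_sits_on_that_sample(self):
        res = self._ordination()
        rel = pd.DataFrame({"f": [0.0, 0.0, 1.0, 0.0]},
                           index=["s1", "s2", "s3", "s4"])
        load = biplot_loadings(res, rel)
        assert np.allclose(load.loc["f", res.coordinates.columns],
                           res.coordinates.loc["s3"])

    def test_uniform_feature_at_origin(self):
        res = self._ordination()
        rel = pd.DataFrame({"f": [0.25] * 4}, index=["s1", "s2", "s3", "s4"])
        load = biplot_loadings(res, rel)
        assert np.allclose(load.loc["f", res.coordinates.columns], 0.0,
                           atol=1e-12)

    def test_matches_hand_computed_weighted_average(self):
        res = self._ordination()
        rel = pd.DataFrame({"f": [0.6, 0.2, 0.2, 0.0],
                            "gone": [0.0, 0.0, 0.0, 0.0]},
                           index=["s1", "s2", "s3", "s4"])
        load = biplot_loadings(res, rel)
        w = np.array([0.6, 0.2, 0.2, 0.0])
        expected = w @ res.coordinates.to_numpy()
        assert np.allclose(load.loc["f", res.coordinates.columns], expected)
        assert "gone" not in load.index  # absent feature excluded
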