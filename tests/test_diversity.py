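import itertools
import math

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from dmftbiome import (
    FeatureTable,
    bray_curtis,
    jensen_shannon,
    observed_richness,
    pcoa,
    permanova,
    rarefaction_curve,
    shannon,
    tve,
    unifrac,
)
from dmftbiome.diversity import rarefy_sample

from _oracles import permanova_exact_p, permanova_f, unifrac_matrix


def star_tree(taxa, length=1.0):
    root = TreeNode()
    for t in taxa:
        leaf = TreeNode(name=t)
        leaf.length = length
        root.append(leaf)
    return root


class TestShannon:
    def test_uniform_closed_form(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(math.log(4), abs=1e-12)

    def test_single_taxon_zero(self):
        assert shannon([7, 0, 0]) == 0.0

    def test_direct_formula(self):
        # p = (1/4, 1/4, 1/2)
        expected = -(0.25 * math.log(0.25) * 2 + 0.5 * math.log(0.5))
        assert shannon([1, 1, 2]) == pytest.approx(expected, abs=1e-9)
        assert shannon([1, 1, 2]) == pytest.approx(1.03972, abs=1e-5)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])


class TestRarefaction:
    def test_full_depth_recovers_observed(self, rng):
        x = np.array([4, 0, 2, 9])
        sub = rarefy_sample(x, int(x.sum()), rng)
        np.testing.assert_array_equal(sub, x)

    def test_depth_one_gives_richness_one(self, rng):
        x = np.array([4, 0, 2, 9])
        assert observed_richness(rarefy_sample(x, 1, rng)) == 1

    def test_hypergeometric_expectation(self):
        """Uniform 10-taxon sample (5 reads each), subsampled to 5: the mean
        observed richness matches 10*(1 - C(45,5)/C(50,5)) within 3 sd."""
        t = FeatureTable(np.full((1, 10), 5), ("s1",), tuple(f"t{i}" for i in range(10)))
        curve = rarefaction_curve(t, [5], n_reps=200, seed=4, metric="observed")
        expected = 10 * (1 - math.comb(45, 5) / math.comb(50, 5))
        sd = curve["sd"].iloc[0] / math.sqrt(200)
        assert abs(curve["mean"].iloc[0] - expected) < 3 * sd

    def test_too_deep_sample_skipped_with_warning(self, small_table):
        with pytest.warns(UserWarning, match="skipped"):
            curve = rarefaction_curve(small_table, [12], n_reps=2, seed=0)
        # only samples with depth >= 12 remain (s3 has depth 17)
        assert set(curve["sample_id"]) == {"s3"}


class TestBetaDistances:
    def test_identical_samples_are_zero(self):
        t = FeatureTable(np.array([[2, 3, 5], [2, 3, 5]]), ("a", "b"), ("x", "y", "z"))
        assert bray_curtis(t)["a", "b"] == pytest.approx(0.0, abs=1e-12)
        assert jensen_shannon(t)["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_closed_forms(self):
        t = FeatureTable(np.array([[4, 0], [0, 9]]), ("a", "b"), ("x", "y"))
        assert bray_curtis(t)["a", "b"] == pytest.approx(1.0, abs=1e-12)
        assert jensen_shannon(t)["a", "b"] == pytest.approx(math.log(2), abs=1e-9)

    def test_bray_curtis_worked_example(self):
        t = FeatureTable(np.array([[2, 2, 0], [0, 2, 2]]), ("a", "b"), ("x", "y", "z"))
        assert bray_curtis(t)["a", "b"] == pytest.approx(0.5, abs=1e-12)

    def test_symmetry_zero_diagonal_range(self, random_table_factory):
        t = random_table_factory(n_samples=6)
        for dm in (bray_curtis(t), jensen_shannon(t)):
            m = np.asarray(dm.data)
            np.testing.assert_allclose(m, m.T, atol=1e-12)
            assert np.all(np.diag(m) == 0)
            assert m.max() <= 1.0 + 1e-12

    def test_empty_sample_rejected(self):
        t = FeatureTable(np.array([[0, 0], [1, 2]]), ("a", "b"), ("x", "y"))
        with pytest.raises(ValueError):
            bray_curtis(t)


class TestUnifrac:
    def test_identical_samples_zero_both_variants(self):
        tree = star_tree(["x", "y", "z"])
        t = FeatureTable(np.array([[1, 2, 3], [1, 2, 3]]), ("a", "b"), ("x", "y", "z"))
        assert unifrac(t, tree, weighted=False)["a", "b"] == pytest.approx(0, abs=1e-12)
        assert unifrac(t, tree, weighted=True)["a", "b"] == pytest.approx(0, abs=1e-12)

    def test_star_tree_disjoint_closed_form(self):
        """Disjoint leaf sets on a unit-branch star: every occupied branch is
        unique to one sample, so both normalized variants are exactly 1."""
        tree = star_tree(["w", "x", "y", "z"])
        t = FeatureTable(np.array([[3, 1, 0, 0], [0, 0, 2, 2]]), ("a", "b"), ("w", "x", "y", "z"))
        assert unifrac(t, tree, weighted=False)["a", "b"] == pytest.approx(1.0, abs=1e-12)
        assert unifrac(t, tree, weighted=True, normalized=True)["a", "b"] == pytest.approx(
            1.0, abs=1e-12
        )

    @pytest.mark.parametrize("weighted,normalized", [(False, True), (True, True), (True, False)])
    def test_matches_branch_enumeration_oracle(self, weighted, normalized, random_table_factory):
        from dmftbiome.synth import generate_tree

        t = random_table_factory(n_samples=10, n_taxa=12, depth=200, zero_frac=0.4)
        tree = generate_tree(t.taxon_ids, seed=2)
        got = np.asarray(unifrac(t, tree, weighted=weighted, normalized=normalized).data)
        want = unifrac_matrix(t, tree, weighted=weighted, normalized=normalized)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_missing_taxon_listed(self):
        tree = star_tree(["x", "y"])
        t = FeatureTable(np.array([[1, 1, 1]]), ("a",), ("x", "y", "zzz"))
        with pytest.raises(ValueError, match="zzz"):
            unifrac(t, tree)


class TestPcoaAndTve:
    def test_equilateral_triangle_two_equal_eigenvalues(self):
        d = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float), ids=list("abc"))
        res = pcoa(d)
        lam = res.eigenvalues
        assert lam[0] == pytest.approx(lam[1], abs=1e-10)
        assert lam[2] == pytest.approx(0.0, abs=1e-10)

    def test_collinear_points_rank_one(self):
        pts = np.array([0.0, 1.0, 2.5, 4.0])
        d = np.abs(pts[:, None] - pts[None, :])
        res = pcoa(DistanceMatrix(d, ids=list("abcd")))
        assert res.coordinates.shape[1] == 1

    def test_euclidean_distances_reconstructed(self, rng):
        pts = rng.normal(size=(7, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(7)]))
        coords = res.coordinates
        rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(rec, d, atol=1e-8)

    def test_eigenvalue_sum_equals_trace(self, random_table_factory):
        t = random_table_factory(n_samples=8)
        d = bray_curtis(t)
        D = np.asarray(d.data)
        n = D.shape[0]
        J = np.eye(n) - 1 / n
        G = J @ (-0.5 * D**2) @ J
        res = pcoa(d)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(G), abs=1e-10)

    def test_cross_check_against_skbio(self, random_table_factory):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        t = random_table_factory(n_samples=9)
        d = bray_curtis(t)
        mine = pcoa(d)
        theirs = skbio_pcoa(d, method="eigh", number_of_dimensions=0)
        np.testing.assert_allclose(
            np.sort(mine.eigenvalues), np.sort(np.asarray(theirs.eigvals)), atol=1e-8
        )

    def test_tve_rank2_is_one_and_k0_is_zero(self):
        d = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float), ids=list("abc"))
        res = pcoa(d)
        assert tve(res, k=5) == pytest.approx(1.0, abs=1e-12)
        assert tve(res, k=0) == 0.0

    def test_tve_equal_eigenvalue_construction(self):
        """11 equidistant points (a regular 10-simplex) have 10 equal
        positive eigenvalues, so TVE(k=5) = 5/10 exactly."""
        d = np.ones((11, 11)) - np.eye(11)
        res = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(11)]))
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 10
        np.testing.assert_allclose(pos, pos[0], atol=1e-10)
        assert tve(res, k=5) == pytest.approx(0.5, abs=1e-10)

    def test_tve_monotone_in_k(self, random_table_factory):
        t = random_table_factory(n_samples=10)
        res = pcoa(bray_curtis(t))
        vals = [tve(res, k=k) for k in range(0, 10)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestPermanova:
    def _two_clouds(self, n_per=4):
        jitter = np.arange(2 * n_per * 2).reshape(2 * n_per, 2) * 0.01
        a = np.zeros((n_per, 2))
        b = np.ones((n_per, 2)) * 10
        pts = np.vstack([a, b]) + jitter
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        return DistanceMatrix(d, ids=[str(i) for i in range(2 * n_per)])

    def test_perfect_separation(self):
        # groups large enough that a random shuffle essentially never
        # reproduces the observed split, so p hits its floor
        d = self._two_clouds(n_per=12)
        res = permanova(d, ["g1"] * 12 + ["g2"] * 12, n_perm=999, seed=0)
        assert res["R2"] > 0.99
        assert res["p"] == pytest.approx(1 / (1 + 999), abs=1e-12)

    def test_matches_exhaustive_oracle_n6(self, random_table_factory):
        t = random_table_factory(n_samples=6)
        d = bray_curtis(t)
        labels = ["a", "a", "a", "b", "b", "b"]
        f_obs, p_exact = permanova_exact_p(np.asarray(d.data) ** 2, labels)
        res = permanova(d, labels, n_perm=9999, seed=3)
        assert res["pseudo_F"] == pytest.approx(f_obs, abs=1e-10)
        assert abs(res["p"] - p_exact) < 0.03

    def test_cross_check_against_skbio(self, random_table_factory):
        from skbio.stats.distance import permanova as skbio_permanova

        t = random_table_factory(n_samples=12)
        d = bray_curtis(t)
        labels = ["a"] * 6 + ["b"] * 6
        mine = permanova(d, labels, n_perm=99, seed=0)
        theirs = skbio_permanova(d, grouping=labels, permutations=0)
        assert mine["pseudo_F"] == pytest.approx(theirs["test statistic"], abs=1e-10)

    def test_invariant_to_joint_reordering(self, random_table_factory, rng):
        t = random_table_factory(n_samples=10)
        d = bray_curtis(t)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        res1 = permanova(d, labels, n_perm=499, seed=7)
        order = rng.permutation(10)
        ids = np.asarray(d.ids)[order]
        d2 = DistanceMatrix(np.asarray(d.data)[np.ix_(order, order)], ids=list(ids))
        res2 = permanova(d2, labels[order], n_perm=499, seed=7)
        assert res1["pseudo_F"] == pytest.approx(res2["pseudo_F"], abs=1e-12)
        assert res1["R2"] == pytest.approx(res2["R2"], abs=1e-12)

    def test_degenerate_single_group_rejected(self):
        d = self._two_clouds()
        with pytest.raises(ValueError):
            permanova(d, ["g"] * 8, n_perm=9, seed=0)
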