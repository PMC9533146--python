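import networkx as nx
import numpy as np
import pytest

from dmftbiome import (
    FeatureTable,
    bh_fdr,
    build_graph,
    communities,
    degree_rank,
    entropy_statistic,
    network_for_table,
    spearman_matrix,
)

from _oracles import bh_stepup, spearman_rank_then_pearson


class TestSpearmanMatrix:
    def test_self_correlation_is_one(self, random_table_factory):
        t = random_table_factory(n_samples=12, n_taxa=6)
        rho, _ = spearman_matrix(t)
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_perfectly_monotone_pair(self):
        up = np.array([1, 2, 3, 4, 5, 6])
        counts = np.column_stack([up, up * 3, up[::-1]])
        t = FeatureTable(counts, tuple(f"s{i}" for i in range(6)), ("a", "b", "c"))
        rho, _ = spearman_matrix(t)
        assert rho[0, 1] == pytest.approx(1.0)
        assert rho[0, 2] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, random_table_factory):
        t = random_table_factory(n_samples=8, n_taxa=7, zero_frac=0.0)
        rho, _ = spearman_matrix(t)
        oracle = spearman_rank_then_pearson(t.relative_abundance())
        np.testing.assert_allclose(rho, oracle, atol=1e-12)

    def test_constant_genus_flagged_nan(self):
        rel_const = np.array([[2, 2], [4, 4], [6, 6], [8, 8]])  # both constant at 0.5
        t = FeatureTable(rel_const, tuple(f"s{i}" for i in range(4)), ("a", "b"))
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman_matrix(t)
        assert np.isnan(rho[0, 1]) and np.isnan(p[0, 1])

    def test_too_few_samples_rejected(self):
        t = FeatureTable(np.ones((3, 3), int), ("a", "b", "c"), ("x", "y", "z"))
        with pytest.raises(ValueError):
            spearman_matrix(t)


class TestBhFdr:
    def test_hand_stepup_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_all_ones_stay_ones(self):
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_matches_stepup_oracle_and_preserves_order(self, rng):
        p = rng.random(200)
        adj = bh_fdr(p)
        np.testing.assert_allclose(adj, bh_stepup(p), atol=1e-12)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestBuildGraph:
    def _simple(self, rho_ab, p_ab):
        rho = np.array([[1.0, rho_ab], [rho_ab, 1.0]])
        p = np.array([[np.nan, p_ab], [p_ab, np.nan]])
        return build_graph(rho, p, ["a", "b"])

    def test_threshold_is_strict(self):
        assert self._simple(0.5, 0.001).number_of_edges() == 0
        assert self._simple(0.5000001, 0.001).number_of_edges() == 1

    def test_negative_edge_significant(self):
        g = self._simple(-0.6, 0.01)
        assert g.edges["a", "b"]["rho"] == -0.6
        assert g.edges["a", "b"]["significant"] is True

    def test_significance_is_attribute_not_filter(self):
        g = self._simple(0.9, 0.2)
        assert g.number_of_edges() == 1
        assert g.edges["a", "b"]["significant"] is False

    def test_symmetric_in_input_order(self, random_table_factory):
        t = random_table_factory(n_samples=15, n_taxa=10, zero_frac=0.0)
        g1 = network_for_table(t)
        rev = t.drop_taxa([])  # copy
        rev = FeatureTable(t.counts[:, ::-1], t.sample_ids, t.taxon_ids[::-1])
        g2 = network_for_table(rev)
        assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))
        for u, v in g1.edges:
            assert g1.edges[u, v]["rho"] == pytest.approx(g2.edges[u, v]["rho"], abs=1e-12)


class TestEntropyStatistic:
    def _graph(self, flags):
        g = nx.Graph()
        g.graph["n_pairs_tested"] = 10
        for i, sig in enumerate(flags):
            g.add_edge(f"a{i}", f"b{i}", rho=0.8, abs_rho=0.8, p_adj=0.01, significant=sig)
        return g

    def test_all_significant_is_one(self):
        assert entropy_statistic(self._graph([True] * 4)) == 1.0

    def test_half_significant(self):
        assert entropy_statistic(self._graph([True, False])) == 0.5

    def test_all_pairs_denominator(self):
        g = self._graph([True, True])
        assert entropy_statistic(g, denominator="all_pairs") == pytest.approx(0.2)

    def test_edgeless_graph_rejected(self):
        g = nx.Graph()
        g.add_node("a")
        with pytest.raises(ValueError):
            entropy_statistic(g)


class TestCommunities:
    def test_two_cliques_one_bridge(self):
        g = nx.Graph()
        left = ["a1", "a2", "a3", "a4"]
        right = ["b1", "b2", "b3", "b4"]
        for grp in (left, right):
            for i, u in enumerate(grp):
                for v in grp[i + 1 :]:
                    g.add_edge(u, v, abs_rho=1.0, significant=True, rho=1.0, p_adj=0.0)
        g.add_edge("a1", "b1", abs_rho=1.0, significant=True, rho=1.0, p_adj=0.0)
        comms = communities(g, seed=0)
        assert sorted(map(tuple, comms)) == [tuple(left), tuple(right)]

    def test_complete_graph_single_community(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 1.0, "abs_rho")
        assert len(communities(g, seed=0)) == 1

    def test_isolated_nodes_are_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(["x", "y", "z"])
        assert communities(g, seed=0) == [["x"], ["y"], ["z"]]

    def test_deterministic(self, random_table_factory):
        t = random_table_factory(n_samples=15, n_taxa=12, zero_frac=0.0)
        g = network_for_table(t)
        assert communities(g, seed=1) == communities(g, seed=1)


class TestDegreeRank:
    def test_star_center_first(self):
        g = nx.star_graph(["hub", "a", "b", "c"])
        assert degree_rank(g)[0] == "hub"

    def test_regular_graph_lexicographic(self):
        g = nx.cycle_graph(["d", "b", "a", "c"])
        assert degree_rank(g) == ["a", "b", "c", "d"]

    def test_matches_degree_count_oracle(self, rng):
        g = nx.gnp_random_graph(30, 0.2, seed=5)
        got = degree_rank(g, top_k=30)
        degrees = dict(g.degree())
        oracle = sorted(g.nodes, key=lambda n: (-degrees[n], n))
        assert got == oracle

    def test_truncates_at_top_k(self):
        g = nx.complete_graph(10)
        assert len(degree_rank(g, top_k=4)) == 4


class TestNullBehaviour:
    def test_independence_null_rarely_significant(self):
        """Under factor_strength=0, BH at 0.05 yields a significant fraction
        below alpha in the large majority of replicates (here 15)."""
        import warnings

        from dmftbiome.synth import SyntheticDesign, generate_dataset

        below = 0
        n_reps = 15
        for rep in range(n_reps):
            d = SyntheticDesign(
                n_per_category=(8, 8, 8, 8, 8),
                n_taxa=100,
                core_size=100,
                accessory_rate=0.0,
                factor_strength=0.0,
                depth_log_mean=9.0,
                depth_log_sd=0.3,
                seed=4200 + rep,
            )
            table, *_ = generate_dataset(d)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                g = network_for_table(table)
            try:
                frac = entropy_statistic(g)
            except ValueError:
                frac = 0.0
            below += frac < 0.05
        assert below >= int(0.9 * n_reps)

    def test_entropy_increases_with_factor_strength(self):
        """Mean significant fraction is non-decreasing in the latent factor
        strength (averaged over replicate cohorts)."""
        import warnings

        from dmftbiome.synth import SyntheticDesign, generate_dataset

        means = []
        for fs in (0.0, 0.8, 2.0):
            vals = []
            for rep in range(8):
                d = SyntheticDesign(
                    n_per_category=(8, 8, 8, 8, 8),
                    n_taxa=60,
                    core_size=60,
                    accessory_rate=0.0,
                    factor_strength=fs,
                    depth_log_mean=9.0,
                    depth_log_sd=0.3,
                    seed=7100 + rep,
                )
                table, *_ = generate_dataset(d)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    g = network_for_table(table)
                try:
                    vals.append(entropy_statistic(g))
                except ValueError:
                    vals.append(0.0)
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]
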