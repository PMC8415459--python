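"""Co-occurrence inference, Brown/BH, RMT threshold, modules, topology."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecoassembly.network import (
    bh_adjust,
    browns_combine,
    build_network,
    dominant_modules,
    fast_greedy_modules,
    infer_edges,
    local_network_distance,
    local_network_features,
    module_eigengene,
    pairwise_scores,
    reboot_pvalues,
    rmt_threshold,
)
from ecoassembly.simulate import simulate_correlated_blocks
from ecoassembly.tables import OtuTable


class TestPairwiseScores:
    def test_identical_profiles(self):
        rel = pd.DataFrame({"a": [0.1, 0.2, 0.3, 0.4], "b": [0.1, 0.2, 0.3, 0.4]})
        rho, bc = pairwise_scores(rel)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert bc.loc["a", "b"] == pytest.approx(1.0)

    def test_opposite_trends(self):
        rel = pd.DataFrame({"a": [1, 2, 3, 4.0], "b": [4, 3, 2, 1.0]})
        rho, _ = pairwise_scores(rel)
        assert rho.loc["a", "b"] == pytest.approx(-1.0)

    def test_hand_bray_curtis_similarity(self):
        # sum|x-y| = 1+2+3 = 6, sum(x+y) = 18 -> similarity 1 - 6/18
        rel = pd.DataFrame({"a": [1, 2, 3, 0.0], "b": [2, 4, 6, 0.0]})
        rho, bc = pairwise_scores(rel)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert bc.loc["a", "b"] == pytest.approx(1 - 6 / 18)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pairwise_scores(pd.DataFrame({"a": [1, 2], "b": [2, 1]}))


class TestReboot:
    def _table(self, seed=0, n=30):
        table, _ = simulate_correlated_blocks(2, 4, rho=0.9, n_samples=n, seed=seed)
        return table.counts

    def test_correlated_pair_small_p(self):
        hits = 0
        for seed in range(5):
            counts = self._table(seed)
            res = reboot_pvalues(counts, ("b1_t1", "b1_t2"), n_perm=300, n_boot=300, seed=seed)
            hits += res.p_spearman < 0.01
        assert hits >= 4

    def test_independent_pair_large_p(self):
        # truly independent taxa (rho = 0 generator; with 8 taxa and no
        # block structure the compositional closure effect is mild)
        ps = []
        for seed in range(5):
            table, _ = simulate_correlated_blocks(2, 4, rho=0.0, n_samples=30, seed=seed)
            res = reboot_pvalues(
                table.counts, ("b1_t1", "b2_t1"), n_perm=300, n_boot=300, seed=seed
            )
            ps.append(res.p_spearman)
        assert np.median(ps) > 0.05

    def test_degenerate_constant_pair(self):
        counts = pd.DataFrame(
            {"a": [5] * 8, "b": [5] * 8, "c": [1, 2, 3, 4, 5, 6, 7, 8]},
            index=[f"s{i}" for i in range(8)],
        )
        res = reboot_pvalues(counts, ("a", "b"), n_perm=50, n_boot=50, seed=0)
        assert res.degenerate
        assert res.p_spearman == 1.0


class TestBrown:
    def test_zero_covariance_reduces_to_fisher(self):
        # p1 = p2 = 0.05: X = 11.98, chi2_4 tail = 0.0175
        p = browns_combine([0.05], [0.05], cov_estimate=0.0)
        x = -4 * np.log(0.05)
        assert p == pytest.approx(stats.chi2.sf(x, 4), abs=1e-9)
        assert p == pytest.approx(0.0175, abs=5e-4)

    def test_fully_dependent_duplicated_measure(self):
        # duplicated measure: cov = Var(-2 ln p) = 4 -> brown_p ~ p1
        for p1 in (0.01, 0.05, 0.2, 0.7):
            bp = browns_combine([p1], [p1], cov_estimate=4.0)
            assert bp == pytest.approx(p1, rel=1e-9)

    def test_unit_pvalues(self):
        assert browns_combine([1.0], [1.0], cov_estimate=0.0) == pytest.approx(1.0)

    def test_empirical_covariance_route(self, rng):
        p1 = rng.uniform(0.001, 1, 50)
        out = browns_combine(p1, p1)  # perfectly dependent arrays
        assert np.allclose(out, p1, rtol=0.3)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            browns_combine([0.0], [0.5], cov_estimate=0.0)


class TestBH:
    def test_worked_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_q_at_least_p_and_order_invariant(self, rng):
        p = rng.uniform(0, 1, 30)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        perm = rng.permutation(30)
        q2 = bh_adjust(p[perm])
        assert np.allclose(q2, q[perm])


class TestRmt:
    def test_scan_bounds_respected(self):
        table, _ = simulate_correlated_blocks(2, 20, rho=0.9, n_samples=40, seed=1)
        rel = table.counts.div(table.counts.sum(axis=1), axis=0)
        rho, _ = pairwise_scores(rel)
        t = rmt_threshold(rho, min_component=15)
        assert 0.50 <= t <= 0.95

    def test_block_structure_threshold_below_block_rho(self):
        table, _ = simulate_correlated_blocks(2, 25, rho=0.9, n_samples=50, seed=2)
        rel = table.counts.div(table.counts.sum(axis=1), axis=0)
        rho, _ = pairwise_scores(rel)
        t = rmt_threshold(rho, min_component=20)
        assert t <= 0.9

    def test_fallback_warning_on_sparse_matrix(self):
        rng = np.random.default_rng(3)
        n = 40
        r = np.eye(n) + rng.uniform(-0.05, 0.05, (n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        rho = pd.DataFrame(r, index=[f"t{i}" for i in range(n)], columns=[f"t{i}" for i in range(n)])
        with pytest.warns(UserWarning, match="default"):
            t = rmt_threshold(rho, default=0.74)
        assert t == 0.74


class TestBuildNetwork:
    def _edges(self):
        return pd.DataFrame(
            {
                "taxon_a": ["a", "a", "b", "c"],
                "taxon_b": ["b", "c", "c", "d"],
                "rho": [0.9, 0.70, -0.8, 0.95],
                "bc_sim": [0.8, 0.5, 0.4, 0.9],
                "sign": ["+", "+", "-", "+"],
                "q": [0.01, 0.01, 0.04, 0.06],
            }
        )

    def test_q_and_rho_filters(self):
        g = build_network(self._edges(), q_max=0.05, rho_min=0.74)
        # (a,c): rho 0.70 < 0.74 excluded; (c,d): q 0.06 > 0.05 excluded
        assert set(map(frozenset, g.edges)) == {frozenset("ab"), frozenset("bc")}

    def test_filter_order_commutes(self):
        e = self._edges()
        by_q_then_rho = e[(e.q <= 0.05)]
        by_q_then_rho = by_q_then_rho[by_q_then_rho.rho.abs() >= 0.74]
        by_rho_then_q = e[e.rho.abs() >= 0.74]
        by_rho_then_q = by_rho_then_q[by_rho_then_q.q <= 0.05]
        assert by_q_then_rho.equals(by_rho_then_q)

    def test_domain_subgraph(self):
        from ecoassembly.network import domain_subgraph

        domain = pd.Series({"a": "bacteria", "b": "bacteria", "c": "fungi", "d": "fungi"})
        g = build_network(self._edges(), q_max=0.05, rho_min=0.5, domain=domain)
        sub = domain_subgraph(g, "bacteria")
        assert set(sub.nodes) == {"a", "b"}
        assert all(g.nodes[n]["domain"] == "bacteria" for n in sub)


def brute_force_best_modularity(g):
    """Maximum modularity over every partition of the node set."""
    nodes = list(g.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[head] + part[i]] + part[i + 1:]
            yield [[head]] + part

    best = -1.0
    for part in partitions(nodes):
        q = nx.community.modularity(g, [set(b) for b in part])
        best = max(best, q)
    return best


class TestModules:
    def test_two_triangles_q_half(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        modules, q = fast_greedy_modules(g)
        assert modules.nunique() == 2
        assert q == pytest.approx(0.5)

    def test_single_clique_q_zero(self):
        g = nx.complete_graph(5)
        modules, q = fast_greedy_modules(g)
        assert modules.nunique() == 1
        assert q == pytest.approx(0.0)

    def test_matches_brute_force_on_small_modular_graphs(self):
        graphs = [
            nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]),
            nx.barbell_graph(3, 1),
            nx.Graph([(0, 1), (1, 2), (2, 3), (3, 0), (4, 5), (5, 6), (6, 7), (7, 4), (0, 4)]),
        ]
        for g in graphs:
            _, q = fast_greedy_modules(g)
            assert q == pytest.approx(brute_force_best_modularity(g), abs=1e-9)

    def test_never_exceeds_brute_force_optimum(self):
        # CNM is greedy: on sparse chains it can stop below the optimum,
        # but it can never exceed it
        g = nx.Graph([(0, 1), (1, 2), (2, 3), (4, 5), (5, 6), (6, 7), (0, 4)])
        _, q = fast_greedy_modules(g)
        assert q <= brute_force_best_modularity(g) + 1e-12

    def test_negative_edges_excluded_from_clustering(self):
        g = nx.Graph()
        g.add_edge("a", "b", sign="+")
        g.add_edge("b", "c", sign="-")
        modules, q = fast_greedy_modules(g)
        assert set(modules.index) == {"a", "b", "c"}

    def test_block_recovery_ari(self):
        from sklearn.metrics import adjusted_rand_score

        table, blocks = simulate_correlated_blocks(2, 15, rho=0.9, n_samples=40, seed=4)
        rel = table.counts.div(table.counts.sum(axis=1), axis=0)
        rho, _ = pairwise_scores(rel)
        # clustering runs on positive associations; compositional closure
        # makes between-block correlations negative
        A = (rho >= 0.5).astype(int)
        np.fill_diagonal(A.values, 0)
        g = nx.from_pandas_adjacency(A)
        modules, _ = fast_greedy_modules(g)
        ari = adjusted_rand_score(blocks[modules.index], modules)
        assert ari > 0.9

    def test_dominant_modules_rule(self):
        assignment = pd.Series([1] * 50 + [2] * 40 + [3] * 5 + [4] * 5)
        assert dominant_modules(assignment) == [1, 2]


class TestEigengene:
    def test_identical_members_explain_everything(self):
        profile = np.array([1, 3, 2, 5, 4.0])
        rel = pd.DataFrame({f"t{i}": profile for i in range(4)},
                           index=[f"s{i}" for i in range(5)])
        eg, var = module_eigengene(rel, rel.columns)
        assert var == pytest.approx(1.0)
        assert abs(np.corrcoef(eg, profile)[0, 1]) == pytest.approx(1.0)

    def test_sign_fixed_to_mean_profile(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 5, 12)
        rel = pd.DataFrame(
            {f"t{i}": base + rng.normal(0, 0.1, 12) for i in range(5)},
            index=[f"s{i}" for i in range(12)],
        )
        eg, _ = module_eigengene(rel, rel.columns)
        assert np.corrcoef(eg, base)[0, 1] > 0.9

    def test_gradient_module_tracks_gradient(self):
        x = np.linspace(0, 1, 20)
        rng = np.random.default_rng(1)
        rel = pd.DataFrame(
            {f"t{i}": x * (i + 1) + rng.normal(0, 0.05, 20) for i in range(5)},
            index=[f"s{i}" for i in range(20)],
        )
        eg, _ = module_eigengene(rel, rel.columns)
        assert abs(stats.spearmanr(eg, x).statistic) > 0.7

    def test_small_module_rejected(self):
        rel = pd.DataFrame({"a": [1, 2, 3.0], "b": [1, 2, 3.0]})
        with pytest.raises(ValueError, match="at least 3"):
            module_eigengene(rel, ["a", "b"])


class TestLocalNetworks:
    def _graph_and_table(self):
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, {i: f"t{i}" for i in range(4)})
        path = nx.path_graph(4)
        path = nx.relabel_nodes(path, {i: f"p{i}" for i in range(4)})
        whole = nx.union(g, path)
        counts = pd.DataFrame(
            {
                **{f"t{i}": [5, 0] for i in range(4)},
                **{f"p{i}": [0, 5] for i in range(4)},
            },
            index=["clique_sample", "path_sample"],
        )
        return whole, OtuTable(counts)

    def test_clique_and_path_features(self):
        g, table = self._graph_and_table()
        feats = local_network_features(g, table)
        assert feats.loc["clique_sample", "density"] == pytest.approx(1.0)
        assert feats.loc["clique_sample", "diameter"] == 1
        assert feats.loc["path_sample", "diameter"] == 3

    def test_feature_distance_matrix_properties(self):
        g, table = self._graph_and_table()
        feats = local_network_features(g, table)
        d, kept = local_network_distance(feats, collinearity_rho=0.99)
        assert np.allclose(d.values, d.values.T)
        assert (np.diag(d.values) == 0).all()
        assert len(kept) >= 1


class TestEdgeInference:
    def test_blocks_give_significant_within_edges(self):
        table, blocks = simulate_correlated_blocks(2, 6, rho=0.9, n_samples=30, seed=5)
        edges = infer_edges(table.counts, n_perm=200, n_boot=200, seed=0)
        edges["same_block"] = [
            blocks[a] == blocks[b] for a, b in zip(edges.taxon_a, edges.taxon_b)
        ]
        within = edges[edges.same_block]
        between = edges[~edges.same_block]
        assert (within.q <= 0.05).mean() > (between.q <= 0.05).mean()

    def test_null_generator_false_discovery_controlled(self):
        q_max = 0.05
        rates = []
        for seed in range(3):
            table, _ = simulate_correlated_blocks(2, 6, rho=0.0, n_samples=30, seed=seed)
            edges = infer_edges(table.counts, n_perm=200, n_boot=200, seed=seed)
            rates.append((edges.q <= q_max).mean())
        assert np.mean(rates) <= 2 * q_max
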