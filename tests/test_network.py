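import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from bentheco.data_model import OtuTable, TaxonomyTable
from bentheco.network import (
    CorrelationMatrix,
    bootstrap_pvalues,
    build_network,
    edge_sign_summary,
    fdr_bh,
    filter_min_count,
    sparcc,
    topology_metrics,
)
from bentheco.synthetic import simulate_compositional


def brute_force_topology(g: nx.Graph) -> dict:
    """All-pairs BFS implementation of the topology summary."""
    nodes = list(g.nodes)
    n, e = len(nodes), g.number_of_edges()
    adj = {u: set(g.neighbors(u)) for u in nodes}
    # local clustering
    cc = []
    for u in nodes:
        k = len(adj[u])
        if k < 2:
            cc.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(adj[u], 2) if b in adj[a])
        cc.append(2 * links / (k * (k - 1)))
    # BFS distances on largest component
    comps = []
    seen = set()
    for u in nodes:
        if u in seen:
            continue
        comp, queue = {u}, [u]
        while queue:
            x = queue.pop()
            for y in adj[x]:
                if y not in comp:
                    comp.add(y)
                    queue.append(y)
        seen |= comp
        comps.append(comp)
    giant = max(comps, key=len)
    dists = []
    diameter = 0
    for u in giant:
        level = {u: 0}
        queue = [u]
        while queue:
            x = queue.pop(0)
            for y in adj[x]:
                if y not in level:
                    level[y] = level[x] + 1
                    queue.append(y)
        for v, dv in level.items():
            if v != u:
                dists.append(dv)
                diameter = max(diameter, dv)
    return {
        "average_degree": 2 * e / n,
        "density": 2 * e / (n * (n - 1)) if n > 1 else 0.0,
        "average_clustering": float(np.mean(cc)),
        "diameter": float(diameter),
        "average_path_length": float(np.mean(dists)) if dists else 0.0,
    }


class TestFilterMinCount:
    def test_strict_threshold_at_20(self):
        table = OtuTable(["s1", "s2"], ["keep", "drop"],
                         np.array([[11, 10], [10, 10]]))
        out = filter_min_count(table, 20)
        assert out.otu_ids == ["keep"]
        assert out.sample_ids == table.sample_ids

    def test_zero_threshold_drops_only_empty(self):
        table = OtuTable(["s"], ["a", "b"], np.array([[0, 1]]))
        assert filter_min_count(table, 0).otu_ids == ["b"]

    def test_empty_result_errors(self):
        table = OtuTable(["s"], ["a"], np.array([[5]]))
        with pytest.raises(ValueError, match="threshold"):
            filter_min_count(table, 100)


class TestSparcc:
    def test_diagonal_and_symmetry(self):
        tab = simulate_compositional(np.eye(8), 40, 2000, seed=1)
        r = sparcc(tab, seed=2).r
        np.testing.assert_allclose(np.diag(r), 1.0)
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        assert (np.abs(r) <= 1).all()

    def test_noise_calibrated_null_bound(self):
        # per-pair sampling sd at n=200 is ~0.07; max over 45 pairs stays
        # well under 0.3
        tab = simulate_compositional(np.eye(10), 200, 10_000, seed=3)
        r = sparcc(tab, seed=4).r
        off = r[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 0.3
        assert np.abs(np.median(off)) < 0.05

    def test_compositional_scale_invariance(self):
        tab = simulate_compositional(np.eye(8), 60, 3000, seed=5)
        r1 = sparcc(tab, seed=6).r
        scaled = tab.counts.copy()
        scaled[0] *= 10  # one sample sequenced 10x deeper
        r2 = sparcc(OtuTable(tab.sample_ids, tab.otu_ids, scaled), seed=6).r
        assert np.abs(r1 - r2).max() < 0.02

    def test_too_few_otus_rejected(self):
        tab = OtuTable([f"s{i}" for i in range(12)], ["a", "b", "c"],
                       np.ones((12, 3), dtype=int))
        with pytest.raises(ValueError):
            sparcc(tab)


class TestBootstrapP:
    def test_planted_pair_hits_floor(self):
        corr = np.eye(10)
        corr[0, 1] = corr[1, 0] = 0.8
        tab = simulate_compositional(corr, 200, 10_000, seed=7)
        obs = sparcc(tab, seed=8)
        p = bootstrap_pvalues(tab, obs, n_boot=99, seed=9)
        assert p[0, 1] == pytest.approx(1 / 100)
        assert (p >= 1 / 100 - 1e-12).all()

    def test_null_p_roughly_uniform(self):
        tab = simulate_compositional(np.eye(10), 200, 10_000, seed=10)
        obs = sparcc(tab, seed=11)
        p = bootstrap_pvalues(tab, obs, n_boot=99, seed=12)
        vals = p[np.triu_indices(10, 1)]
        _, ks_p = stats.kstest(vals, "uniform")
        assert ks_p > 0.01


class TestFdrBH:
    def test_single_test_unchanged(self):
        assert fdr_bh(np.array([0.037]))[0] == pytest.approx(0.037)

    def test_hand_step_up_example(self):
        adj = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, 0.04, atol=1e-12)

    def test_matrix_adjustment_monotone(self):
        rng = np.random.default_rng(13)
        p = np.ones((6, 6))
        iu, ju = np.triu_indices(6, 1)
        vals = rng.uniform(0.001, 1, iu.size)
        p[iu, ju] = vals
        p[ju, iu] = vals
        adj = fdr_bh(p)
        assert (adj[iu, ju] >= p[iu, ju] - 1e-12).all()
        np.testing.assert_allclose(adj, adj.T)


class TestBuildNetwork:
    def _corr(self, r01, p01):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = r01
        p = np.ones((3, 3))
        p[0, 1] = p[1, 0] = p01
        return CorrelationMatrix(["a", "b", "c"], r), p

    def test_strict_threshold_combinations(self):
        corr, p = self._corr(0.41, 0.005)
        assert build_network(corr, p).has_edge("a", "b")
        corr, p = self._corr(0.39, 0.005)
        assert build_network(corr, p).number_of_edges() == 0
        corr, p = self._corr(0.41, 0.02)
        assert build_network(corr, p).number_of_edges() == 0

    def test_all_p_one_gives_empty_network(self):
        corr, _ = self._corr(0.9, 1.0)
        g = build_network(corr, np.ones((3, 3)))
        assert g.number_of_nodes() == 0

    def test_edge_sign_matches_correlation_sign(self):
        corr, p = self._corr(-0.5, 0.001)
        g = build_network(corr, p)
        assert g["a"]["b"]["sign"] == -1

    def test_edge_set_monotone_in_thresholds(self):
        rng = np.random.default_rng(17)
        r = np.eye(8)
        iu, ju = np.triu_indices(8, 1)
        rv = rng.uniform(-1, 1, iu.size)
        r[iu, ju] = rv; r[ju, iu] = rv
        p = np.ones((8, 8))
        pv = rng.uniform(0, 0.05, iu.size)
        p[iu, ju] = pv; p[ju, iu] = pv
        corr = CorrelationMatrix([f"o{i}" for i in range(8)], r)
        loose = build_network(corr, p, 0.3, 0.04)
        tight = build_network(corr, p, 0.5, 0.02)
        tight_edges = {frozenset(e) for e in tight.edges}
        loose_edges = {frozenset(e) for e in loose.edges}
        assert tight_edges <= loose_edges


class TestTopology:
    def test_triangle(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        nx.set_edge_attributes(g, 1, "sign")
        t = topology_metrics(g)
        assert t["density"] == pytest.approx(1.0)
        assert t["average_clustering"] == pytest.approx(1.0)
        assert t["diameter"] == 1
        assert t["average_path_length"] == pytest.approx(1.0)
        assert t["percent_positive_edges"] == pytest.approx(100.0)

    def test_four_node_path(self):
        g = nx.path_graph(4)
        nx.set_edge_attributes(g, 1, "sign")
        t = topology_metrics(g)
        assert t["diameter"] == 3
        assert t["density"] == pytest.approx(0.5)
        assert t["average_path_length"] == pytest.approx(10 / 6)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(19)
        for rep in range(50):
            g = nx.gnp_random_graph(10, 0.35, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            nx.set_edge_attributes(g, 1, "sign")
            mine = topology_metrics(g)
            ref = brute_force_topology(g)
            for key, val in ref.items():
                assert mine[key] == pytest.approx(val, abs=1e-10), key


class TestEdgeSigns:
    def _net(self):
        g = nx.Graph()
        g.add_edge("o1", "o2", sign=1)
        g.add_edge("o1", "o3", sign=1)
        g.add_edge("o2", "o3", sign=1)
        g.add_edge("o1", "o4", sign=-1)
        return g

    def test_percent_positive(self):
        tax = TaxonomyTable({
            "o1": ["X", "Cercozoa"], "o2": ["Y", "Bacillariophyta"],
            "o3": ["Y", "Bacillariophyta"], "o4": ["Y", "Bacillariophyta"],
        })
        out = edge_sign_summary(self._net(), tax, [("Cercozoa", "Bacillariophyta")])
        # o1-o2 (+), o1-o3 (+), o1-o4 (-) cross the group pair -> 2/3 positive
        assert out["percent_positive"][0] == pytest.approx(100 * 2 / 3)

    def test_no_intergroup_edges_flagged(self):
        tax = TaxonomyTable({
            "o1": ["X", "A"], "o2": ["X", "A"], "o3": ["X", "A"], "o4": ["X", "A"],
            "o9": ["X", "B"],
        })
        g = self._net()
        g.add_node("o9")
        out = edge_sign_summary(g, tax, [("A", "B")])
        assert out["flag"][0] == "no_inter_group_edges"
        assert np.isnan(out["percent_positive"][0])

    def test_unknown_group_lists_available(self):
        tax = TaxonomyTable({o: ["X", "A"] for o in ["o1", "o2", "o3", "o4"]})
        with pytest.raises(ValueError, match="available"):
            edge_sign_summary(self._net(), tax, [("A", "Nope")])
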