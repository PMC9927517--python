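"""Cooccurrence network construction, topology metrics, and comparisons."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phyllo.errors import ValidationError
from phyllo.network import (
    build_network,
    compare_networks,
    hubs,
    network_from_table,
    node_metrics,
    spearman_matrix,
    summarize,
)

from conftest import make_table


def brute_force_metrics(g: nx.Graph) -> pd.DataFrame:
    """Independent recomputation: triangle counting + Floyd-Warshall paths."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((n, n), dtype=bool)
    for u, v in g.edges:
        adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = True
    # all-pairs shortest paths
    dist = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    rows = {}
    for v in nodes:
        i = idx[v]
        neigh = np.flatnonzero(adj[i])
        deg = len(neigh)
        triangles = sum(
            adj[a, b] for a, b in itertools.combinations(neigh, 2)
        )
        clustering = 2 * triangles / (deg * (deg - 1)) if deg > 1 else 0.0
        reachable = np.isfinite(dist[i]) & (np.arange(n) != i)
        total = dist[i][reachable].sum()
        closeness = reachable.sum() / total if total > 0 else 0.0
        # betweenness: fraction of shortest paths through v, normalized
        bet = 0.0
        for s, t in itertools.combinations(range(n), 2):
            if s == i or t == i or not np.isfinite(dist[s, t]):
                continue
            paths_st = count_paths(adj, dist, s, t)
            through = 0
            if np.isclose(dist[s, i] + dist[i, t], dist[s, t]):
                through = count_paths(adj, dist, s, i) * count_paths(adj, dist, i, t)
            bet += through / paths_st
        bet /= (n - 1) * (n - 2) / 2 if n > 2 else 1
        rows[v] = {"degree": deg, "clustering": clustering, "closeness": closeness,
                   "betweenness": bet}
    return pd.DataFrame(rows).T


def count_paths(adj: np.ndarray, dist: np.ndarray, s: int, t: int) -> int:
    if s == t:
        return 1
    total = 0
    for u in np.flatnonzero(adj[:, t]):
        if np.isclose(dist[s, u] + 1, dist[s, t]):
            total += count_paths(adj, dist, s, u)
    return total


def brute_force_modularity(g: nx.Graph, partition) -> float:
    # Q = sum_c [ L_c / m - (sum of degrees in c / 2m)^2 ]
    m = g.number_of_edges()
    q = 0.0
    for comm in partition:
        lc = sum(1 for u, v in g.edges if u in comm and v in comm)
        dc = sum(g.degree(v) for v in comm)
        q += lc / m - (dc / (2 * m)) ** 2
    return q


class TestSpearmanMatrix:
    def test_monotone_pairs(self):
        rel = pd.DataFrame(
            [[1, 2, 3, 4, 5], [2, 4, 6, 8, 10], [5, 4, 3, 2, 1]],
            index=["a", "b", "c"], columns=list("vwxyz"), dtype=float,
        )
        rho, p = spearman_matrix(rel)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert rho.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self, rng):
        x = rng.random((6, 20))
        rho, p = spearman_matrix(pd.DataFrame(x, index=list("abcdef")))
        for i, j in itertools.combinations(range(6), 2):
            ref = stats.spearmanr(x[i], x[j])
            assert rho.iloc[i, j] == pytest.approx(ref.statistic, abs=1e-12)
            assert p.iloc[i, j] == pytest.approx(ref.pvalue, abs=1e-9)

    def test_constant_taxon_undefined(self, rng):
        x = rng.random((3, 10))
        x[1] = 0.5
        rho, p = spearman_matrix(pd.DataFrame(x, index=list("abc")))
        assert np.isnan(rho.loc["b", "a"])

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            spearman_matrix(pd.DataFrame(np.random.rand(3, 4)))


class TestBuildNetwork:
    def _kingdom(self, ids):
        return pd.Series("bacteria", index=ids)

    def test_all_zero_rho_empty(self):
        ids = list("abcd")
        rho = pd.DataFrame(np.eye(4), index=ids, columns=ids)
        p = pd.DataFrame(np.ones((4, 4)), index=ids, columns=ids)
        g = build_network(rho, p, self._kingdom(ids))
        assert g.number_of_edges() == 0

    def test_adjusted_p_excludes_edge(self):
        # |rho| passes, raw p passes, BH-adjusted p = 0.02 > 0.01 -> no edge
        ids = list("abcdefgh")
        n = len(ids)
        rho = pd.DataFrame(np.eye(n), index=ids, columns=ids)
        p = pd.DataFrame(np.ones((n, n)), index=ids, columns=ids)
        rho.loc["a", "b"] = rho.loc["b", "a"] = 0.61
        # 28 pairs; raw p 0.001 adjusts to 0.001 * 28 = 0.028 > 0.01
        p.loc["a", "b"] = p.loc["b", "a"] = 0.001
        g = build_network(rho, p, self._kingdom(ids))
        assert g.number_of_edges() == 0
        g_raw = build_network(rho, p, self._kingdom(ids), correction=None)
        assert g_raw.has_edge("a", "b")

    def test_planted_clique_recovered(self, rng):
        # 3 taxa tied to one latent factor among independent noise taxa
        n_samp = 30
        z = rng.normal(size=n_samp)
        x = rng.normal(size=(12, n_samp)) * 0.2
        for i in range(3):
            x[i] += z
        rel = pd.DataFrame(np.exp(x), index=[f"t{i}" for i in range(12)])
        rho, p = spearman_matrix(rel)
        g = build_network(rho, p, pd.Series("bacteria", index=rel.index))
        assert {tuple(sorted(e)) for e in g.edges} == {("t0", "t1"), ("t0", "t2"), ("t1", "t2")}

    def test_monotone_thresholds(self, rng):
        rel = pd.DataFrame(rng.random((15, 25)))
        rel.index = [f"t{i}" for i in range(15)]
        rho, p = spearman_matrix(rel)
        kd = pd.Series("bacteria", index=rel.index)
        loose = build_network(rho, p, kd, rho_min=0.3, p_max=0.5)
        tight_rho = build_network(rho, p, kd, rho_min=0.5, p_max=0.5)
        tight_p = build_network(rho, p, kd, rho_min=0.3, p_max=0.1)
        canon = lambda g: {tuple(sorted(e)) for e in g.edges}
        assert canon(tight_rho) <= canon(loose)
        assert canon(tight_p) <= canon(loose)

    def test_interkingdom_edge_classes(self, rng):
        n_samp = 20
        z = rng.normal(size=n_samp)
        rows = np.vstack([z + 0.05 * rng.normal(size=n_samp) for _ in range(4)])
        rel = pd.DataFrame(np.exp(rows), index=["b1", "b2", "f1", "f2"])
        kd = pd.Series(["bacteria", "bacteria", "fungi", "fungi"], index=rel.index)
        rho, p = spearman_matrix(rel)
        g = build_network(rho, p, kd)
        classes = {tuple(sorted(e)): d["edge_class"] for *e, d in g.edges(data=True)}
        assert classes[("b1", "b2")] == "BB"
        assert classes[("b1", "f1")] == "BF"
        assert classes[("f1", "f2")] == "FF"


class TestTopologyMetrics:
    def test_triangle_graph(self):
        g = nx.Graph()
        for u, v in [("a", "b"), ("b", "c"), ("a", "c")]:
            g.add_edge(u, v, rho=0.9, adjusted_p=0.001, sign=1, edge_class="BB")
        s = summarize(g)
        assert s.average_degree == pytest.approx(2.0)
        assert s.average_clustering == pytest.approx(1.0)
        assert s.proportion_positive == 1.0

    def test_two_cliques_modularity_closed_form(self):
        g = nx.Graph()
        for block, names in enumerate(("abcde", "fghij")):
            for u, v in itertools.combinations(names, 2):
                g.add_edge(u, v, rho=0.9, adjusted_p=0.001, sign=1, edge_class="BB")
        s = summarize(g)
        partition = [set("abcde"), set("fghij")]
        assert s.modularity == pytest.approx(brute_force_modularity(g, partition), abs=1e-12)
        metrics = node_metrics(g)
        assert metrics.groupby("module").size().tolist() == [5, 5]

    def test_star_graph_closeness(self):
        g = nx.star_graph(4)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(5)})
        for u, v in g.edges:
            g.edges[u, v].update(rho=0.9, adjusted_p=0.001, sign=1, edge_class="BB")
        metrics = node_metrics(g)
        assert metrics.loc["n0", "degree"] == 4
        for leaf in ["n1", "n2", "n3", "n4"]:
            assert metrics.loc[leaf, "closeness"] == pytest.approx(4 / 7)

    def test_hub_ranking_deterministic_tiebreak(self):
        g = nx.Graph()
        for u, v in [("b", "a"), ("b", "c"), ("d", "a"), ("d", "c"), ("a", "c")]:
            g.add_edge(u, v, rho=0.9, adjusted_p=0.001, sign=1, edge_class="BB")
        top = hubs(g, k=4)
        # a and c tie on degree 3 and closeness; lexicographic ID breaks the tie
        assert list(top.index[:2]) == ["a", "c"]

    def test_empty_summary_zeros(self):
        s = summarize(nx.Graph())
        assert s.n_edges == 0 and s.average_degree == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 25))
        g = nx.gnp_random_graph(n, 0.25, seed=seed)
        g = nx.relabel_nodes(g, {i: f"t{i:02d}" for i in range(n)})
        for u, v in g.edges:
            g.edges[u, v].update(rho=0.8, adjusted_p=0.001, sign=1, edge_class="BB")
        ref = brute_force_metrics(g)
        ours = node_metrics(g)
        for col in ("degree", "clustering", "closeness", "betweenness"):
            assert np.allclose(ours[col].loc[ref.index], ref[col], atol=1e-10), col
        if g.number_of_edges():
            s = summarize(g)
            comms = nx.community.greedy_modularity_communities(g)
            assert s.modularity == pytest.approx(brute_force_modularity(g, comms), abs=1e-10)
            assert s.modularity >= -1e-12  # at least as good as the one-block partition


class TestCompare:
    def _net(self, p_edge, seed, n=40):
        g = nx.gnp_random_graph(n, p_edge, seed=seed)
        g = nx.relabel_nodes(g, {i: f"t{i}" for i in range(n)})
        for u, v in g.edges:
            g.edges[u, v].update(rho=0.8, adjusted_p=0.001, sign=1, edge_class="BB")
        return g

    def test_self_comparison_null(self):
        g = self._net(0.2, 1)
        cmp = compare_networks(g, g)
        assert (cmp["difference"].abs() < 1e-12).all()
        assert cmp.loc["node_degree", "ranksum_p"] == pytest.approx(1.0)

    def test_dense_vs_sparse_detected(self):
        cmp = compare_networks(self._net(0.4, 2, n=100), self._net(0.08, 3, n=100))
        assert cmp.loc["node_degree", "ranksum_p"] < 0.01
        assert cmp.loc["node_degree", "difference"] > 0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            compare_networks(nx.Graph(), self._net(0.2, 1))


def test_edge_set_invariant_to_orderings(rng):
    counts = rng.integers(0, 80, size=(20, 24))
    counts[0] = counts[1] + rng.integers(0, 3, size=24)  # one correlated pair
    table = make_table(counts)
    g1 = network_from_table(table, rho_min=0.5, p_max=0.05)
    perm_taxa = rng.permutation(table.taxon_ids)
    perm_samples = list(rng.permutation(table.sample_ids))
    from phyllo.tables import FeatureTable

    shuffled = FeatureTable(
        table.counts.loc[perm_taxa, perm_samples], table.kingdom.loc[perm_taxa]
    )
    g2 = network_from_table(shuffled, rho_min=0.5, p_max=0.05)
    canon = lambda g: {tuple(sorted(e)) for e in g.edges}
    assert canon(g1) == canon(g2)
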