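"""Thresholded Spearman cooccurrence networks and their topology metrics.

Edges connect taxa whose pairwise Spearman rank correlation (across
samples, on relative abundances) satisfies |rho| > 0.6 with a
Benjamini-Hochberg-adjusted p < 0.01 — the robustness thresholds used
throughout the phyllosphere network literature this package targets.
Topology (clustering, closeness, betweenness, modularity) is computed on
the unweighted, unsigned skeleton; edge signs are kept only for the
positive/negative stability proportions.  Interkingdom networks carry a
BB/BF/FF class per edge.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .tables import FeatureTable

MODULARITY_ALGORITHM = "greedy_modularity (Clauset-Newman-Moore, deterministic)"


def spearman_matrix(relabund: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and two-sided p for a taxon x sample matrix.

    Rho uses rank transform with average ties; p is the t-approximation.
    Constant taxa (zero rank variance) get NaN rho/p and are excluded from
    any downstream edge.
    """
    if relabund.shape[1] < 5:
        raise ValidationError("Spearman networks need at least 5 samples")
    x = relabund.to_numpy()
    n = x.shape[1]
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    sd = ranks.std(axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / n
    denom = np.outer(sd, sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = cov / denom
    rho[(sd == 0), :] = np.nan
    rho[:, (sd == 0)] = np.nan
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, 0.0)
    idx = relabund.index
    return pd.DataFrame(rho, index=idx, columns=idx), pd.DataFrame(p, index=idx, columns=idx)


def _edge_class(k1: str, k2: str) -> str:
    code = {"bacteria": "B", "fungi": "F"}
    return "".join(sorted(code[k1] + code[k2]))


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    kingdom: pd.Series,
    rho_min: float = 0.6,
    p_max: float = 0.01,
    correction: str = "fdr_bh",
) -> nx.Graph:
    """Threshold the correlation matrix into an undirected cooccurrence graph.

    Keeps pairs with |rho| > ``rho_min`` and multiplicity-adjusted p <
    ``p_max`` (BH across all candidate pairs by default; ``correction=None``
    uses raw p).  Nodes are taxa with at least one retained edge, annotated
    with their kingdom; edges carry rho, adjusted p, sign, and BB/BF/FF
    class, canonically ordered by the input taxon order.
    """
    if not 0 <= rho_min < 1 or not 0 < p_max <= 1:
        raise ValidationError("rho_min must be in [0,1) and p_max in (0,1]")
    if not rho.index.equals(p.index) or not rho.columns.equals(p.columns):
        raise ValidationError("rho and p matrices are not aligned")
    taxa = list(rho.index)
    r = rho.to_numpy()
    pv = p.to_numpy()
    iu = np.triu_indices(len(taxa), 1)
    pairs_r = r[iu]
    pairs_p = pv[iu]
    valid = ~np.isnan(pairs_r)
    if correction is None:
        adj = pairs_p.copy()
    else:
        adj = np.full_like(pairs_p, np.nan)
        if valid.any():
            adj[valid] = multipletests(pairs_p[valid], method=correction)[1]
    keep = valid & (np.abs(pairs_r) > rho_min) & (adj < p_max)
    g = nx.Graph()
    g.graph["rho_min"] = rho_min
    g.graph["p_max"] = p_max
    g.graph["correction"] = correction or "raw"
    g.graph["modularity_algorithm"] = MODULARITY_ALGORITHM
    g.graph["taxon_order"] = {t: i for i, t in enumerate(taxa)}
    for a, b, rr, pp in zip(iu[0][keep], iu[1][keep], pairs_r[keep], adj[keep]):
        ti, tj = taxa[a], taxa[b]
        for t in (ti, tj):
            if t not in g:
                g.add_node(t, kingdom=kingdom[t])
        g.add_edge(
            ti, tj,
            rho=float(rr),
            adjusted_p=float(pp),
            sign=1 if rr > 0 else -1,
            edge_class=_edge_class(kingdom[ti], kingdom[tj]),
        )
    return g


def network_from_table(
    table: FeatureTable,
    rho_min: float = 0.6,
    p_max: float = 0.01,
    rare_min: float = 0.0001,
    correction: str = "fdr_bh",
) -> nx.Graph:
    """Rare-filter (<0.01 % mean relative abundance), correlate, threshold."""
    filtered = table.filter_rare(rare_min)
    rho, p = spearman_matrix(filtered.relative_abundance())
    return build_network(rho, p, filtered.kingdom, rho_min=rho_min, p_max=p_max, correction=correction)


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    average_degree: float
    average_clustering: float
    modularity: float
    proportion_positive: float
    proportion_negative: float
    edge_class_counts: dict = field(default_factory=dict)
    modularity_algorithm: str = MODULARITY_ALGORITHM


def summarize(g: nx.Graph) -> NetworkSummary:
    """Global topology and stability metrics of a cooccurrence network.

    Modularity is that of the best partition found by deterministic greedy
    modularity maximisation on the unweighted skeleton; stability is read
    from the positive/negative edge proportions (more negative edges and
    higher modularity indicating a more stable community).
    """
    n, e = g.number_of_nodes(), g.number_of_edges()
    if e == 0:
        return NetworkSummary(n, 0, 0.0, 0.0, 0.0, 0.0, 0.0, {})
    signs = [d["sign"] for _, _, d in g.edges(data=True)]
    classes = pd.Series([d.get("edge_class", "BB") for _, _, d in g.edges(data=True)])
    communities = nx.community.greedy_modularity_communities(g)
    q = nx.community.modularity(g, communities)
    return NetworkSummary(
        n_nodes=n,
        n_edges=e,
        average_degree=2.0 * e / n,
        average_clustering=float(nx.average_clustering(g)),
        modularity=float(q),
        proportion_positive=float(np.mean(np.array(signs) > 0)),
        proportion_negative=float(np.mean(np.array(signs) < 0)),
        edge_class_counts=classes.value_counts().to_dict(),
    )


def node_metrics(g: nx.Graph) -> pd.DataFrame:
    """Per-node degree, clustering, closeness, betweenness, and module id.

    Closeness is normalised within each connected component as
    (n_component - 1) / sum of shortest-path distances.
    """
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["kingdom", "degree", "clustering", "closeness", "betweenness", "module"])
    clustering = nx.clustering(g)
    closeness = nx.closeness_centrality(g, wf_improved=False)
    betweenness = nx.betweenness_centrality(g)
    communities = nx.community.greedy_modularity_communities(g) if g.number_of_edges() else []
    module = {}
    for m, comm in enumerate(communities):
        for node in comm:
            module[node] = m
    return pd.DataFrame(
        {
            "kingdom": {v: g.nodes[v].get("kingdom", "bacteria") for v in g},
            "degree": dict(g.degree()),
            "clustering": clustering,
            "closeness": closeness,
            "betweenness": betweenness,
            "module": {v: module.get(v, -1) for v in g},
        }
    ).sort_index()


def hubs(g: nx.Graph, k: int = 10) -> pd.DataFrame:
    """Top-k hub nodes ranked by degree, ties by closeness, then by ID."""
    metrics = node_metrics(g)
    # mergesort is stable; pre-sorting by ID gives the final deterministic tie-break
    ranked = metrics.sort_index().sort_values(
        by=["degree", "closeness"], ascending=[False, False], kind="mergesort"
    )
    return ranked.head(k)


def compare_networks(g_a: nx.Graph, g_b: nx.Graph) -> pd.DataFrame:
    """Compare two networks: summary deltas + rank-sum tests on node metrics.

    Returns one row per metric with the two values, their difference, and
    (for node-level degree and clustering distributions) a two-sided
    Wilcoxon rank-sum p-value.
    """
    if g_a.number_of_nodes() == 0 or g_b.number_of_nodes() == 0:
        raise ValidationError("cannot compare an empty network")
    sa, sb = summarize(g_a), summarize(g_b)
    ma, mb = node_metrics(g_a), node_metrics(g_b)
    rows = []
    for name in ("n_nodes", "n_edges", "average_degree", "average_clustering",
                 "modularity", "proportion_positive", "proportion_negative"):
        va, vb = getattr(sa, name), getattr(sb, name)
        rows.append((name, va, vb, va - vb, np.nan))
    for metric in ("degree", "clustering"):
        xa, xb = ma[metric].to_numpy(dtype=float), mb[metric].to_numpy(dtype=float)
        if np.ptp(np.concatenate([xa, xb])) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        rows.append((f"node_{metric}", float(xa.mean()), float(xb.mean()), float(xa.mean() - xb.mean()), p))
    return pd.DataFrame(rows, columns=["metric", "a", "b", "difference", "ranksum_p"]).set_index("metric")


def canonical_edges(g: nx.Graph) -> list[tuple[str, str]]:
    """Edges oriented and sorted by the original taxon order (i < j)."""
    order = g.graph.get("taxon_order", {})
    key = lambda t: order.get(t, t)
    edges = [tuple(sorted(e, key=key)) for e in g.edges]
    return sorted(edges, key=lambda e: (key(e[0]), key(e[1])))


def write_edge_list(g: nx.Graph, path) -> None:
    rows = [
        (u, v, g.edges[u, v]["rho"], g.edges[u, v]["adjusted_p"],
         g.edges[u, v]["sign"], g.edges[u, v]["edge_class"])
        for u, v in canonical_edges(g)
    ]
    pd.DataFrame(rows, columns=["source", "target", "rho", "adjusted_p", "sign", "class"]).to_csv(
        path, sep="\t", index=False
    )


def write_node_table(g: nx.Graph, path) -> None:
    metrics = node_metrics(g)
    metrics.index.name = "id"
    metrics.to_csv(path, sep="\t")


def write_gexf(g: nx.Graph, path) -> None:
    """Graph exchange export for external layout tools (e.g. Gephi)."""
    nx.write_gexf(g, path)
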