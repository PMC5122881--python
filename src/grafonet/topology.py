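"""Topological analysis of inferred networks.

Centralities, components, path statistics, the small-world index of
Humphries & Gurney, and the weighted-network view of the stability table.
Module detection lives in :mod:`grafonet.community`.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import GrafonetError, MixedGraph, StabilityTable


@dataclass
class TopologySummary:
    """Per-node and graph-level topology statistics."""

    per_node: pd.DataFrame  # columns: degree, clustering, betweenness
    mean_degree: float
    mean_clustering: float
    mean_shortest_path: float | None
    small_world_index: float | None


def connected_components(graph: MixedGraph) -> list[set[str]]:
    """Components sorted by size (desc), ties by smallest node name."""
    comps = [set(c) for c in nx.connected_components(graph.g)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def node_centralities(graph: MixedGraph) -> pd.DataFrame:
    """Degree, local clustering and betweenness for every node.

    Local clustering of nodes with degree < 2 is 0.  Betweenness is computed
    and normalized within each connected component (division by
    (n-1)(n-2)/2 for component size n), counting multiple shortest paths
    fractionally, so values are comparable to the fraction of shortest paths
    a node sits on inside its component.
    """
    g = graph.g
    nodes = sorted(g.nodes)
    degree = {n: g.degree(n) for n in nodes}
    clustering = nx.clustering(g)
    betweenness: dict[str, float] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        betweenness.update(nx.betweenness_centrality(sub, normalized=len(comp) > 2))
    return pd.DataFrame(
        {
            "degree": [degree[n] for n in nodes],
            "clustering": [clustering[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
        },
        index=nodes,
    )


def average_shortest_path(graph: MixedGraph, scope: str = "largest_component") -> float:
    """Mean shortest-path length over unordered node pairs.

    ``largest_component`` restricts to the biggest component; the
    ``per_component`` scope pools all intra-component pairs (pairs in
    different components never contribute).
    """
    if scope not in ("largest_component", "per_component"):
        raise GrafonetError(f"unknown scope {scope!r}")
    if graph.n_edges == 0:
        raise GrafonetError("average shortest path undefined on an edgeless graph")
    comps = connected_components(graph)
    if scope == "largest_component":
        comps = comps[:1]
    total, npairs = 0.0, 0
    for comp in comps:
        if len(comp) < 2:
            continue
        sub = graph.g.subgraph(comp)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
        npairs += len(comp) * (len(comp) - 1)
    if npairs == 0:
        raise GrafonetError("no connected pairs in scope")
    return total / npairs  # each unordered pair counted twice in both sums


def node_average_distance(graph: MixedGraph, node: str) -> float:
    """Mean distance from one node to all other nodes of its component
    (the per-node 'average shortest path length'); self-distance excluded."""
    if node not in graph.g:
        raise GrafonetError(f"unknown node {node!r}")
    lengths = nx.single_source_shortest_path_length(graph.g, node)
    del lengths[node]
    if not lengths:
        raise GrafonetError(f"node {node!r} is isolated")
    return float(np.mean(list(lengths.values())))


def small_world_index(graph: MixedGraph, mode: str = "analytic",
                      n_random: int = 50, seed: int = 0) -> float:
    """Small-world index S = (C/C_rand) / (L/L_rand).

    C is the mean local clustering coefficient and L the average shortest
    path length of the graph; C_rand and L_rand are Erdos-Renyi expectations
    for the same size and mean degree: analytically C_rand = k/n and
    L_rand = ln(n)/ln(k), or Monte-Carlo averages over ``n_random`` sampled
    G(n, M) graphs.  Requires a connected graph with mean degree > 1.
    """
    g = graph.g
    n = g.number_of_nodes()
    if n < 3 or not nx.is_connected(g):
        raise GrafonetError(
            "small_world_index needs a connected graph; pass the largest component")
    k = 2 * g.number_of_edges() / n
    if k <= 1:
        raise GrafonetError("mean degree must exceed 1")
    C = nx.average_clustering(g)
    L = average_shortest_path(graph)
    if mode == "analytic":
        c_rand = k / n
        l_rand = np.log(n) / np.log(k)
    elif mode == "montecarlo":
        rng = np.random.default_rng(seed)
        cs, ls = [], []
        m = g.number_of_edges()
        while len(cs) < n_random:
            r = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
            if not nx.is_connected(r):
                continue
            cs.append(nx.average_clustering(r))
            ls.append(nx.average_shortest_path_length(r))
        c_rand, l_rand = float(np.mean(cs)), float(np.mean(ls))
    else:
        raise GrafonetError(f"unknown mode {mode!r}")
    return (C / c_rand) / (L / l_rand)


def mediation_fraction(graph: MixedGraph, node: str,
                       include_adjacent: bool = True) -> float:
    """Fraction of all shortest paths that pass through ``node``.

    Multiple shortest paths between a pair count fractionally.  The
    denominator is the number of connected unordered pairs; with
    ``include_adjacent=False`` only pairs at distance >= 2 count.
    """
    if node not in graph.g:
        raise GrafonetError(f"unknown node {node!r}")
    raw = 0.0
    denom = 0
    for comp in nx.connected_components(graph.g):
        sub = graph.g.subgraph(comp)
        nsub = len(comp)
        if node in comp:
            raw = nx.betweenness_centrality(sub, normalized=False)[node]
        if include_adjacent:
            denom += nsub * (nsub - 1) // 2
        else:
            denom += nsub * (nsub - 1) // 2 - sub.number_of_edges()
    if denom == 0:
        raise GrafonetError("no eligible pairs")
    return raw / denom


def topology_summary(graph: MixedGraph) -> TopologySummary:
    """Per-node table plus the paper-style graph-level statistics.

    Path-based statistics (mean shortest path, small-world index) are
    computed on the largest connected component and are None for graphs
    without edges.
    """
    per_node = node_centralities(graph)
    n, e = graph.n_nodes, graph.n_edges
    mean_degree = 2 * e / n if n else 0.0
    mean_clustering = float(per_node["clustering"].mean()) if n else 0.0
    msp = swi = None
    if e > 0:
        comps = connected_components(graph)
        largest = graph.subgraph(sorted(comps[0]))
        if largest.n_nodes >= 3:
            msp = average_shortest_path(largest)
            k = 2 * largest.n_edges / largest.n_nodes
            if k > 1:
                swi = small_world_index(largest)
    return TopologySummary(per_node, mean_degree, mean_clustering, msp, swi)


def weighted_graph(table: StabilityTable) -> MixedGraph:
    """Graph with every ever-selected pair as an edge weighted by frequency."""
    g = nx.Graph()
    for (u, v), f in sorted(table.frequencies().items()):
        if f > 0:
            g.add_edge(u, v, frequency=f, weight=f)
    return MixedGraph(g)
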