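"""Modularity-based module detection.

Three methods:

* ``exact`` — provably modularity-maximal partition by branch and bound over
  the clique-partitioning formulation.  Modularity is additive over pairs of
  co-clustered node groups (merging groups i and j changes Q by exactly
  dQ_ij = 2(e_ij - a_i a_j)), so the best achievable score from any state is
  bounded by the current Q plus all positive pairwise gains; branching
  either merges the currently best pair or forbids it.  A greedy
  agglomeration provides the incumbent.  Practical up to a few dozen nodes.
* ``greedy`` — deterministic Clauset-Newman-Moore agglomeration (networkx).
* ``spinglass`` — seeded stochastic optimization (python-igraph), applied
  per connected component.

Modules of singleton components are always singletons.
"""

from __future__ import annotations

import random

import networkx as nx
import numpy as np

from .datatypes import GrafonetError, MixedGraph, ModulePartition

EXACT_NODE_LIMIT = 120


def modularity(graph: MixedGraph, assignment: dict[str, int]) -> float:
    """Newman modularity of a node -> module assignment (0 for an edgeless
    graph, where the score is degenerate)."""
    if graph.g.number_of_edges() == 0:
        return 0.0
    groups: dict[int, set[str]] = {}
    for node, m in assignment.items():
        groups.setdefault(m, set()).add(node)
    return nx.community.modularity(graph.g, list(groups.values()))


def _canonical(graph: MixedGraph, groups: list[set[str]]) -> ModulePartition:
    groups = sorted(groups, key=lambda c: (-len(c), min(c)))
    assignment = {n: i for i, c in enumerate(groups) for n in c}
    return ModulePartition(assignment=assignment, modularity=modularity(graph, assignment))


def detect_modules(graph: MixedGraph, method: str = "greedy", seed: int = 0) -> ModulePartition:
    """Partition the nodes into modules maximizing modularity."""
    g = graph.g
    if g.number_of_edges() == 0:
        return _canonical(graph, [{n} for n in g.nodes])
    if method == "greedy":
        groups = [set(c) for c in nx.community.greedy_modularity_communities(g)]
    elif method == "exact":
        if g.number_of_nodes() > EXACT_NODE_LIMIT:
            raise GrafonetError(
                f"exact modularity is limited to {EXACT_NODE_LIMIT} nodes; "
                "use method='greedy' or 'spinglass'")
        groups = _exact_groups(g)
    elif method == "spinglass":
        groups = _spinglass_groups(g, seed)
    else:
        raise GrafonetError(f"unknown module detection method {method!r}")
    return _canonical(graph, groups)


def _spinglass_groups(g: nx.Graph, seed: int) -> list[set[str]]:
    import igraph

    groups: list[set[str]] = []
    state = random.getstate()
    try:
        random.seed(seed)
        for comp in nx.connected_components(g):
            comp = sorted(comp)
            if len(comp) == 1:
                groups.append(set(comp))
                continue
            sub = g.subgraph(comp)
            ig = igraph.Graph()
            ig.add_vertices(comp)
            ig.add_edges([(u, v) for u, v in sub.edges])
            clustering = ig.community_spinglass()
            for cluster in clustering:
                groups.append({comp[i] for i in cluster})
    finally:
        random.setstate(state)
    return groups


# -- exact branch and bound -------------------------------------------------


def _exact_groups(g: nx.Graph) -> list[set[str]]:
    """Exact maximum-modularity partition.

    Optimal modules never span components (cross-component merges have
    strictly negative gain), so each component is solved separately — but
    with gains computed against the *global* edge count, since modularity is
    defined on the whole graph.
    """
    m_total = g.number_of_edges()
    groups: list[set[str]] = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        if len(comp) <= 2:
            # within a 1-2 node component, one module is always optimal
            groups.append(set(comp))
            continue
        groups.extend(_exact_component(g.subgraph(comp), m_total))
    return groups


def _pair_gains(g: nx.Graph, nodes: list[str], m: int) -> tuple[np.ndarray, float]:
    """Pairwise merge gains dQ_ij for singleton clusters, and the clusters'
    base contribution to modularity; ``m`` is the global edge count."""
    idx = {n: i for i, n in enumerate(nodes)}
    k = len(nodes)
    a = np.array([g.degree(n) / (2 * m) for n in nodes])
    e = np.zeros((k, k))
    for u, v in g.edges:
        e[idx[u], idx[v]] += 1 / m
    e = (e + e.T) / 2  # e_ij symmetric, each edge contributing 1/m in total
    gains = 2 * (e - np.outer(a, a))
    np.fill_diagonal(gains, 0.0)
    base = float(-np.sum(a**2))  # all-singleton contribution (no self loops)
    return gains, base


def _greedy_value(gains: np.ndarray, forbidden: np.ndarray, q: float) -> tuple[float, list[list[int]]]:
    """Greedy best-merge agglomeration used for the incumbent solution."""
    gains = gains.copy()
    forbidden = forbidden.copy()
    clusters: list[list[int] | None] = [[i] for i in range(len(gains))]
    while True:
        masked = np.where(forbidden, -np.inf, gains)
        np.fill_diagonal(masked, -np.inf)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= 0:
            break
        q += gains[i, j]
        gains[i] += gains[j]
        gains[:, i] += gains[:, j]
        forbidden[i] |= forbidden[j]
        forbidden[:, i] |= forbidden[:, j]
        gains[j] = gains[:, j] = -np.inf
        clusters[i] = clusters[i] + clusters[j]  # type: ignore[operator]
        clusters[j] = None
    return q, [c for c in clusters if c is not None]


def _exact_component(g: nx.Graph, m_total: int) -> list[set[str]]:
    nodes = sorted(g.nodes)
    gains0, base = _pair_gains(g, nodes, m_total)
    k = len(nodes)
    forbidden0 = np.zeros((k, k), dtype=bool)
    best_q, best_clusters = _greedy_value(gains0, forbidden0, base)

    # search state: active clusters as frozensets of node indices
    def recurse(gains: np.ndarray, forbidden: np.ndarray,
                clusters: list[list[int] | None], q: float) -> None:
        nonlocal best_q, best_clusters
        active = [i for i, c in enumerate(clusters) if c is not None]
        pos = 0.0
        best_pair = None
        best_gain = 0.0
        for ii, i in enumerate(active):
            for j in active[ii + 1:]:
                if forbidden[i, j]:
                    continue
                gval = gains[i, j]
                if gval > 0:
                    pos += gval
                    if gval > best_gain:
                        best_gain, best_pair = gval, (i, j)
        if q + pos <= best_q + 1e-12:
            if best_pair is None and q > best_q:
                best_q = q
                best_clusters = [list(c) for c in clusters if c is not None]
            return
        if best_pair is None:
            if q > best_q:
                best_q = q
                best_clusters = [list(c) for c in clusters if c is not None]
            return
        i, j = best_pair
        # branch 1: merge clusters i and j
        g2 = gains.copy()
        f2 = forbidden.copy()
        c2: list[list[int] | None] = [list(c) if c is not None else None for c in clusters]
        g2[i] += g2[j]
        g2[:, i] += g2[:, j]
        f2[i] |= f2[j]
        f2[:, i] |= f2[:, j]
        c2[i] = c2[i] + c2[j]  # type: ignore[operator]
        c2[j] = None
        recurse(g2, f2, c2, q + gains[i, j])
        # branch 2: forbid i and j from sharing a module
        f3 = forbidden.copy()
        f3[i, j] = f3[j, i] = True
        recurse(gains, f3, clusters, q)

    recurse(gains0, forbidden0, [[i] for i in range(k)], base)
    return [set(nodes[i] for i in c) for c in best_clusters]


def brute_force_modules(graph: MixedGraph) -> ModulePartition:
    """Exhaustive search over all set partitions (testing oracle, <= ~10 nodes)."""
    nodes = sorted(graph.g.nodes)
    if len(nodes) > 10:
        raise GrafonetError("brute force limited to 10 nodes")
    best: tuple[float, list[set[str]]] | None = None
    for part in _set_partitions(nodes):
        assignment = {n: i for i, c in enumerate(part) for n in c}
        q = modularity(graph, assignment)
        if best is None or q > best[0] + 1e-15:
            best = (q, [set(c) for c in part])
    assert best is not None
    return _canonical(graph, best[1])


def _set_partitions(items: list[str]):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in _set_partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [[first] + sub[i]] + sub[i + 1:]
        yield [[first]] + sub
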