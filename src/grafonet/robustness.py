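"""Stability analyses of an inferred network.

Covers the edge-cutoff sweep (20%...100% of subsamples), centrality
correlations against the reference model, adjusted Rand comparison of module
assignments with a random background, split-half (twin-wise) model
replication, and node-restricted comparison against an enlarged model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import adjusted_rand_score

from .community import detect_modules
from .datatypes import (
    GrafonetError,
    MixedDataset,
    MixedGraph,
    ModulePartition,
    StabilityTable,
)
from .inference import InferenceConfig, infer_mgm, threshold_edges
from .topology import node_centralities

DEFAULT_CUTOFFS = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class StabilityReport:
    cutoff_stats: dict[float, dict] = field(default_factory=dict)
    background_ari: list[float] = field(default_factory=list)
    split_overlap: float | None = None
    unique_to_reference: int | None = None


def cutoff_sweep(table: StabilityTable,
                 cutoffs: Sequence[float] = DEFAULT_CUTOFFS) -> dict[float, MixedGraph]:
    """Graphs at each edge-inclusion cutoff.

    Cutoffs below 1.0 use the strict 'more than' rule of the main model; the
    100% cutoff is non-strict so that always-selected edges survive.
    """
    out: dict[float, MixedGraph] = {}
    for c in cutoffs:
        if not 0.0 < c <= 1.0:
            raise GrafonetError(f"cutoff {c} outside (0, 1]")
        edges = threshold_edges(table, c, strict=c < 1.0)
        g = MixedGraph.from_nodes_edges(
            sorted({n for e in table.counts for n in e}),
            [(u, v, {"frequency": table.frequency(u, v)}) for u, v in sorted(edges)],
        )
        out[c] = g
    return out


def centrality_correlation(graph_a: MixedGraph, graph_b: MixedGraph,
                           method: str = "spearman") -> tuple[float, float]:
    """Correlation of node degrees and clustering coefficients over the
    shared node universe (rank correlation by default)."""
    shared = sorted(set(graph_a.g.nodes) & set(graph_b.g.nodes))
    if len(shared) < 3:
        raise GrafonetError("need at least 3 shared nodes")
    ca = node_centralities(graph_a).loc[shared]
    cb = node_centralities(graph_b).loc[shared]
    corr = spearmanr if method == "spearman" else pearsonr
    if method not in ("spearman", "pearson"):
        raise GrafonetError(f"unknown correlation method {method!r}")

    def _corr(x, y) -> float:
        if np.std(x) == 0 or np.std(y) == 0:
            return 1.0 if np.allclose(x, y) else float("nan")
        return float(corr(x, y)[0])

    return (
        _corr(ca["degree"].to_numpy(), cb["degree"].to_numpy()),
        _corr(ca["clustering"].to_numpy(), cb["clustering"].to_numpy()),
    )


def adjusted_rand_index(p1: ModulePartition, p2: ModulePartition) -> float:
    """Chance-corrected pair-counting agreement of two module assignments
    over the same node set (1 = identical up to relabeling, ~0 = random)."""
    if set(p1.assignment) != set(p2.assignment):
        raise GrafonetError("partitions are over different node sets")
    nodes = sorted(p1.assignment)
    return float(adjusted_rand_score(p1.labels(nodes), p2.labels(nodes)))


def ari_background(reference: ModulePartition, n_draws: int = 1000,
                   seed: int = 0, size_preserving: bool = True) -> list[float]:
    """ARI of randomly drawn module assignments against the reference.

    By default each draw permutes the node labels, preserving the reference
    module sizes (the stricter null); ``size_preserving=False`` draws module
    labels uniformly instead.
    """
    if n_draws < 1:
        raise GrafonetError("n_draws must be >= 1")
    nodes = sorted(reference.assignment)
    labels = np.array(reference.labels(nodes))
    k = len(set(labels))
    if k == 1:
        warnings.warn("single-module reference: background ARI is degenerate (1.0)",
                      stacklevel=2)
        return [1.0] * n_draws
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_draws):
        if size_preserving:
            drawn = rng.permutation(labels)
        else:
            drawn = rng.integers(0, k, size=len(labels))
        out.append(float(adjusted_rand_score(labels, drawn)))
    return out


def split_half_datasets(dataset: MixedDataset, seed: int) -> tuple[MixedDataset, MixedDataset]:
    """Split a twin cohort into two disjoint halves, one twin per family.

    The first/second member of each two-person family (in row order) go to
    the first/second half; singletons are distributed randomly by ``seed``.
    Families with more than two members violate the twin-pair assumption.
    """
    members: dict[str, list[str]] = {}
    for sid, fam in dataset.family_ids.items():
        members.setdefault(fam, []).append(sid)
    oversized = {f: m for f, m in members.items() if len(m) > 2}
    if oversized:
        raise GrafonetError(f"families with more than 2 members: {sorted(oversized)}")
    rng = np.random.default_rng(seed)
    first: list[str] = []
    second: list[str] = []
    for fam in members.values():
        if len(fam) == 2:
            first.append(fam[0])
            second.append(fam[1])
        else:
            (first if rng.random() < 0.5 else second).append(fam[0])
    order = {s: i for i, s in enumerate(dataset.sample_ids)}
    first.sort(key=order.get)
    second.sort(key=order.get)
    return dataset.subset_samples(first), dataset.subset_samples(second)


def split_half_models(
    dataset: MixedDataset,
    config: InferenceConfig,
    reference: MixedGraph,
    seed: int,
) -> tuple[MixedGraph, MixedGraph, float, int]:
    """Re-infer the network on the two twin halves and score reproduction.

    Returns the two split models, the fraction of reference edges present in
    the union of the two split models (``split_overlap``), and the number of
    reference edges found in neither (``unique_to_reference``).
    """
    ds1, ds2 = split_half_datasets(dataset, seed)
    from dataclasses import replace

    g1, _ = infer_mgm(ds1, replace(config, seed=config.seed * 2 + 1))
    g2, _ = infer_mgm(ds2, replace(config, seed=config.seed * 2 + 2))
    ref_edges = reference.edge_set()
    if not ref_edges:
        raise GrafonetError("reference graph has no edges")
    union = g1.edge_set() | g2.edge_set()
    reproduced = ref_edges & union
    overlap = len(reproduced) / len(ref_edges)
    return g1, g2, overlap, len(ref_edges) - len(reproduced)


def restrict_and_compare(
    large_graph: MixedGraph,
    node_subset: Sequence[str],
    reference_partition: ModulePartition,
    seed: int = 0,
    method: str = "greedy",
) -> tuple[MixedGraph, float]:
    """Induced subgraph of an enlarged model on the reference's nodes, with
    modules re-detected on it and compared to the reference by ARI."""
    sub = large_graph.subgraph(list(node_subset))
    part = detect_modules(sub, method=method, seed=seed)
    ref = {n: m for n, m in reference_partition.assignment.items() if n in set(node_subset)}
    if set(ref) != set(part.assignment):
        raise GrafonetError("reference partition does not cover the node subset")
    ari = float(adjusted_rand_score(
        [ref[n] for n in sorted(ref)],
        [part.assignment[n] for n in sorted(ref)],
    ))
    return sub, ari


def stability_report(
    table: StabilityTable,
    reference: MixedGraph,
    reference_partition: ModulePartition,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    n_draws: int = 1000,
    seed: int = 0,
    module_method: str = "greedy",
) -> StabilityReport:
    """Cutoff sweep with centrality correlations and module ARIs, plus the
    random-assignment ARI background."""
    report = StabilityReport()
    sweep = cutoff_sweep(table, cutoffs)
    for c, g in sweep.items():
        stats: dict = {"n_edges": g.n_edges, "n_nodes": g.n_nodes}
        try:
            dc, cc = centrality_correlation(reference, g)
            stats["degree_correlation"] = dc
            stats["clustering_correlation"] = cc
        except GrafonetError:
            stats["degree_correlation"] = stats["clustering_correlation"] = float("nan")
        shared = sorted(set(g.g.nodes) & set(reference_partition.assignment))
        if shared:
            part = detect_modules(g.subgraph(shared), method=module_method, seed=seed)
            ref_labels = [reference_partition.assignment[n] for n in shared]
            stats["ari_vs_reference"] = float(
                adjusted_rand_score(ref_labels, [part.assignment[n] for n in shared]))
        report.cutoff_stats[c] = stats
    report.background_ari = ari_background(reference_partition, n_draws=n_draws, seed=seed)
    return report
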