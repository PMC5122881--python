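"""Reproducible simulation studies of the inference procedure.

Two canonical studies, used by the analysis drivers, the test suite and the
acceptance script:

* :func:`null_fwer_study` — empirical family-wise error rate of the full
  procedure under a global null (independent inverse-normalized variables):
  the fraction of replicate datasets on which the final model contains at
  least one (necessarily false) edge.  Run at p = 20, n = 200, B = 50 with
  the default error-bound q rule and threshold 0.8.
* :func:`recovery_study` — structure recovery on latent-Gaussian
  modular-block data (p = 18 continuous variables, three ring blocks joined
  by bridges, partial correlation 0.6, n = 600, B = 50): edge-recovery
  precision/recall/F1 against the generating graph, module recovery
  (adjusted Rand index of detected modules vs the true blocks) and twin
  split-half reproduction (fraction of reference edges re-found in the
  union of the two one-twin-per-family models).

Problem sizes are chosen so each study runs on a single CPU in minutes; the
forest profile is the LightGBM simulation profile (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import detect_modules
from .datatypes import MixedDataset, VariableSpec
from .inference import InferenceConfig, infer_mgm, stable_seed
from .preprocess import transform_continuous
from .robustness import split_half_models
from .simulate import SimulationConfig, make_truth_graph, recovery_metrics, simulate_mixed

NULL_P = 20
NULL_N = 200
NULL_B = 50

RECOVERY = SimulationConfig(
    n_samples=600, n_continuous=18, n_binary=0, structure="modular_blocks",
    edge_strength=0.6, n_blocks=3, missing_rate=0.0, n_families=200, seed=0)

MIXED_RECOVERY = SimulationConfig(
    n_samples=600, n_continuous=14, n_binary=4, structure="modular_blocks",
    edge_strength=0.6, n_blocks=3, missing_rate=0.0, n_families=200, seed=0)


def null_dataset(n: int, p: int, seed: int) -> MixedDataset:
    """p mutually independent standard-normal variables, inverse normalized."""
    rng = np.random.default_rng(seed)
    names = [f"v{i + 1:02d}" for i in range(p)]
    values = pd.DataFrame(rng.standard_normal((n, p)), columns=names,
                          index=[f"s{i + 1:04d}" for i in range(n)])
    specs = [VariableSpec(c, "continuous", "phenotype") for c in names]
    ds = MixedDataset(values, specs, pd.Series([f"f{i}" for i in range(n)],
                                               index=values.index))
    return transform_continuous(ds)


def null_fwer_config(seed: int, B: int = NULL_B) -> InferenceConfig:
    """Inference settings of the null study: default q rule, threshold 0.8,
    50-tree simulation forests (ranking quality is irrelevant under the
    null; the selection threshold does the error control)."""
    return InferenceConfig.simulation(seed=seed, B=B, rf_trees=50)


def null_fwer_study(n_replicates: int = 40, seed: int = 0,
                    n: int = NULL_N, p: int = NULL_P, B: int = NULL_B,
                    progress=None) -> dict:
    """Empirical FWER of the full inference pipeline under the global null."""
    hits = 0
    per_replicate = []
    for r in range(1, n_replicates + 1):
        ds = null_dataset(n, p, seed=stable_seed("null-data", seed, r))
        cfg = null_fwer_config(seed=stable_seed("null-infer", seed, r), B=B)
        graph, table = infer_mgm(ds, cfg)
        freqs = table.frequencies()
        per_replicate.append({
            "n_edges": graph.n_edges,
            "max_frequency": max(freqs.values()) if freqs else 0.0,
        })
        hits += int(graph.n_edges > 0)
        if progress is not None:
            progress(r, n_replicates, per_replicate[-1])
    return {
        "fwer": hits / n_replicates,
        "n_replicates": n_replicates,
        "replicates_with_edges": hits,
        "per_replicate": per_replicate,
        "n": n, "p": p, "B": B, "threshold": 0.8,
    }


@dataclass
class RecoveryResult:
    precision: float
    recall: float
    f1: float
    module_ari: float
    n_modules: int
    split_overlap: float
    unique_to_reference: int
    n_edges_inferred: int
    n_edges_true: int


def recovery_study(seed: int = 0, sim: SimulationConfig | None = None,
                   with_split_half: bool = True) -> RecoveryResult:
    """Edge/module/split-half recovery on modular-block synthetic data.

    q is set to the true edge count (the sparsity a simulation study grants
    the method); everything else uses the simulation profile.
    """
    sim = sim if sim is not None else RECOVERY
    sim = SimulationConfig(**{**sim.__dict__, "seed": stable_seed("recovery-data", seed)})
    truth = make_truth_graph(sim)
    dataset = simulate_mixed(truth, sim)
    from .preprocess import preprocess

    clean, _ = preprocess(dataset, add_family=False)
    cfg = InferenceConfig.simulation(seed=stable_seed("recovery-infer", seed),
                                     B=50, q=len(truth.edges))
    graph, _ = infer_mgm(clean, cfg)
    precision, recall, f1 = recovery_metrics(graph.edge_set(), truth)

    blocks = truth.block_labels() or {}
    partition = detect_modules(graph, method="greedy")
    if blocks:
        from sklearn.metrics import adjusted_rand_score

        nodes = sorted(blocks)
        module_ari = float(adjusted_rand_score(
            [blocks[n] for n in nodes], [partition.assignment[n] for n in nodes]))
    else:
        module_ari = float("nan")

    overlap, unique = float("nan"), -1
    if with_split_half:
        _, _, overlap, unique = split_half_models(
            clean, cfg, graph, seed=stable_seed("recovery-split", seed))
    return RecoveryResult(
        precision=precision, recall=recall, f1=f1,
        module_ari=module_ari, n_modules=partition.n_modules,
        split_overlap=overlap, unique_to_reference=unique,
        n_edges_inferred=graph.n_edges, n_edges_true=len(truth.edges),
    )
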