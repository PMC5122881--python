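"""Mixed graphical model inference via graphical random forests and
complementary-pairs stability selection (CPSS).

For every variable a random forest predicts it from all other variables; the
forest's variable importances rank the candidate neighbours.  Each unordered
pair gets two directional ranks (x predicting y, y predicting x) and the
worse (maximum) of the two is the pair's rank.  The best-ranking ``q`` pairs
form one subsample model.  This is repeated on B random half-samples and
their complements; pairs kept in more than a fraction ``tau`` of the 2B
half-sample models become edges of the final network, which controls the
family-wise error rate of false edges.

Edge signs are estimated afterwards from full regression models (linear for
continuous targets, logistic for binary ones) purely for interpretation;
forests themselves carry no sign.
"""

from __future__ import annotations

import hashlib
import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import (
    GrafonetError,
    MixedDataset,
    MixedGraph,
    StabilityTable,
    pair_key,
)

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def stable_seed(*parts) -> int:
    """Deterministic sub-seed below 2^31, keyed by names not indices."""
    h = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass(frozen=True)
class InferenceConfig:
    """Knobs of the network inference stage.

    ``q`` is the number of pairs each half-sample model keeps; ``None``
    invokes the stability-selection bound q = floor(sqrt(alpha*(2*tau-1)*P))
    with alpha = 0.05 and P the number of candidate pairs, which guarantees
    an expected number of falsely selected edges below alpha.
    """

    B: int = 100
    q: int | None = None
    threshold: float = 0.8
    rf_trees: int = 500
    rf_importance: str = "permutation"  # sklearn backend: permutation | impurity
    backend: str = "sklearn"  # sklearn | lightgbm
    rf_leaves: int = 31  # lightgbm backend only
    min_samples_leaf: int = 1
    fwer_alpha: float = 0.05
    both_halves: bool = False  # CPSS variant: count pairs selected in both halves
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise GrafonetError("B must be >= 1")
        if not 0.5 < self.threshold <= 1.0:
            raise GrafonetError("threshold must lie in (0.5, 1]")
        if self.q is not None and self.q < 1:
            raise GrafonetError("q must be >= 1")
        if self.backend not in ("sklearn", "lightgbm"):
            raise GrafonetError(f"unknown backend {self.backend!r}")
        if self.rf_importance not in ("permutation", "impurity"):
            raise GrafonetError(f"unknown importance type {self.rf_importance!r}")

    @classmethod
    def simulation(cls, seed: int = 0, B: int = 50, **overrides) -> "InferenceConfig":
        """The scaled profile used for simulation studies: LightGBM forest
        backend, 100 trees, 8-leaf trees.  See docs/methods.md."""
        base = cls(B=B, backend="lightgbm", rf_trees=100, rf_leaves=8,
                   min_samples_leaf=5, seed=seed)
        return replace(base, **overrides)


def default_q(n_pairs: int, threshold: float, alpha: float = 0.05) -> int:
    """Largest per-model selection size still satisfying the CPSS error bound
    E[false selections] <= q^2 / ((2*tau - 1) * P) <= alpha."""
    return max(1, math.floor(math.sqrt(alpha * (2 * threshold - 1) * n_pairs)))


@dataclass(frozen=True)
class SubsamplePlan:
    """B complementary pairs of half-sample id sets (2B subsets in total)."""

    pairs: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    seed: int

    def subsets(self) -> list[tuple[str, ...]]:
        out = []
        for a, b in self.pairs:
            out.extend([a, b])
        return out


def make_subsample_plan(sample_ids: Sequence[str] | int, B: int, seed: int) -> SubsamplePlan:
    """Split the samples into B random half/complement pairs.

    Sample ids (or 0..n-1 when an integer is given) are shuffled in sorted
    order so the plan is invariant to the row order of the input table.
    Half sizes are floor(n/2) and ceil(n/2).
    """
    if isinstance(sample_ids, int):
        sample_ids = [str(i) for i in range(sample_ids)]
    ids = sorted(str(s) for s in sample_ids)
    n = len(ids)
    if n < 4:
        raise GrafonetError("need at least 4 samples for complementary pairs")
    if B < 1:
        raise GrafonetError("B must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = []
    half = n // 2
    for _ in range(B):
        perm = rng.permutation(n)
        first = tuple(ids[i] for i in sorted(perm[:half]))
        second = tuple(ids[i] for i in sorted(perm[half:]))
        pairs.append((first, second))
    return SubsamplePlan(pairs=tuple(pairs), seed=seed)


# -- forests ---------------------------------------------------------------


def _lightgbm_importance(X: np.ndarray, y: np.ndarray, kind: str,
                         cfg: InferenceConfig, seed: int) -> np.ndarray:
    import lightgbm as lgb

    p = X.shape[1]
    if kind == "continuous":
        objective = {"objective": "regression"}
        frac = math.ceil(p / 3) / p
    else:
        classes = np.unique(y)
        if len(classes) > 2:
            objective = {"objective": "multiclass", "num_class": int(y.max()) + 1}
        else:
            objective = {"objective": "binary"}
        frac = math.ceil(math.sqrt(p)) / p
    params = {
        **objective,
        "boosting_type": "rf",
        "bagging_freq": 1,
        "bagging_fraction": 0.632,
        "feature_fraction_bynode": min(1.0, frac),
        "num_leaves": cfg.rf_leaves,
        "min_data_in_leaf": cfg.min_samples_leaf,
        "verbosity": -1,
        "num_threads": 1,
        "seed": seed,
        "deterministic": True,
    }
    data = lgb.Dataset(X, label=y, params={"verbosity": -1, "min_data_in_bin": 1})
    booster = lgb.train(params, data, num_boost_round=cfg.rf_trees,
                        keep_training_booster=True)
    return booster.feature_importance(importance_type="gain").astype(float)


def _sklearn_importance(X: np.ndarray, y: np.ndarray, kind: str,
                        cfg: InferenceConfig, seed: int) -> np.ndarray:
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
    from sklearn.inspection import permutation_importance

    p = X.shape[1]
    if kind == "continuous":
        model = RandomForestRegressor(
            n_estimators=cfg.rf_trees, max_features=max(1, math.ceil(p / 3)),
            min_samples_leaf=cfg.min_samples_leaf, random_state=seed, n_jobs=1)
    else:
        model = RandomForestClassifier(
            n_estimators=cfg.rf_trees, max_features=max(1, math.ceil(math.sqrt(p))),
            min_samples_leaf=cfg.min_samples_leaf, random_state=seed, n_jobs=1)
        y = y.astype(int)
    model.fit(X, y)
    if cfg.rf_importance == "impurity":
        return model.feature_importances_
    res = permutation_importance(model, X, y, n_repeats=5, random_state=seed, n_jobs=1)
    return res.importances_mean


def target_importance(X: np.ndarray, y: np.ndarray, kind: str,
                      cfg: InferenceConfig, seed: int) -> np.ndarray:
    """Importance of each column of X for predicting y (one forest)."""
    if kind != "continuous" and len(np.unique(y)) < 2:
        raise GrafonetError("single-class target")
    if cfg.backend == "lightgbm":
        return _lightgbm_importance(X, y, kind, cfg, seed)
    return _sklearn_importance(X, y, kind, cfg, seed)


def importance_matrix(dataset: MixedDataset, config: InferenceConfig,
                      subsample_index: int = 0) -> pd.DataFrame:
    """p x p variable-importance matrix; entry (i, j) is the importance of
    predictor j for target i.  Rows are built from independent forests with
    seeds keyed by (run seed, subsample index, target name), so the result
    does not depend on column order."""
    if not dataset.is_complete():
        raise GrafonetError("importance_matrix requires a complete dataset")
    names = sorted(dataset.variable_names)
    kinds = {v.name: v.kind for v in dataset.variables}
    return _importance_from_matrix(dataset.numeric_matrix(names), kinds, config,
                                   subsample_index)


def rank_pairs(M: pd.DataFrame) -> list[Pair]:
    """Order all unordered pairs by the worse of their two directional ranks.

    Within each target row, predictors are ranked 1 (most important) to p-1
    by descending importance (ties averaged).  A pair's rank is the maximum
    of its two directional ranks; ties break on the sum of the ranks and then
    on the pair name.
    """
    names = list(M.index)
    p = len(names)
    if p < 2:
        raise GrafonetError("need at least two variables")
    vals = M.to_numpy(dtype=float)
    ranks = np.full((p, p), np.nan)
    for i in range(p):
        others = [j for j in range(p) if j != i]
        row = vals[i, others]
        ranks[i, others] = rankdata(-row, method="average")
    scored = []
    for i in range(p):
        for j in range(i + 1, p):
            r1, r2 = ranks[i, j], ranks[j, i]
            scored.append((max(r1, r2), r1 + r2, (names[i], names[j])))
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    return [pair for _, _, pair in scored]


def select_top_q(ranking: Sequence[Pair], q: int) -> set[Pair]:
    if q > len(ranking):
        raise GrafonetError(f"q={q} exceeds the number of candidate pairs {len(ranking)}")
    if q < 1:
        raise GrafonetError("q must be >= 1")
    return set(ranking[:q])


def aggregate_stability(edge_sets: Sequence[Iterable[Pair]]) -> StabilityTable:
    """Selection frequency of every pair across the 2B half-sample models."""
    return StabilityTable.from_edge_sets(edge_sets)


def threshold_edges(table: StabilityTable, threshold: float = 0.8,
                    strict: bool = True) -> set[Pair]:
    """Pairs whose selection frequency exceeds the threshold (strictly, per
    the 'more than 80%' rule; ``strict=False`` for the >= variant)."""
    if not 0.0 < threshold <= 1.0:
        raise GrafonetError("threshold must lie in (0, 1]")
    freqs = table.frequencies()
    if strict:
        return {p for p, f in freqs.items() if f > threshold}
    return {p for p, f in freqs.items() if f >= threshold}


def _aggregate_both_halves(edge_sets: Sequence[set[Pair]]) -> StabilityTable:
    """Simultaneous-selection variant: a pair counts once per complementary
    pair only when selected in both halves."""
    counts: dict[Pair, int] = {}
    B = len(edge_sets) // 2
    for b in range(B):
        both = set(edge_sets[2 * b]) & set(edge_sets[2 * b + 1])
        for pair in both:
            counts[pair] = counts.get(pair, 0) + 2  # keep multiples of 1/(2B)
    return StabilityTable(counts=counts, n_subsamples=2 * B)


# -- signs -----------------------------------------------------------------


def _marginal_sign(x: np.ndarray, y: np.ndarray) -> float:
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x, y)[0, 1]
    return 0.0 if np.isnan(r) else float(np.sign(r))


def estimate_signs(dataset: MixedDataset, edges: Iterable[Pair]) -> dict[Pair, str]:
    """Edge signs from full regression models.

    Each endpoint variable is regressed on all other (non-meta) variables:
    ordinary least squares for continuous targets, logistic regression for
    binary ones.  An edge is positive/negative when the two coefficient signs
    agree, ambiguous otherwise.  Singular designs fall back to the marginal
    correlation sign with a warning.
    """
    edges = [pair_key(u, v) for u, v in edges]
    if not edges:
        return {}
    if not dataset.is_complete():
        raise GrafonetError("estimate_signs requires a complete dataset")
    names = sorted(v.name for v in dataset.variables if v.layer != "meta")
    kinds = {v.name: v.kind for v in dataset.variables}
    num = dataset.numeric_matrix(names)
    X = num.to_numpy(dtype=float)
    n, p = X.shape
    endpoints = sorted({u for e in edges for u in e})
    coef_sign: dict[str, dict[str, float]] = {}
    for target in endpoints:
        i = names.index(target)
        others = [j for j in range(p) if j != i]
        y = X[:, i]
        A = X[:, others]
        signs: dict[str, float] = {}
        if n <= len(others) + 1:
            warnings.warn(
                f"singular design for {target!r} (n={n}, p={len(others)}); "
                "using marginal signs", stacklevel=2)
            for j in others:
                signs[names[j]] = _marginal_sign(X[:, j], y)
        elif kinds[target] == "binary":
            from sklearn.linear_model import LogisticRegression

            if len(np.unique(y)) < 2:
                for j in others:
                    signs[names[j]] = 0.0
            else:
                model = LogisticRegression(C=np.inf, max_iter=1000)
                model.fit(A, y.astype(int))
                for k, j in enumerate(others):
                    signs[names[j]] = float(np.sign(model.coef_[0, k]))
        else:
            design = np.column_stack([np.ones(n), A])
            beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
            if rank < design.shape[1]:
                warnings.warn(
                    f"rank-deficient design for {target!r}; using marginal signs",
                    stacklevel=2)
                for j in others:
                    signs[names[j]] = _marginal_sign(X[:, j], y)
            else:
                for k, j in enumerate(others):
                    signs[names[j]] = float(np.sign(beta[k + 1]))
        coef_sign[target] = signs
    out: dict[Pair, str] = {}
    for u, v in edges:
        su = coef_sign[u].get(v, 0.0)
        sv = coef_sign[v].get(u, 0.0)
        if su > 0 and sv > 0:
            out[(u, v)] = "+"
        elif su < 0 and sv < 0:
            out[(u, v)] = "-"
        else:
            out[(u, v)] = "ambiguous"
    return out


# -- orchestration ---------------------------------------------------------


def infer_mgm(dataset: MixedDataset, config: InferenceConfig) -> tuple[MixedGraph, StabilityTable]:
    """Full network inference on a preprocessed (complete) dataset.

    Runs the subsample plan, per-half-sample importance ranking and top-q
    selection, aggregates selection frequencies, applies the CPSS threshold
    and attaches regression signs.  A family meta-variable participates in
    every forest but its node and incident edges are removed from the
    returned graph.
    """
    if not dataset.is_complete():
        raise GrafonetError("infer_mgm requires a complete dataset; impute first")
    names = sorted(dataset.variable_names)
    kinds = {v.name: v.kind for v in dataset.variables}
    num_all = dataset.numeric_matrix(names)
    p = len(names)
    n_pairs = p * (p - 1) // 2
    q = config.q if config.q is not None else default_q(
        n_pairs, config.threshold, config.fwer_alpha)
    logger.info("inference: p=%d variables, %d candidate pairs, q=%d, B=%d, tau=%.2f",
                p, n_pairs, q, config.B, config.threshold)
    plan = make_subsample_plan(dataset.sample_ids, config.B, config.seed)
    edge_sets: list[set[Pair]] = []
    for idx, subset_ids in enumerate(plan.subsets()):
        sub = num_all.loc[list(subset_ids)]
        M = _importance_from_matrix(sub, kinds, config, idx)
        ranking = rank_pairs(M)
        edge_sets.append(select_top_q(ranking, q))
    if config.both_halves:
        table = _aggregate_both_halves(edge_sets)
    else:
        table = aggregate_stability(edge_sets)
    selected = threshold_edges(table, config.threshold, strict=True)
    meta_names = {v.name for v in dataset.variables if v.layer == "meta"}
    selected = {e for e in selected if not (set(e) & meta_names)}
    sign_ds = dataset.subset_variables(
        [v.name for v in dataset.variables if v.layer != "meta"])
    signs = estimate_signs(sign_ds, selected)
    g = MixedGraph.from_nodes_edges(
        [(v.name, {"layer": v.layer, "kind": v.kind})
         for v in dataset.variables if v.name not in meta_names],
        [(u, v, {"frequency": table.frequency(u, v), "sign": signs[(u, v)]})
         for (u, v) in sorted(selected)],
    )
    return g, table


def _importance_from_matrix(num: pd.DataFrame, kinds: dict[str, str],
                            config: InferenceConfig, subsample_index: int) -> pd.DataFrame:
    """Importance matrix from an already-encoded numeric table (fast path)."""
    names = list(num.columns)
    arr = num.to_numpy(dtype=float)
    p = len(names)
    M = pd.DataFrame(np.nan, index=names, columns=names)
    vals = M.to_numpy()
    for i, target in enumerate(names):
        others = [j for j in range(p) if j != i]
        y = arr[:, i]
        seed = stable_seed(config.seed, subsample_index, target)
        try:
            imp = target_importance(arr[:, others], y, kinds[target], config, seed)
        except GrafonetError:
            logger.warning("degenerate target %r in subsample %d", target, subsample_index)
            imp = np.zeros(len(others))
        vals[i, others] = imp
    return pd.DataFrame(vals, index=names, columns=names)
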