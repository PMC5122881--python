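import numpy as np
import pandas as pd
import pytest

from conftest import random_dataset
from grafonet.datatypes import GrafonetError, MixedDataset, StabilityTable, VariableSpec
from grafonet.inference import (
    InferenceConfig,
    aggregate_stability,
    default_q,
    estimate_signs,
    importance_matrix,
    infer_mgm,
    make_subsample_plan,
    rank_pairs,
    select_top_q,
    threshold_edges,
)


def _dataset(values: np.ndarray, kinds=None) -> MixedDataset:
    n, p = values.shape
    names = [f"v{i:02d}" for i in range(p)]
    kinds = kinds or ["continuous"] * p
    df = pd.DataFrame(values, columns=names, index=[f"s{i:03d}" for i in range(n)])
    return MixedDataset(df, [VariableSpec(nm, k) for nm, k in zip(names, kinds)],
                        [f"f{i}" for i in range(n)])


class TestSubsamplePlan:
    def test_minimal_partition(self):
        plan = make_subsample_plan(4, B=1, seed=0)
        a, b = plan.pairs[0]
        assert len(a) == 2 and len(b) == 2
        assert set(a) | set(b) == {"0", "1", "2", "3"}
        assert not set(a) & set(b)

    def test_odd_n_gives_floor_and_ceil_halves(self):
        a, b = make_subsample_plan(5, B=1, seed=0).pairs[0]
        assert sorted([len(a), len(b)]) == [2, 3]

    def test_hundred_pairs_give_two_hundred_models(self):
        plan = make_subsample_plan(12, B=100, seed=1)
        assert len(plan.subsets()) == 200

    def test_reproducible_and_row_order_invariant(self):
        ids = [f"s{i}" for i in range(9)]
        p1 = make_subsample_plan(ids, B=3, seed=5)
        p2 = make_subsample_plan(list(reversed(ids)), B=3, seed=5)
        assert p1 == p2

    def test_rejects_bad_inputs(self):
        with pytest.raises(GrafonetError):
            make_subsample_plan(3, B=1, seed=0)
        with pytest.raises(GrafonetError):
            make_subsample_plan(8, B=0, seed=0)


class TestDefaultQ:
    def test_satisfies_error_bound(self):
        for P in (10, 190, 1000, 10440):
            for tau in (0.6, 0.8, 1.0):
                q = default_q(P, tau)
                assert q >= 1
                # expected false selections bounded by alpha (for q the bound allows)
                if q > 1:
                    assert q**2 / ((2 * tau - 1) * P) <= 0.05 + 1e-12

    def test_known_value_for_twenty_variables(self):
        assert default_q(190, 0.8) == 2


class TestRankPairs:
    def test_hand_enumerated_three_variable_case(self):
        # A-row ranks: B=1, C=2; B-row: A=1, C=2; C-row: B=1, A=2
        M = pd.DataFrame(
            [[np.nan, 0.9, 0.5], [0.9, np.nan, 0.5], [0.5, 0.9, np.nan]],
            index=list("ABC"), columns=list("ABC"))
        order = rank_pairs(M)
        # pair ranks: AB = 1, AC = 2, BC = 2; ties break on rank sum (BC: 3 < AC: 4)
        assert order == [("A", "B"), ("B", "C"), ("A", "C")]

    @pytest.mark.parametrize("seed", range(3))
    def test_symmetric_matrix_gives_equal_directional_ranks(self, seed):
        rng = np.random.default_rng(seed)
        p = 5
        M = rng.random((p, p))
        M = (M + M.T) / 2
        np.fill_diagonal(M, np.nan)
        names = [f"x{i}" for i in range(p)]
        df = pd.DataFrame(M, index=names, columns=names)
        order = rank_pairs(df)
        assert len(order) == p * (p - 1) // 2

    def test_two_variables_single_pair(self):
        M = pd.DataFrame([[np.nan, 1.0], [2.0, np.nan]], index=["a", "b"],
                         columns=["a", "b"])
        assert rank_pairs(M) == [("a", "b")]


class TestSelection:
    def test_top_one_is_best_pair(self):
        ranking = [("A", "B"), ("B", "C"), ("A", "C")]
        assert select_top_q(ranking, 1) == {("A", "B")}
        assert select_top_q(ranking, 3) == set(ranking)
        with pytest.raises(GrafonetError):
            select_top_q(ranking, 4)

    def test_aggregate_counts(self):
        sets = [{("a", "b")}, {("a", "b")}, {("a", "b"), ("c", "d")}, {("a", "b")}]
        table = aggregate_stability(sets)
        assert table.frequency("a", "b") == 1.0
        assert table.frequency("c", "d") == 0.25
        assert aggregate_stability([set(), set()]).counts == {}

    def test_threshold_is_strict(self):
        table = StabilityTable(
            counts={("a", "e"): 85, ("a", "f"): 80, ("a", "g"): 79}, n_subsamples=100)
        assert threshold_edges(table, 0.8) == {("a", "e")}
        assert threshold_edges(table, 0.8, strict=False) == {("a", "e"), ("a", "f")}

    @pytest.mark.parametrize("t1,t2", [(0.6, 0.8), (0.8, 0.9), (0.51, 1.0)])
    def test_threshold_monotonicity(self, t1, t2):
        rng = np.random.default_rng(1)
        counts = {(f"a{i}", f"b{i}"): int(rng.integers(0, 101)) for i in range(30)}
        table = StabilityTable(counts=counts, n_subsamples=100)
        assert threshold_edges(table, t2) <= threshold_edges(table, t1)


class TestImportance:
    @pytest.mark.parametrize("backend", ["lightgbm", "sklearn"])
    def test_duplicated_variable_dominates_its_row(self, backend):
        rng = np.random.default_rng(0)
        n = 200
        x = rng.standard_normal(n)
        vals = np.column_stack([x, x, rng.standard_normal(n), rng.standard_normal(n)])
        ds = _dataset(vals)
        cfg = InferenceConfig(B=1, rf_trees=60, backend=backend,
                              rf_importance="impurity", min_samples_leaf=5, seed=3)
        M = importance_matrix(ds, cfg)
        # v01 duplicates v00: each is the top predictor of the other
        assert M.loc["v01"].idxmax() == "v00"
        assert M.loc["v00"].idxmax() == "v01"

    def test_independent_noise_stays_below_permuted_null(self):
        rng = np.random.default_rng(42)
        n, p = 150, 5
        vals = rng.standard_normal((n, p))
        ds = _dataset(vals)
        cfg = InferenceConfig.simulation(seed=0, B=1)
        M = importance_matrix(ds, cfg)
        observed_max = np.nanmax(M.to_numpy())
        # null distribution: importances for explicitly permuted targets
        null_max = []
        for rep in range(30):
            shuffled = vals.copy()
            shuffled[:, 0] = rng.permutation(shuffled[:, 0])
            Mn = importance_matrix(_dataset(shuffled),
                                   InferenceConfig.simulation(seed=100 + rep, B=1))
            null_max.append(np.nanmax(Mn.loc["v00"].to_numpy()))
        assert observed_max <= np.quantile(null_max, 0.99) * 1.5

    @pytest.mark.parametrize("backend", ["lightgbm", "sklearn"])
    def test_identical_runs_identical_matrices(self, backend):
        ds = _dataset(np.random.default_rng(5).standard_normal((60, 4)))
        cfg = InferenceConfig(B=1, rf_trees=30, backend=backend,
                              rf_importance="impurity", min_samples_leaf=5, seed=9)
        M1 = importance_matrix(ds, cfg, subsample_index=2)
        M2 = importance_matrix(ds, cfg, subsample_index=2)
        assert M1.equals(M2)

    def test_single_class_target_gets_minimal_row(self):
        vals = np.column_stack([
            np.zeros(30),  # constant binary target
            np.random.default_rng(0).standard_normal(30),
            np.random.default_rng(1).standard_normal(30),
        ])
        ds = _dataset(vals, kinds=["binary", "continuous", "continuous"])
        M = importance_matrix(ds, InferenceConfig.simulation(seed=0))
        assert (M.loc["v00"].dropna() == 0).all()


class TestSigns:
    def _xyz(self, slope: float, n: int = 500, seed: int = 0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        y = slope * x + 0.5 * rng.standard_normal(n)
        z = rng.standard_normal(n)
        return _dataset(np.column_stack([x, y, z]))

    def test_positive_relationship(self):
        signs = estimate_signs(self._xyz(2.0), [("v00", "v01")])
        assert signs[("v00", "v01")] == "+"

    def test_negative_relationship(self):
        signs = estimate_signs(self._xyz(-2.0), [("v00", "v01")])
        assert signs[("v00", "v01")] == "-"

    def test_signs_only_for_supplied_edges(self):
        signs = estimate_signs(self._xyz(2.0), [("v00", "v01")])
        assert set(signs) == {("v00", "v01")}

    def test_binary_endpoint_uses_logistic_model(self):
        rng = np.random.default_rng(3)
        n = 400
        x = rng.standard_normal(n)
        b = (x + 0.5 * rng.standard_normal(n) > 0).astype(float)
        ds = _dataset(np.column_stack([x, b, rng.standard_normal(n)]),
                      kinds=["continuous", "binary", "continuous"])
        signs = estimate_signs(ds, [("v00", "v01")])
        assert signs[("v00", "v01")] == "+"

    def test_singular_design_falls_back_to_marginal(self):
        rng = np.random.default_rng(1)
        ds = _dataset(rng.standard_normal((4, 6)))  # n < p
        with pytest.warns(UserWarning, match="marginal"):
            signs = estimate_signs(ds, [("v00", "v01")])
        assert signs[("v00", "v01")] in {"+", "-", "ambiguous"}


class TestInferMgm:
    @pytest.fixture(scope="class")
    def chain_data(self):
        rng = np.random.default_rng(11)
        n, p, rho = 500, 10, 0.6
        omega = np.eye(p)
        for i in range(p - 1):
            omega[i, i + 1] = omega[i + 1, i] = -rho
        omega += (0.05 - min(np.linalg.eigvalsh(omega)[0], 0.05)) * np.eye(p)
        vals = rng.multivariate_normal(np.zeros(p), np.linalg.inv(omega), size=n)
        return _dataset(vals)

    def test_chain_recovered_without_shortcuts(self, chain_data):
        cfg = InferenceConfig.simulation(seed=4, B=20, q=9)
        graph, table = infer_mgm(chain_data, cfg)
        expected = {(f"v{i:02d}", f"v{i+1:02d}") for i in range(9)}
        assert graph.edge_set() == expected

    def test_determinism_same_seed_same_graph(self, chain_data):
        cfg = InferenceConfig.simulation(seed=7, B=4, q=5)
        g1, t1 = infer_mgm(chain_data, cfg)
        g2, t2 = infer_mgm(chain_data, cfg)
        assert g1.edge_set() == g2.edge_set()
        assert t1.counts == t2.counts

    def test_invariant_to_row_and_column_permutation(self, chain_data):
        cfg = InferenceConfig.simulation(seed=7, B=4, q=5)
        g1, _ = infer_mgm(chain_data, cfg)
        rng = np.random.default_rng(0)
        cols = list(rng.permutation(chain_data.variable_names))
        rows = list(rng.permutation(chain_data.sample_ids))
        shuffled = chain_data.subset_variables(cols).subset_samples(rows)
        g2, _ = infer_mgm(shuffled, cfg)
        assert g1.edge_set() == g2.edge_set()

    def test_family_meta_variable_removed_from_graph(self):
        rng = np.random.default_rng(2)
        ds = _dataset(rng.standard_normal((60, 4)))
        from grafonet.preprocess import attach_family_variable

        with_family = attach_family_variable(ds)
        cfg = InferenceConfig.simulation(seed=1, B=2, q=3)
        graph, _ = infer_mgm(with_family, cfg)
        assert "family" not in graph.nodes()
        assert set(graph.nodes()) == set(ds.variable_names)

    def test_incomplete_dataset_rejected(self, small_mixed_dataset):
        with pytest.raises(GrafonetError, match="complete"):
            infer_mgm(small_mixed_dataset, InferenceConfig())
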