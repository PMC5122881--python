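import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtri

from conftest import random_dataset
from grafonet.datatypes import GrafonetError, MixedDataset, VariableSpec
from grafonet.preprocess import (
    attach_family_variable,
    dichotomize,
    filter_missing,
    impute_missing,
    inverse_normal,
    preprocess,
    transform_continuous,
)


def _continuous(values: np.ndarray, families=None) -> MixedDataset:
    n, p = values.shape
    cols = [f"v{i}" for i in range(p)]
    df = pd.DataFrame(values, columns=cols, index=[f"s{i}" for i in range(n)])
    return MixedDataset(df, [VariableSpec(c, "continuous") for c in cols],
                        families or [f"f{i}" for i in range(n)])


class TestFilterMissing:
    def test_sample_above_threshold_dropped(self):
        vals = np.random.default_rng(0).standard_normal((5, 10))
        vals[0, :3] = np.nan  # 30% missing > 20%
        ds, report = filter_missing(_continuous(vals))
        assert report.dropped_samples == ["s0"]
        assert report.dropped_variables == []
        assert ds.n_samples == 4

    def test_fully_observed_unchanged(self):
        ds0 = _continuous(np.random.default_rng(1).standard_normal((4, 4)))
        ds, report = filter_missing(ds0)
        assert ds.values.equals(ds0.values)
        assert report.dropped_samples == [] and report.dropped_variables == []
        assert report.n_imputed_cells == 0

    def test_variable_at_exact_threshold_retained(self):
        vals = np.random.default_rng(2).standard_normal((5, 4))
        vals[0, 1] = np.nan  # exactly 1/5 = 20%, strict rule keeps it
        ds, report = filter_missing(_continuous(vals))
        assert report.dropped_variables == []
        assert "v1" in ds.variable_names

    def test_missing_fraction_never_increases_after_filtering(self):
        ds0 = random_dataset(30, 8, seed=5, missing=0.25)
        before = ds0.variable_missing_fraction()
        ds, _ = filter_missing(ds0)
        after = ds.variable_missing_fraction()
        for v in ds.variable_names:
            assert after[v] <= 0.2 + 1e-12 or after[v] <= before[v]

    def test_all_samples_removed_is_error(self):
        vals = np.full((4, 4), np.nan)
        vals[:, 0] = 1.0
        with pytest.raises(GrafonetError):
            filter_missing(_continuous(vals), sample_max_missing=0.1)


class TestImpute:
    def test_median_for_continuous(self):
        vals = np.array([[1.0], [2.0], [30.0], [np.nan]])
        out = impute_missing(_continuous(vals))
        assert out.values.iloc[3, 0] == 2.0

    def test_mode_for_binary(self):
        df = pd.DataFrame({"b": [0.0, 0.0, 0.0, 1.0, np.nan]},
                          index=[f"s{i}" for i in range(5)])
        ds = MixedDataset(df, [VariableSpec("b", "binary")], ["f"] * 5)
        out = impute_missing(ds)
        assert out.values.iloc[4, 0] == 0.0

    def test_knn_k1_copies_duplicate_row(self):
        vals = np.array([
            [1.0, 2.0, 3.0],
            [1.0, 2.0, np.nan],  # duplicate of row 0 except the gap
            [-5.0, 7.0, -1.0],
            [4.0, -2.0, 0.5],
        ])
        out = impute_missing(_continuous(vals), method="knn", k=1)
        assert out.values.iloc[1, 2] == 3.0

    def test_observed_values_never_change(self):
        ds = random_dataset(20, 6, seed=7, missing=0.2, kinds="mixed")
        for method in ("median_mode", "knn"):
            out = impute_missing(ds, method=method)
            assert out.is_complete()
            mask = ds.observed.to_numpy()
            assert np.array_equal(out.values.to_numpy()[mask], ds.values.to_numpy()[mask])

    def test_all_missing_variable_named_in_error(self):
        vals = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(GrafonetError, match="v1"):
            impute_missing(_continuous(vals))


class TestInverseNormal:
    def test_blom_quantiles_of_three_values(self):
        out = inverse_normal([3.0, 1.0, 2.0])
        expected = ndtri((np.array([3, 1, 2]) - 0.375) / 3.25)
        assert np.allclose(out, expected)
        assert np.allclose(out, [0.8694, -0.8694, 0.0], atol=5e-5)

    def test_one_third_offset_variant(self):
        out = inverse_normal([3.0, 1.0, 2.0], offset=1 / 3)
        assert np.allclose(out, [0.8416, -0.8416, 0.0], atol=5e-5)

    def test_median_maps_to_zero_for_odd_n(self):
        x = np.random.default_rng(0).permutation(np.arange(11.0))
        out = inverse_normal(x)
        assert out[np.argsort(x)[5]] == pytest.approx(0.0, abs=1e-12)

    def test_ties_share_transformed_value(self):
        out = inverse_normal([1.0, 1.0, 2.0])
        assert out[0] == out[1]

    def test_constant_vector_rejected(self):
        with pytest.raises(GrafonetError):
            inverse_normal([2.0, 2.0, 2.0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=40, unique=True))
    def test_symmetric_mean_zero_and_monotone(self, xs):
        out = inverse_normal(np.array(xs))
        assert abs(out.mean()) < 1e-12
        order = np.argsort(xs)
        assert np.all(np.diff(out[order]) > 0)


class TestDichotomize:
    @pytest.fixture
    def categorical_ds(self):
        df = pd.DataFrame({"x": ["a", "b", "c", "a"], "b0": [0.0, 1.0, 0.0, 1.0]},
                          index=[f"s{i}" for i in range(4)])
        specs = [VariableSpec("x", "categorical", "phenotype", ("a", "b", "c")),
                 VariableSpec("b0", "binary")]
        return MixedDataset(df, specs, ["f"] * 4)

    def test_three_levels_give_two_indicators(self, categorical_ds):
        out = dichotomize(categorical_ds)
        assert out.variable_names == ["x::b", "x::c", "b0"]
        # sample with level "c" -> indicators (0, 1); binary passes through
        assert list(out.values.loc["s2", ["x::b", "x::c"]]) == [0.0, 1.0]
        assert list(out.values["b0"]) == [0.0, 1.0, 0.0, 1.0]

    def test_original_level_recoverable(self, categorical_ds):
        out = dichotomize(categorical_ds)
        rec = []
        for s in out.sample_ids:
            if out.values.loc[s, "x::b"]:
                rec.append("b")
            elif out.values.loc[s, "x::c"]:
                rec.append("c")
            else:
                rec.append("a")
        assert rec == list(categorical_ds.values["x"])

    def test_single_level_rejected(self):
        df = pd.DataFrame({"x": ["a", "a"]}, index=["s0", "s1"])
        ds = MixedDataset(df, [VariableSpec("x", "categorical", "phenotype", ("a",))],
                          ["f", "f"])
        with pytest.raises(GrafonetError):
            dichotomize(ds)


class TestFamilyVariable:
    def test_family_ids_copied(self, small_mixed_dataset):
        out = attach_family_variable(small_mixed_dataset)
        assert out.variable_names[-1] == "family"
        assert list(out.values["family"]) == ["f1", "f1", "f2", "f2", "f3"]
        assert out.spec("family").layer == "meta"

    def test_singleton_families_give_distinct_levels(self):
        ds = random_dataset(6, 2, seed=0)
        ds = MixedDataset(ds.values, ds.variables, [f"f{i}" for i in range(6)])
        out = attach_family_variable(ds)
        assert len(out.spec("family").levels) == 6

    def test_double_application_rejected(self, small_mixed_dataset):
        once = attach_family_variable(small_mixed_dataset)
        with pytest.raises(GrafonetError):
            attach_family_variable(once)


def test_preprocess_chain_produces_complete_transformed_dataset(small_mixed_dataset):
    clean, report = preprocess(small_mixed_dataset, impute="median_mode", seed=1)
    assert clean.is_complete()
    # the two samples with 25% missing cells exceed the 20% filter
    assert report.dropped_samples == ["s3", "s5"]
    assert clean.n_samples == 3
    # categorical expanded, family attached
    assert "diet::mid" in clean.variable_names and "family" in clean.variable_names
    age = clean.values["age"]
    assert abs(age.mean()) < 1e-12  # inverse normalized

    # with a laxer sample filter the gaps survive filtering and are imputed
    clean2, report2 = preprocess(small_mixed_dataset, sample_max_missing=0.5,
                                 variable_max_missing=0.5, impute="median_mode", seed=1)
    assert clean2.n_samples == 5 and clean2.is_complete()
    assert report2.n_imputed_cells == 2


def test_transform_continuous_requires_complete_data(small_mixed_dataset):
    with pytest.raises(GrafonetError):
        transform_continuous(small_mixed_dataset)
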