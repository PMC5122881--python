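"""Pre-processing of mixed cohort data before network inference.

Order of operations in the standard workflow:

1. :func:`filter_missing` — drop samples with more than 20% missing cells,
   then variables with more than 20% missing cells (strict inequalities).
2. :func:`impute_missing` — fill the remaining gaps (median/mode or k-NN).
3. :func:`inverse_normal` — rank-based inverse normal transform of every
   continuous variable (Blom offset by default).
4. :func:`dichotomize` — recode categorical variables as L-1 indicators.
5. :func:`attach_family_variable` — add the family identifier as a
   categorical meta-variable so relatedness is conditioned on during
   inference (the corresponding node is removed from the final network).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .datatypes import GrafonetError, MixedDataset, VariableSpec

FAMILY_VARIABLE = "family"

#: rank offset c in (r - c)/(n - 2c + 1); 3/8 is the Blom convention
BLOM_OFFSET = 0.375


@dataclass
class PreprocessReport:
    dropped_samples: list[str] = field(default_factory=list)
    dropped_variables: list[str] = field(default_factory=list)
    n_imputed_cells: int = 0
    transform_log: dict[str, str] = field(default_factory=dict)


def filter_missing(
    dataset: MixedDataset,
    sample_max_missing: float = 0.2,
    variable_max_missing: float = 0.2,
) -> tuple[MixedDataset, PreprocessReport]:
    """Drop samples, then variables, whose missing fraction strictly exceeds
    the given thresholds (variable fractions computed on retained samples)."""
    for f in (sample_max_missing, variable_max_missing):
        if not 0.0 <= f <= 1.0:
            raise GrafonetError(f"missingness threshold {f} outside [0,1]")
    report = PreprocessReport()
    smiss = dataset.sample_missing_fraction()
    keep_samples = [s for s in dataset.sample_ids if smiss[s] <= sample_max_missing]
    report.dropped_samples = [s for s in dataset.sample_ids if s not in set(keep_samples)]
    if not keep_samples:
        raise GrafonetError("all samples exceed the missingness threshold")
    trimmed = dataset.subset_samples(keep_samples)
    vmiss = trimmed.variable_missing_fraction()
    keep_vars = [v for v in trimmed.variable_names if vmiss[v] <= variable_max_missing]
    report.dropped_variables = [v for v in trimmed.variable_names if v not in set(keep_vars)]
    out = trimmed.subset_variables(keep_vars)
    report.n_imputed_cells = int((~out.observed).to_numpy().sum())
    return out, report


def _mode(series: pd.Series):
    counts = series.value_counts()
    top = counts[counts == counts.max()]
    return sorted(top.index)[0]  # deterministic tie-break: smallest value/label


def impute_missing(
    dataset: MixedDataset,
    method: str = "median_mode",
    seed: int = 0,
    k: int = 5,
) -> MixedDataset:
    """Single-shot imputation of remaining missing cells.

    ``median_mode`` fills continuous variables with the observed median and
    binary/categorical ones with the observed mode.  ``knn`` fills each cell
    from the ``k`` nearest samples (mean squared difference over commonly
    observed numeric columns) that observe the target variable: mean for
    continuous, mode for binary/categorical.  Observed values never change.
    """
    if method not in ("median_mode", "knn"):
        raise GrafonetError(f"unknown imputation method {method!r}")
    empty = [v for v in dataset.variable_names if dataset.values[v].dropna().empty]
    if empty:
        raise GrafonetError(f"variables with no observed values: {empty}")
    out = dataset.copy()
    if method == "median_mode":
        for spec in out.variables:
            col = out.values[spec.name]
            if not col.isna().any():
                continue
            if spec.kind == "continuous":
                fill = float(col.median())
            else:
                fill = _mode(col.dropna())
            out.values[spec.name] = col.fillna(fill)
        return MixedDataset(out.values, out.variables, out.family_ids)

    # knn: distances on z-scored numeric codes over commonly observed columns
    num = dataset.numeric_matrix()
    z = (num - num.mean()) / num.std(ddof=0).replace(0.0, 1.0)
    Z = z.to_numpy(dtype=float)
    obs = dataset.observed.to_numpy()
    n = len(Z)
    filled = out.values.copy()
    for j, spec in enumerate(dataset.variables):
        col_missing = np.where(~obs[:, j])[0]
        if col_missing.size == 0:
            continue
        donors_j = np.where(obs[:, j])[0]
        for i in col_missing:
            shared = obs[i] & obs[donors_j]  # (n_donors, p) mask of shared columns
            diffs = Z[donors_j] - Z[i]
            sq = np.where(shared, diffs**2, np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                d = np.nanmean(sq, axis=1)
            d = np.where(np.isnan(d), np.inf, d)
            order = np.lexsort((donors_j, d))  # tie-break on donor position: stable
            nearest = donors_j[order[: min(k, len(donors_j))]]
            vals = dataset.values.iloc[nearest, j]
            if spec.kind == "continuous":
                fill = float(vals.astype(float).mean())
            else:
                fill = _mode(vals)
            filled.iloc[i, j] = fill
    return MixedDataset(filled, list(dataset.variables), dataset.family_ids)


def inverse_normal(values: np.ndarray | pd.Series, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Rank-based inverse normal transform.

    Maps values to standard normal quantiles of their offset ranks,
    Phi^-1((r - c)/(n - 2c + 1)) with c the Blom offset 3/8 by default;
    ties receive average ranks.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise GrafonetError("inverse_normal needs a 1-d vector of length >= 2")
    if np.isnan(x).any():
        raise GrafonetError("inverse_normal input must have no missing values")
    if np.all(x == x[0]):
        raise GrafonetError("constant vector: ranks are degenerate")
    r = rankdata(x, method="average")
    n = len(x)
    return ndtri((r - offset) / (n - 2 * offset + 1))


def transform_continuous(dataset: MixedDataset, offset: float = BLOM_OFFSET) -> MixedDataset:
    """Apply `inverse_normal` to every continuous variable of a complete dataset."""
    out = dataset.copy()
    for spec in out.variables:
        if spec.kind == "continuous":
            out.values[spec.name] = inverse_normal(out.values[spec.name], offset=offset)
    return MixedDataset(out.values, out.variables, out.family_ids)


def dichotomize(dataset: MixedDataset) -> MixedDataset:
    """Replace each categorical variable (L levels) by L-1 binary indicators.

    The reference is the first level in metadata order; indicators are named
    ``<var>::<level>``.  Binary and continuous variables pass through.
    """
    cols: dict[str, pd.Series] = {}
    specs: list[VariableSpec] = []
    for spec in dataset.variables:
        col = dataset.values[spec.name]
        if spec.kind != "categorical":
            cols[spec.name] = col
            specs.append(spec)
            continue
        if len(spec.levels) < 2:
            raise GrafonetError(f"categorical {spec.name!r} has a single level")
        for level in spec.levels[1:]:
            name = f"{spec.name}::{level}"
            ind = col.map(lambda x, lv=level: np.nan if pd.isna(x) else float(x == lv))
            cols[name] = ind
            specs.append(VariableSpec(name, "binary", spec.layer))
    table = pd.DataFrame(cols, index=dataset.values.index)
    return MixedDataset(table, specs, dataset.family_ids)


def attach_family_variable(dataset: MixedDataset) -> MixedDataset:
    """Add the per-sample family id as a categorical meta-layer variable.

    The variable takes part in inference (so shared family background is
    conditioned on) and its node is dropped from the final network.
    """
    if any(v.layer == "meta" and v.name == FAMILY_VARIABLE for v in dataset.variables):
        raise GrafonetError("family meta-variable already present")
    levels = tuple(dict.fromkeys(dataset.family_ids))  # first-appearance order
    spec = VariableSpec(FAMILY_VARIABLE, "categorical", "meta", levels)
    table = dataset.values.copy()
    table[FAMILY_VARIABLE] = dataset.family_ids.astype(object)
    return MixedDataset(table, list(dataset.variables) + [spec], dataset.family_ids)


def preprocess(
    dataset: MixedDataset,
    sample_max_missing: float = 0.2,
    variable_max_missing: float = 0.2,
    impute: str = "median_mode",
    seed: int = 0,
    add_family: bool = True,
) -> tuple[MixedDataset, PreprocessReport]:
    """Full pre-processing chain; returns the analysis-ready dataset."""
    ds, report = filter_missing(dataset, sample_max_missing, variable_max_missing)
    ds = impute_missing(ds, method=impute, seed=seed)
    ds = transform_continuous(ds)
    for spec in ds.variables:
        report.transform_log[spec.name] = (
            "inverse_normal" if spec.kind == "continuous"
            else "dichotomize" if spec.kind == "categorical" else "none"
        )
    ds = dichotomize(ds)
    if add_family:
        ds = attach_family_variable(ds)
    return ds, report
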