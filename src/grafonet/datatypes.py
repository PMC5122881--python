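"""Shared domain types for mixed graphical model analysis.

A *mixed* dataset holds continuous, binary and categorical variables measured
on the same samples (here: multi-omics markers plus clinical phenotypes), with
an explicit missingness mask and a family identifier per sample so that twin
structure can be accounted for during network inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

KINDS = ("continuous", "binary", "categorical")
LAYERS = (
    "epigenomics",
    "transcriptomics",
    "glycomics",
    "metabolomics",
    "dxa",
    "phenotype",
    "meta",
)

#: edge sign labels as stored in graphml
SIGN_POSITIVE = "+"
SIGN_NEGATIVE = "-"
SIGN_AMBIGUOUS = "ambiguous"
SIGNS = (SIGN_POSITIVE, SIGN_NEGATIVE, SIGN_AMBIGUOUS)


class GrafonetError(ValueError):
    """Base class for domain errors raised by this package."""


@dataclass(frozen=True)
class VariableSpec:
    """Description of one measured variable.

    Parameters
    ----------
    name
        Unique identifier within a dataset.
    kind
        One of ``continuous``, ``binary``, ``categorical``.
    layer
        The omics layer (or ``phenotype``/``dxa``/``meta``) the variable
        belongs to; carried through to graph node attributes.
    levels
        Category labels, required (non-empty) iff ``kind == "categorical"``.
        The first level is the reference level for dichotomization.
    """

    name: str
    kind: str
    layer: str = "phenotype"
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise GrafonetError("variable name must be non-empty")
        if self.kind not in KINDS:
            raise GrafonetError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.layer not in LAYERS:
            raise GrafonetError(f"unknown layer {self.layer!r} for {self.name!r}")
        if self.kind == "categorical":
            if len(self.levels) == 0:
                raise GrafonetError(f"categorical variable {self.name!r} needs levels")
        elif self.levels:
            raise GrafonetError(f"levels given for non-categorical variable {self.name!r}")
        object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))


class MixedDataset:
    """Sample x variable table of mixed-type values with missingness mask.

    ``values`` is a pandas DataFrame indexed by sample id, one column per
    variable in the canonical order of ``variables``.  Missing cells are NaN;
    the ``observed`` mask is derived from that.  Continuous and binary columns
    are float, categorical columns hold level labels (object dtype).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        variables: Sequence[VariableSpec],
        family_ids: Sequence[str] | pd.Series,
    ) -> None:
        variables = list(variables)
        names = [v.name for v in variables]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise GrafonetError(f"duplicate variable names: {dupes}")
        if list(values.columns) != names:
            raise GrafonetError("values columns must match variable specs in order")
        if values.index.has_duplicates:
            raise GrafonetError("duplicate sample ids")
        fam = pd.Series(list(family_ids), index=values.index, dtype=object) \
            if not isinstance(family_ids, pd.Series) else family_ids.reindex(values.index)
        if len(fam) != len(values) or fam.isna().any() or (fam == "").any():
            raise GrafonetError("family_ids must be non-empty, one per sample")
        self.values = values.copy()
        self.values.index = values.index.astype(str)
        self.variables = variables
        self.family_ids = fam.astype(str)
        self.family_ids.index = self.values.index
        self._validate_cells()

    def _validate_cells(self) -> None:
        for spec in self.variables:
            col = self.values[spec.name]
            obs = col.dropna()
            if spec.kind == "continuous":
                vals = pd.to_numeric(obs, errors="coerce")
                if vals.isna().any() or not np.isfinite(vals.to_numpy(dtype=float)).all():
                    raise GrafonetError(
                        f"continuous variable {spec.name!r} has non-finite observed values"
                    )
                self.values[spec.name] = pd.to_numeric(col, errors="coerce").astype(float)
            elif spec.kind == "binary":
                vals = pd.to_numeric(obs, errors="coerce")
                if vals.isna().any() or not vals.isin([0.0, 1.0]).all():
                    bad = sorted(set(obs) - {0, 1, 0.0, 1.0, "0", "1"})
                    raise GrafonetError(
                        f"binary variable {spec.name!r} has values outside {{0,1}}: {bad}"
                    )
                self.values[spec.name] = pd.to_numeric(col, errors="coerce").astype(float)
            else:
                bad = sorted(set(obs.astype(str)) - set(spec.levels))
                if bad:
                    raise GrafonetError(
                        f"categorical variable {spec.name!r} has unknown levels {bad}"
                    )

    # -- accessors ---------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def observed(self) -> pd.DataFrame:
        """Boolean mask, True where a cell was measured."""
        return self.values.notna()

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def spec(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def is_complete(self) -> bool:
        return bool(self.observed.all().all())

    # -- manipulation ------------------------------------------------------

    def copy(self) -> "MixedDataset":
        return MixedDataset(self.values.copy(), list(self.variables), self.family_ids.copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "MixedDataset":
        ids = list(sample_ids)
        return MixedDataset(self.values.loc[ids], list(self.variables), self.family_ids.loc[ids])

    def subset_variables(self, names: Sequence[str]) -> "MixedDataset":
        names = list(names)
        specs = [self.spec(n) for n in names]
        return MixedDataset(self.values[names], specs, self.family_ids)

    def sample_missing_fraction(self) -> pd.Series:
        return 1.0 - self.observed.mean(axis=1)

    def variable_missing_fraction(self) -> pd.Series:
        return 1.0 - self.observed.mean(axis=0)

    def numeric_matrix(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        """Values as floats; categorical variables coded by level index.

        Used to feed forests, which only need an ordering of category codes.
        """
        names = list(names) if names is not None else self.variable_names
        out = {}
        for n in names:
            spec = self.spec(n)
            col = self.values[n]
            if spec.kind == "categorical":
                mapping = {lvl: float(i) for i, lvl in enumerate(spec.levels)}
                out[n] = col.map(mapping).astype(float)
            else:
                out[n] = col.astype(float)
        return pd.DataFrame(out, index=self.values.index)


class MixedGraph:
    """Undirected variable network with stability frequencies and signs.

    Thin wrapper over :class:`networkx.Graph`.  Node attributes: ``layer``,
    ``kind`` and optional ``module``; edge attributes: ``frequency`` (selection
    fraction in [0, 1]) and optional ``sign`` in ``{"+", "-", "ambiguous"}``.
    """

    def __init__(self, graph: nx.Graph | None = None) -> None:
        g = graph if graph is not None else nx.Graph()
        if g.is_directed():
            raise GrafonetError("mixed graphical models are undirected")
        loops = list(nx.selfloop_edges(g))
        if loops:
            raise GrafonetError(f"self-loops are not allowed: {loops}")
        for u, v, d in g.edges(data=True):
            f = d.get("frequency")
            if f is not None:
                f = float(f)
                if not 0.0 <= f <= 1.0:
                    raise GrafonetError(f"edge ({u},{v}) frequency {f} outside [0,1]")
                d["frequency"] = f
            s = d.get("sign")
            if s is not None and s not in SIGNS:
                raise GrafonetError(f"edge ({u},{v}) sign {s!r} not in {SIGNS}")
        self.g = g

    @classmethod
    def from_nodes_edges(
        cls,
        nodes: Iterable[str | tuple[str, Mapping]],
        edges: Iterable[tuple] = (),
    ) -> "MixedGraph":
        g = nx.Graph()
        for n in nodes:
            if isinstance(n, tuple):
                g.add_node(n[0], **dict(n[1]))
            else:
                g.add_node(n)
        for e in edges:
            u, v, *rest = e
            attrs = dict(rest[0]) if rest else {}
            g.add_edge(u, v, **attrs)
        return cls(g)

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.g.nodes)

    def edge_set(self) -> set[tuple[str, str]]:
        return {pair_key(u, v) for u, v in self.g.edges}

    def subgraph(self, nodes: Sequence[str]) -> "MixedGraph":
        missing = sorted(set(nodes) - set(self.g.nodes))
        if missing:
            raise GrafonetError(f"unknown nodes: {missing}")
        return MixedGraph(nx.Graph(self.g.subgraph(nodes)))

    def copy(self) -> "MixedGraph":
        return MixedGraph(self.g.copy())


def pair_key(u: str, v: str) -> tuple[str, str]:
    """Canonical (sorted) form of an unordered variable pair."""
    if u == v:
        raise GrafonetError(f"self-pair ({u},{v})")
    return (u, v) if u < v else (v, u)


@dataclass
class StabilityTable:
    """Selection counts of variable pairs across the 2B half-sample models."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    n_subsamples: int = 2

    def __post_init__(self) -> None:
        if self.n_subsamples < 2 or self.n_subsamples % 2:
            raise GrafonetError("n_subsamples must be even and >= 2")
        for pair, c in self.counts.items():
            if not 0 <= c <= self.n_subsamples:
                raise GrafonetError(f"count {c} for {pair} outside [0, {self.n_subsamples}]")

    @classmethod
    def from_edge_sets(cls, edge_sets: Sequence[Iterable[tuple[str, str]]]) -> "StabilityTable":
        counts: dict[tuple[str, str], int] = {}
        for s in edge_sets:
            for u, v in s:
                k = pair_key(u, v)
                counts[k] = counts.get(k, 0) + 1
        return cls(counts=counts, n_subsamples=len(edge_sets))

    def frequency(self, u: str, v: str) -> float:
        return self.counts.get(pair_key(u, v), 0) / self.n_subsamples

    def frequencies(self) -> dict[tuple[str, str], float]:
        return {p: c / self.n_subsamples for p, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"var1": u, "var2": v, "frequency": c / self.n_subsamples}
            for (u, v), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["var1", "var2", "frequency"])


@dataclass
class ModulePartition:
    """Node -> module assignment together with its modularity score."""

    assignment: dict[str, int]
    modularity: float

    def __post_init__(self) -> None:
        if self.modularity > 1.0 + 1e-12:
            raise GrafonetError(f"modularity {self.modularity} > 1")

    def labels(self, nodes: Sequence[str]) -> list[int]:
        return [self.assignment[n] for n in nodes]

    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.assignment.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))
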