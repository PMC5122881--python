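"""Readers and writers: CSV/TSV tables and graphml networks.

The tabular dialect is auto-detected from the extension (``.tsv``/``.tab`` use
tabs, anything else commas); empty strings and ``NA`` denote missing cells.
Graphml files use declared attribute keys: node ``layer``/``kind``/``module``,
edge ``frequency`` (decimal string, four places) and ``sign`` in
``{"+", "-", "ambiguous"}``.  Unknown attributes round-trip verbatim.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import networkx as nx
import pandas as pd

from .datatypes import (
    GrafonetError,
    MixedDataset,
    MixedGraph,
    VariableSpec,
)

NA_VALUES = ["", "NA"]
FAMILY_COLUMN = "family_id"
SAMPLE_COLUMN = "sample_id"


def _sep(path: str | Path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","


def load_metadata(metadata_file: str | Path) -> list[VariableSpec]:
    meta = pd.read_csv(metadata_file, sep=_sep(metadata_file), dtype=str,
                       keep_default_na=False, na_values=NA_VALUES)
    required = {"name", "kind", "layer"}
    if not required.issubset(meta.columns):
        raise GrafonetError(f"metadata must have columns {sorted(required)}")
    specs = []
    for _, row in meta.iterrows():
        levels = ()
        if "levels" in meta.columns and isinstance(row.get("levels"), str) and row["levels"]:
            levels = tuple(row["levels"].split(";"))
        specs.append(VariableSpec(row["name"], row["kind"], row["layer"], levels))
    return specs


def load_dataset(
    data_file: str | Path,
    metadata_file: str | Path,
    family_column: str = FAMILY_COLUMN,
) -> MixedDataset:
    """Read a sample x variable table plus its variable metadata.

    The data file needs a ``sample_id`` column and a family-id column
    (default ``family_id``); every other column must be described in the
    metadata table and vice versa.  Variable order follows the data file.
    """
    specs = load_metadata(metadata_file)
    spec_map = {s.name: s for s in specs}
    raw = pd.read_csv(data_file, sep=_sep(data_file), dtype=str,
                      keep_default_na=False, na_values=NA_VALUES)
    for col in (SAMPLE_COLUMN, family_column):
        if col not in raw.columns:
            raise GrafonetError(f"data file lacks required column {col!r}")
    var_cols = [c for c in raw.columns if c not in (SAMPLE_COLUMN, family_column)]
    missing_meta = sorted(set(var_cols) - set(spec_map))
    missing_data = sorted(set(spec_map) - set(var_cols))
    if missing_meta or missing_data:
        raise GrafonetError(
            f"variable mismatch: in data but not metadata {missing_meta}; "
            f"in metadata but not data {missing_data}"
        )
    raw = raw.set_index(SAMPLE_COLUMN)
    family = raw[family_column]
    values = {}
    for name in var_cols:
        spec = spec_map[name]
        col = raw[name]
        if spec.kind in ("continuous", "binary"):
            def _parse(cell, row):
                if pd.isna(cell):
                    return float("nan")
                try:
                    # float() is correctly rounded, so repr() round trips bit-exactly
                    return float(cell)
                except ValueError:
                    raise GrafonetError(
                        f"non-numeric value {cell!r} for {spec.kind} variable "
                        f"{name!r} in sample {row!r}") from None
            values[name] = pd.Series(
                [_parse(c, r) for r, c in col.items()], index=col.index, dtype=float)
        else:
            values[name] = col
    table = pd.DataFrame(values, index=raw.index)[var_cols]
    table.index.name = None
    return MixedDataset(table, [spec_map[n] for n in var_cols], family.rename(None))


def save_dataset(
    dataset: MixedDataset,
    data_file: str | Path,
    metadata_file: str | Path,
) -> None:
    """Write a dataset back to the tabular dialect `load_dataset` reads."""
    out = dataset.values.copy()
    for spec in dataset.variables:
        if spec.kind != "categorical":
            # repr() keeps full float precision for exact round trips
            out[spec.name] = out[spec.name].map(
                lambda x: "" if pd.isna(x) else repr(float(x)))
        else:
            out[spec.name] = out[spec.name].fillna("")
    out.insert(0, SAMPLE_COLUMN, dataset.sample_ids)
    out.insert(1, FAMILY_COLUMN, dataset.family_ids.values)
    out.to_csv(data_file, sep=_sep(data_file), index=False)
    meta = pd.DataFrame(
        {
            "name": [v.name for v in dataset.variables],
            "kind": [v.kind for v in dataset.variables],
            "layer": [v.layer for v in dataset.variables],
            "levels": [";".join(v.levels) for v in dataset.variables],
        }
    )
    meta.to_csv(metadata_file, sep=_sep(metadata_file), index=False)


# -- graphml ---------------------------------------------------------------


def write_graph(graph: MixedGraph, path: str | Path) -> None:
    """Write graphml with canonical node/edge order and stable formatting.

    Nodes and edges are sorted by name; ``frequency`` is written with four
    decimal places.  Writing, reading and writing again is byte-identical.
    """
    g = nx.Graph()
    for n in sorted(graph.g.nodes):
        attrs = {k: str(v) for k, v in sorted(graph.g.nodes[n].items()) if v is not None}
        g.add_node(n, **attrs)
    for u, v in sorted(tuple(sorted(e)) for e in graph.g.edges):
        d = graph.g.edges[u, v]
        attrs = {}
        for k, val in sorted(d.items()):
            if val is None:
                continue
            if k == "frequency":
                attrs[k] = f"{float(val):.4f}"
            else:
                attrs[k] = str(val)
        g.add_edge(u, v, **attrs)
    nx.write_graphml_xml(g, str(path), encoding="utf-8", prettyprint=True)


def read_graph(path: str | Path) -> MixedGraph:
    """Read a graphml network; rejects directed graphs, self-loops and
    duplicate node ids."""
    tree = ET.parse(path)
    ns = "{http://graphml.graphdrawing.org/xmlns}"
    seen: set[str] = set()
    for node in tree.iter(f"{ns}node"):
        nid = node.get("id")
        if nid in seen:
            raise GrafonetError(f"duplicate node id {nid!r} in {path}")
        seen.add(nid)
    g = nx.read_graphml(str(path))
    if g.is_directed():
        raise GrafonetError(f"{path} contains directed edges; model is undirected")
    for u, v, d in g.edges(data=True):
        if "frequency" in d:
            d["frequency"] = float(d["frequency"])
    return MixedGraph(g)
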