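import numpy as np
import pandas as pd
import pytest

from grafonet.datatypes import MixedDataset, MixedGraph, VariableSpec


@pytest.fixture
def small_mixed_dataset() -> MixedDataset:
    """5 samples x 4 variables (2 continuous, 1 binary, 1 categorical) with
    two missing cells and two twin families."""
    values = pd.DataFrame(
        {
            "age": [34.0, 55.0, np.nan, 70.0, 61.0],
            "glyc": [0.1, -0.4, 1.2, 0.8, np.nan],
            "smoker": [0.0, 1.0, 0.0, 1.0, 1.0],
            "diet": ["low", "high", "mid", "low", "high"],
        },
        index=[f"s{i}" for i in range(1, 6)],
    )
    specs = [
        VariableSpec("age", "continuous", "phenotype"),
        VariableSpec("glyc", "continuous", "glycomics"),
        VariableSpec("smoker", "binary", "phenotype"),
        VariableSpec("diet", "categorical", "phenotype", ("low", "mid", "high")),
    ]
    return MixedDataset(values, specs, ["f1", "f1", "f2", "f2", "f3"])


def random_dataset(n: int, p: int, seed: int, missing: float = 0.0,
                   kinds: str = "continuous") -> MixedDataset:
    """Deterministic random dataset for round-trip and property tests."""
    rng = np.random.default_rng(seed)
    specs = []
    cols = {}
    for i in range(p):
        name = f"v{i:02d}"
        if kinds == "mixed" and i % 3 == 2:
            specs.append(VariableSpec(name, "binary", "phenotype"))
            cols[name] = rng.integers(0, 2, n).astype(float)
        else:
            specs.append(VariableSpec(name, "continuous", "metabolomics"))
            cols[name] = rng.standard_normal(n)
    values = pd.DataFrame(cols, index=[f"s{i:03d}" for i in range(n)])
    if missing > 0:
        mask = rng.random(values.shape) < missing
        values = values.mask(mask)
    fams = [f"f{i // 2}" for i in range(n)]
    return MixedDataset(values, specs, fams)


def graph_from_edges(edges, extra_nodes=()) -> MixedGraph:
    nodes = sorted({n for e in edges for n in e} | set(extra_nodes))
    return MixedGraph.from_nodes_edges(nodes, [(u, v) for u, v in edges])
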