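"""Shared helpers for the numbered analysis drivers."""

from pathlib import Path

from grafonet.datatypes import VariableSpec, pair_key
from grafonet.io import read_graph
from grafonet.simulate import TruthGraph

#: small, reportable artifacts (tables, graphml, json) live in results/;
#: bulky regenerable data (simulated cohorts, cleaned matrices) in scratch/
RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "analysis"

#: edge count of the 3-block / 18-variable cohort truth graph (3 rings of 6
#: plus 2 bridges); q for the cohort model is set to this oracle sparsity
COHORT_TRUTH_EDGES = 20


def load_truth(path: Path) -> TruthGraph:
    """Rebuild a TruthGraph from a truth graphml written by the simulator."""
    g = read_graph(path)
    specs = [
        VariableSpec(n, g.g.nodes[n].get("kind", "continuous"),
                     g.g.nodes[n].get("layer", "phenotype"))
        for n in g.nodes()
    ]
    edges = {pair_key(u, v): float(g.g.edges[u, v].get("strength", 0.5))
             for u, v in g.g.edges}
    truth = TruthGraph(variables=specs, edges=edges)
    blocks = {n: int(g.g.nodes[n]["block"]) for n in g.nodes()
              if "block" in g.g.nodes[n]}
    if blocks:
        truth._blocks = blocks
    return truth
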