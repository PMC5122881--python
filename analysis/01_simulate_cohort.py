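#!/usr/bin/env python
"""Generate the synthetic study cohort.

Emulates the shape of the twin-cohort multi-omics table the pipeline was
designed for: 510 female twins' worth of samples, mixed
continuous/binary variables spread over omics layers, 200 twin pairs with a
shared family intercept, and 5% missing cells.  The cohort mixes 14
continuous omics markers with 4 binary phenotypes over a 3-block truth
graph; the all-continuous recovery benchmark is generated on the fly by
script 05 (see docs/methods.md for why the two are separate).

The truth graph lands in results/sim/; the (regenerable) data tables in
scratch/analysis/.
"""

from analysis_common import RESULTS, SCRATCH
from grafonet.io import save_dataset
from grafonet.simulate import (
    SimulationConfig,
    make_truth_graph,
    simulate_mixed,
    truth_to_graphml,
)

SEED = 20161125

COHORT = SimulationConfig(
    n_samples=510, n_continuous=14, n_binary=4, structure="modular_blocks",
    edge_strength=0.6, n_blocks=3, missing_rate=0.05, n_families=200, seed=SEED)


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    (RESULTS / "sim").mkdir(parents=True, exist_ok=True)
    truth = make_truth_graph(COHORT)
    dataset = simulate_mixed(truth, COHORT)
    save_dataset(dataset, SCRATCH / "cohort.csv", SCRATCH / "cohort_meta.csv")
    truth_to_graphml(truth, RESULTS / "sim" / "cohort_truth.graphml")
    n_miss = int((~dataset.observed).to_numpy().sum())
    print(f"cohort: {dataset.n_samples} samples x {dataset.n_variables} variables, "
          f"{len(truth.edges)} true edges, {n_miss} missing cells "
          f"({n_miss / dataset.observed.size:.1%})")


if __name__ == "__main__":
    main()
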