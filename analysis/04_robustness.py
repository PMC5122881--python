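#!/usr/bin/env python
"""Stability of the inferred network.

Three analyses mirroring how the method's robustness is assessed on real
cohorts: (i) edge-inclusion cutoff sweep (20/40/60/80/100% of subsamples)
with degree/clustering rank correlations and module ARIs against the 80%
reference model, (ii) the 1000-draw random-assignment ARI background, and
(iii) twin split-half models (one twin per family) scored by the fraction
of reference edges re-found in their union.

Reads results/model/, writes results/robustness/.
"""

import json
import numpy as np
import pandas as pd

from analysis_common import COHORT_TRUTH_EDGES, RESULTS, SCRATCH
from grafonet.community import detect_modules
from grafonet.datatypes import StabilityTable, pair_key
from grafonet.inference import InferenceConfig
from grafonet.io import load_dataset, read_graph
from grafonet.robustness import split_half_models, stability_report

SEED = 20161125


def main() -> None:
    out = RESULTS / "robustness"
    out.mkdir(parents=True, exist_ok=True)
    graph = read_graph(RESULTS / "model" / "model.graphml")
    frame = pd.read_csv(RESULTS / "model" / "stability.tsv", sep="\t")
    table = StabilityTable(
        counts={pair_key(r.var1, r.var2): round(r.frequency * 100)
                for r in frame.itertuples()},
        n_subsamples=100)
    partition = detect_modules(graph, method="exact")

    report = stability_report(table, graph, partition, n_draws=1000, seed=SEED)
    print("cutoff sweep (edges, degree-corr, clustering-corr, ARI vs reference):")
    for c, s in sorted(report.cutoff_stats.items()):
        print(f"  {c:.0%}: edges={s['n_edges']:3d} "
              f"deg_r={s['degree_correlation']:+.3f} "
              f"clust_r={s['clustering_correlation']:+.3f} "
              f"ari={s.get('ari_vs_reference', float('nan')):+.3f}")
    bg = np.array(report.background_ari)
    print(f"ARI background: mean {bg.mean():+.4f}, 95th percentile {np.quantile(bg, 0.95):.4f}")

    clean = load_dataset(SCRATCH / "clean.csv", SCRATCH / "clean_meta.csv")
    cfg = InferenceConfig.simulation(seed=SEED, B=50, q=COHORT_TRUTH_EDGES)
    g1, g2, overlap, unique = split_half_models(clean, cfg, graph, seed=SEED)
    print(f"split-half: models with {g1.n_edges} and {g2.n_edges} edges; "
          f"{overlap:.1%} of reference edges re-found in the union "
          f"({unique} unique to the reference)")

    payload = {
        "cutoffs": {f"{c:.1f}": s for c, s in report.cutoff_stats.items()},
        "background_ari_mean": float(bg.mean()),
        "background_ari_q95": float(np.quantile(bg, 0.95)),
        "split_overlap": overlap,
        "unique_to_reference": unique,
        "split_edges": [g1.n_edges, g2.n_edges],
    }
    with open(out / "robustness.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


if __name__ == "__main__":
    main()
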