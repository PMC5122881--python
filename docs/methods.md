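# Methods

## The model

`grafonet` estimates a **mixed graphical model (MGM)**: an undirected graph
over variables of mixed type (continuous omics markers, binary and
categorical phenotypes) in which an edge between *x* and *y* means that the
two are dependent *conditional on all other modeled variables*.  Absence of
an edge means conditional independence — associations that are mediated by
other variables in the model are removed.  The target application is
multi-omics epidemiology: a few hundred samples, on the order of a hundred
pre-selected variables spanning epigenomics, transcriptomics, glycomics,
metabolomics, DXA body-composition measures and clinical phenotypes, with
twin/family structure.

Edges are estimated in two layers:

1. **Graphical random forest ranking.**  For each variable *v*, a random
   forest predicts *v* from all remaining variables (regression forests for
   continuous targets, classification forests for binary/categorical ones).
   Within each target's forest, predictors are ranked 1 (most important) to
   p−1 by variable importance.  Every unordered pair {x, y} thus receives
   two directional ranks — x as predictor of y, and y of x — and the pair's
   rank is the **maximum (worse)** of the two.  Ranks rather than raw
   importances are compared because importance scales are not comparable
   between regression and classification targets.  The best-ranked `q`
   pairs form one candidate model.

2. **Complementary-pairs stability selection (CPSS).**  The ranking step is
   repeated on B random half-samples and their complements (2B models in
   total; B = 100 by default).  A pair becomes an edge of the final network
   iff it is selected in strictly more than a fraction τ (default 0.8) of
   the 2B half-sample models.  With `q` chosen from the stability-selection
   error bound E[V] ≤ q²/((2τ−1)·P) ≤ α (P = number of candidate pairs,
   α = 0.05), the expected number of falsely selected edges — and hence the
   family-wise error rate — is below 0.05.  Because the bound must be
   *satisfied*, `q = max(1, floor(sqrt(α(2τ−1)P)))` rounds **down**.
   `q` is a first-class knob: the error-bound default is what one wants for
   null-safe discovery, while power studies with known sparsity are run
   with `q` near the expected edge count (see below).

Forests carry no notion of effect sign, so signs are estimated afterwards,
for interpretation only: each endpoint is regressed on all other (non-meta)
variables — ordinary least squares for continuous targets, logistic
regression for binary ones — and an edge is labeled +/− when the two
coefficient signs agree, `ambiguous` otherwise.  Singular designs fall back
to marginal correlation signs with a warning.

**Family structure** is handled the way the twin-cohort application
requires: a categorical meta-variable holding the family id participates in
every forest, so shared family background can be absorbed by it rather than
inducing spurious edges between heritable variables; the family node and
its incident edges are removed from the returned network.

## Pre-processing

Applied in fixed order; all steps strict about their inputs:

* **Missingness filters** — samples with more than 20% missing cells are
  dropped first, then variables with more than 20% missing cells (fractions
  recomputed on the retained samples).  Thresholds are strict (`>`), a
  flagged choice since "more than 20%" admits either reading.
* **Imputation** — single-shot median (continuous) / mode (binary,
  categorical) imputation, or k-NN over z-scored numeric codes (k = 5
  default, mean/mode of the donors).  This deliberately replaces
  multiple imputation by chained equations: the downstream inference is
  rank- and forest-based and insensitive to imputation refinement, and a
  full MICE implementation is out of scope.
* **Inverse-normal transform** — every continuous variable is mapped to
  standard-normal quantiles of its offset ranks, Φ⁻¹((r − c)/(n − 2c + 1))
  with Blom's c = 3/8 (configurable); ties receive average ranks.  The
  transform makes forests and regressions insensitive to marginal scale and
  outliers.
* **Dichotomization** — a categorical variable with L levels becomes L−1
  indicators `var::level` against the first (reference) level.
* **Family indicator** — the per-sample family id appended as a
  categorical `meta`-layer variable (see above).

## Network analysis

Topology statistics follow the standard definitions: degree; local
clustering (0 for degree < 2); betweenness with multiple shortest paths
counted fractionally, normalized by (n−1)(n−2)/2 *within the node's
connected component* (the only normalization that yields the percentage
scale used when reporting hub centrality); mean shortest path over
unordered pairs (largest component by default); a per-node mean distance
for "how central is this variable"; and the **small-world index**
S = (C/C_rand)/(L/L_rand), with Erdős–Rényi expectations C_rand = k̄/n and
L_rand = ln n / ln k̄ used analytically by default (a Monte-Carlo mode
averaging over sampled G(n, M) graphs exists for validation; the analytic
default keeps results deterministic).  `mediation_fraction` reports the
share of all shortest paths that pass through a node; its denominator
includes adjacent pairs (whose single-edge path has no interior vertex) by
default, with a non-adjacent-only variant behind a flag.

**Module detection** maximizes Newman modularity.  Three methods:

* `exact` — branch and bound over the clique-partitioning formulation.
  Modularity is additive over co-clustered cluster pairs (merging clusters
  i, j changes Q by exactly 2(e_ij − a_i a_j)), so any state's achievable
  score is bounded by its current Q plus all positive pairwise gains;
  branching either merges the best pair or forbids it, and a greedy
  agglomeration provides the incumbent.  Guaranteed optimal; practical to
  a few dozen nodes (hard limit 120), and verified against exhaustive
  partition enumeration on small graphs.
* `greedy` — deterministic Clauset–Newman–Moore agglomeration (networkx).
* `spinglass` — seeded stochastic optimization (igraph), run per connected
  component.

Modules never span components; singleton components are singleton modules.

## Robustness analyses

* **Cutoff sweep** — models re-thresholded at 20/40/60/80/100% of
  subsamples (non-strict at 100%, else the top network would be empty by
  construction), compared to the 80% reference by Spearman correlation of
  degrees and clustering coefficients and by ARI of re-detected modules.
* **ARI background** — 1000 random module assignments obtained by
  permuting node labels, preserving the reference module sizes (the
  stricter null; a uniform-assignment mode exists behind a flag).
* **Split-half models** — the cohort is split into two disjoint sets with
  one twin of each family per side (singletons randomized by seed), the
  network re-inferred on each, and stability scored as the fraction of
  reference edges present in the union of the two split models.
* **Node-restricted comparison** — an enlarged model is restricted to the
  reference node set, modules re-detected on the induced subgraph and
  compared to the reference partition by ARI.

Adjusted Rand index uses the standard pair-counting chance correction
(sklearn's implementation, cross-checked in the tests against an
independent brute-force pair-counting oracle).

## Synthetic data

The generator stands in for the restricted cohort data.  A **truth graph**
over p mixed variables (chain, modular blocks, or Erdős–Rényi) with a
target partial correlation ρ per edge is converted to a precision matrix:
off-diagonals −ρ on edges, diagonal loaded until the smallest eigenvalue
reaches 0.05, then rescaled so the implied covariance has unit diagonal.
The construction errors out if loading would shrink realized partial
correlations below half their target — which is why `modular_blocks` uses
a **ring** inside each block (within-block degree 2, one bridge between
consecutive blocks): fully dense blocks at ρ = 0.6 cannot be made positive
definite without destroying the edge strengths.  Block membership is
assigned round-robin over the variable list so each block mixes kinds and
layers, as real multi-omics modules do.

Samples are latent multivariate normal draws; continuous variables are the
latents plus a per-(family, variable) shared twin intercept of variance
0.2 (twins correlate within a variable; no cross-variable confounding);
binary variables indicate a positive latent; cells are set missing
completely at random at the configured rate (≤ 20%).

**What the generator does not emulate:** platform batch effects, run-day
normalization artifacts, non-Gaussian marginals beyond what the
inverse-normal transform removes, assortative missingness, and families
larger than two.  Passing recovery tests therefore demonstrate correctness
of the machinery under the latent-Gaussian model, not performance on any
particular real cohort.

**Latent thresholding caveat.**  Binarizing a latent destroys part of the
conditioning information: given only the *observed* binary, the two latent
neighbours of a binary node remain dependent, so the observed-scale truth
differs from the latent truth graph around binary nodes (extra two-hop
dependencies appear, and binary-adjacent edges are attenuated).  Edge
*recovery* is therefore benchmarked on the all-continuous generator, where
the latent graph is the observed-scale truth; the mixed 14-continuous +
4-binary cohort is analyzed alongside it to quantify the cost of
thresholding (analysis script 05 reports both; across seeds the mixed case
loses roughly 5–25 F1 points relative to the continuous case at the same
settings, driven almost entirely by binary-adjacent edges).

## Study conditions and problem sizes

All simulation studies use a fixed, seeded profile:

* **Forest engine.**  The spec-level default forest is sklearn's
  RandomForest (500 trees, permutation importance, p/3 or √p features per
  split).  Simulation studies use LightGBM in `rf` boosting mode —
  bagging fraction 0.632 with per-node feature subsampling and gain
  (impurity) importance — with 100 trees and 8-leaf trees
  (`InferenceConfig.simulation()`).  LightGBM-rf is a bona fide random
  forest; histogram-based tree growth makes it roughly six times faster at
  these sample sizes, which is what makes replicated studies practical on
  one CPU.
* **Null FWER study** — p = 20 independent inverse-normalized variables,
  n = 200, B = 50 pairs, error-bound q rule (q = 2 at P = 190, τ = 0.8),
  40 replicates, 50-tree forests.  Under the null, importance rankings are
  exchangeable noise whatever the forest quality, so tree count only makes
  rankings noisier (more conservative); observed null selection
  frequencies peak around 0.2–0.3, far below the 0.8 threshold.  ≈ 10
  minutes on one CPU.
* **Recovery study** — modular-block truth, p = 18 continuous, 3 ring
  blocks, ρ = 0.6, n = 600 (200 twin pairs + 200 singletons), B = 50,
  q = 20 (the true edge count — the "oracle sparsity" a power study grants
  the method; the error-bound default q ≤ 2 is a null-discovery setting,
  not a power setting).  Reports edge precision/recall/F1, greedy-module
  ARI against the generating blocks, and twin split-half edge recall.
  ≈ 2 minutes.  At these conditions several true-edge selection
  frequencies sit near the 0.8 threshold, so recall varies noticeably from
  draw to draw (0.75–1.0 across the seeds we ran); the benchmark is
  therefore a fixed-seed simulation, as is conventional for such tests,
  and the analysis driver reports an independent draw alongside it.

## Numerical choices

* Pair ranks use average ranks for ties; the pair order is
  (max rank, sum of ranks, lexicographic pair name) — fully deterministic.
* Per-forest seeds are SHA-256 hashes of (run seed, subsample index,
  target *name*), so results are invariant to column and row order; the
  subsample plan shuffles the *sorted* sample ids for the same reason.
* Degenerate classification targets (a constant binary in some half-sample)
  contribute an all-minimal importance row with a logged warning, keeping
  the 2B models comparable instead of aborting.
* Graphml is written with sorted nodes/edges, four-decimal frequencies and
  stringified attributes: write∘read∘write is byte-identical.
* Exact modularity uses global edge counts when solving per component
  (cross-component merges are never beneficial, but gains must be computed
  against the whole graph's m).

## Known limitations

* Edge signs are a post-hoc linear/logistic summary of a non-linear model;
  `ambiguous` is common and honest.
* The exact modularity solver is exponential in the worst case; beyond a
  few dozen nodes use `greedy` or `spinglass`.
* CPSS controls false *edges*; it says nothing about uncertainty in
  downstream topology or module statistics, which is why the cutoff sweep
  and split-half analyses exist.
* No causal orientation: edges are conditional dependencies only.
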