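# Methods

## Model and pipeline

The unit of analysis is the ordered metabolic dependency between two
gut microbes: how much organism i's in-silico growth rate changes when
organism j is present. Given single-culture rate S > 0 and co-culture
rate P ≥ 0 (1/h, simulated per diet), the dependency weight is

    w(i ← j) = log2(P / S).

w = 0 means no change, w > 0 promotion, w < 0 inhibition; each unordered
pair yields two weights, one per direction. The pipeline then:

1. ingests the pair-growth table, validates it (no self-pairs, no
   duplicate (pair, diet) rows, finite non-negative rates) and builds a
   per-diet directed weight matrix;
2. optionally collapses strain-level model identifiers to species by
   arithmetic mean of w over all contributing ordered strain pairs
   (pairs of distinct strains of one species are dropped) — averaging w
   rather than raw rates keeps aggregation order-independent on the
   scale the analysis uses;
3. selects network nodes as the union of the top-k (default 50) species
   by mean relative abundance in patients and in controls, reporting
   per-group coverage (on realistic skewed profiles the union covers
   well over 90% of total abundance);
4. builds one directed network per condition and diet: edge j → i iff
   |w(i ← j)| strictly exceeds a threshold (default 4 log2 units); the
   sign is kept as an edge attribute, the magnitude is the analysis
   weight;
5. characterizes the network by Louvain modularity communities (on the
   undirected projection, edge weight = sum of the two directed
   magnitudes) and PageRank centrality (magnitude-weighted, directed);
6. contrasts interaction groups defined by a focal species set
   (background / within / affecting / affected) via chi-square tests on
   inhibitory or promoting proportions and two-sided rank-sum tests on
   signed-weight distributions;
7. predicts each node's direction of abundance change from its inbound
   neighborhood: II_c = Σ_j w(i ← j) · ā_j(c) for condition c, with ā
   the neighbor's mean relative abundance; the default decision
   statistic is ΔII = II_patient − II_control (a "static" mode using
   II_control alone is available), and accuracy is scored against
   rank-sum differential-abundance directions, excluding species whose
   observed direction is "unchanged".

## Statistical choices

- **Rank-sum tests** (differential abundance and the four-group weight
  contrasts) use the exact Mann–Whitney null distribution when both
  arms have ≤ 25 observations and no ties, otherwise the normal
  approximation with tie and continuity corrections. Identical constant
  samples short-circuit to p = 1.
- **Direction of change** is the sign of the difference of group
  medians, assigned independently of significance: the influence module
  needs a direction for every species. Exactly equal medians give
  "unchanged".
- **Chi-square tests** on 2×2 (effect count vs. rest) tables run
  without Yates correction by default (a flag enables it); a table with
  a zero margin (both groups all-effect or all-non-effect) is reported
  as statistic 0, p = 1 rather than an error. Zero weights count as
  neither inhibitory nor promoting and are reported as a third
  fraction.
- **Multiple testing**: raw p-values compared to α = 0.05 by default,
  matching how such group contrasts are conventionally starred;
  Benjamini–Hochberg adjustment is opt-in.
- **Edge threshold** applies to |w|, strictly: promotion and inhibition
  of equal strength are equally network-relevant, and the signed value
  remains on the edge for the influence computation.
- **Extinct co-cultures** (P = 0) make log2 undefined; the weight is
  clamped to a configurable floor (default −10) and the entry flagged,
  preserving the strong-inhibition signal while keeping statistics
  finite and auditable.
- **PageRank** is computed by dense power iteration (damping 0.85,
  L1 convergence tolerance 1e-9, max 200 iterations); per-node
  out-weights are normalized and dangling nodes redistribute uniformly.
  The networks here have at most a few hundred nodes, so a dense
  transition matrix is simpler and exactly testable against a linear
  solve. Ranked lists break score ties lexicographically.
- **Communities**: seeded Louvain (resolution 1.0, seed 0 by default)
  on the undirected projection; modularity is reported for the returned
  partition. An edgeless network yields singleton communities with
  modularity 0.
- **Top-k ranking ties** (node selection) break lexicographically on
  species identifier, making selection invariant to input order.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not biological rate magnitudes. Single-culture rates are lognormal
(median ≈ 0.5/h); target weights are drawn Normal(shift, σ_w) on the
log2 scale and co-culture rates are back-computed as S·2^w, so planted
shifts are directly comparable to the edge threshold. Four additive
shift rules plant the asserted interaction structure: within-probiotic
(−2 by default) and affected-probiotic (−2) make probiotics mutually
inhibited and inhibited by others; within-disease-enriched (+2) and
affecting-enriched (+2) make disease-enriched species mutually promoting
and promoting of others. Rules are additive when several match one
ordered pair (e.g. an enriched source promoting a probiotic target nets
to zero under the defaults). The disease-enriched set is drawn from
non-probiotic species.

Abundance profiles draw lognormal per-species base means (σ = 1),
multiply patient means by planted fold-changes (default 4), add
per-sample lognormal noise (σ = 0.5), and renormalize each sample to
sum to 1. Defaults are 50 species, 20 samples per group — sizes at
which a 4-fold change is essentially always detected by the rank-sum
test while the suite stays fast.

Two modes produce differential species. In **independent** mode the
designated enriched set is simply multiplied by the fold-change. In
**ii_driven** mode abundance changes are wired to the network itself so
the influence predictor has a recoverable ground truth: a driver subset
(30% of species) receives planted driver → responder edges of magnitude
6 (one driver per responder, random sign) while all other weights are
truncated below the edge threshold, so drivers have no inbound edges.
Drivers decrease (fold 1/F — consistent with the deterministic tie rule
that a zero influence index predicts "decreased"); each responder's
fold follows the sign of its ΔII given the driver folds; a direction
noise rate q then flips each species' fold independently. At q = 0
end-to-end accuracy is exactly 1 by construction; at q > 0 it
concentrates around 1 − q. This is deliberately the *easiest* geometry
for the predictor: real communities have feedback cycles, many weak
inbound edges and condition-dependent interactions, so passing these
tests validates the computation, not the biological ceiling of the
method (published recognition accuracies on real cohorts are far below
1).

Randomness uses one seed per scenario, split into fixed named
substreams (classification, enriched set, growth, abundance, noise), so
e.g. adding samples never perturbs the growth table and identical seeds
give byte-identical files.

Other aspects of real data the generator does not emulate: diet-specific
interaction structure (diets get independent draws), compositional
coupling beyond simple renormalization, unclassified taxa mass,
sparsity/zero-inflation of profiles, and strain-level heterogeneity
beyond i.i.d. noise around the species effect.

## Degenerate inputs and tie-breaks

- Absent ordered pairs in the weight matrix are explicit lookup misses,
  never zeros; nodes requested but missing from the matrix are dropped
  with a warning and listed.
- Species absent from the classification map to an explicit
  "unclassified" value.
- Missing abundance for a network species is treated as 0 (profilers
  emit zeros by omission).
- A species with all-zero abundance everywhere is flagged degenerate
  (p = 1, unchanged).
- An exactly zero influence decision statistic deterministically
  predicts "decreased" and is counted separately as a tie.
- Empty groups in the four-group contrasts skip their pairwise tests
  with a flag rather than erroring.

## Problem sizes

The test suite and the acceptance script run everything on synthetic
data: the pair-enumeration check at the full 773-organism scale
(298,378 pairs), statistical oracles by exhaustive enumeration at ≤ 6
observations per arm, PageRank against exact solves on 6–20 node
graphs, community recovery on 12-node planted two-block graphs over 20
seeds, group-effect power and influence accuracy over 50 replicates of
50-species communities. These sizes give stable Monte-Carlo estimates
while keeping a full run in well under a minute per check.

## Known limitations

- The pipeline consumes growth-rate tables; it performs no flux-balance
  or co-culture simulation, no read processing, and no taxonomic
  profiling.
- Strain-to-species mapping between model collections and profiler
  output has no canonical default and must be supplied (or be the
  identity).
- Condition-specific networks share the diet's interaction weights;
  only node sets and abundance attributes differ, since the underlying
  pairwise simulations are condition-independent.
- Which condition's abundances enter the influence index, and whether
  it should use thresholded edges or all interactions, are genuinely
  underdetermined choices; both are exposed (delta/static mode, the
  threshold parameter) rather than silently fixed.
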