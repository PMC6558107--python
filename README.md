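# gutnet

Metabolic dependency networks of the gut microbiota: from pairwise
in-silico growth rates and taxonomic abundance profiles to directed
interaction networks, centrality and community structure, four-group
inhibition/promotion statistics, and neighbor-based prediction of how
species abundances change during intestinal disease (IBD, colorectal
cancer).

## The problem

Co-occurrence networks of gut microbes are undirected and say nothing
about mechanism. When genome-scale metabolic models of gut species are
simulated alone and in pairwise co-culture, each ordered pair (i, j)
yields a *directed* dependency: the log2 change of i's growth rate
caused by j,

```
w(i ← j) = log2(P / S)
```

with P the growth rate of i co-cultured with j and S its growth rate
alone (both in 1/h, per diet). w > 0 means promotion, w < 0 inhibition.
`gutnet` consumes such a pair-growth table together with MetaPhlAn-style
relative-abundance profiles (patients vs. healthy controls) and a
species classification (commensal / probiotic / pathogen / opportunistic
pathogen), and provides:

- **Interaction weights** — validated ingestion of the pair table, the
  w = log2(P/S) transform (with a flagged floor for extinct co-cultures),
  and strain-to-species aggregation by arithmetic mean of w.
- **Abundance analysis** — node selection as the union of the top-k most
  abundant species per group (with coverage reporting), and per-species
  two-sided Wilcoxon rank-sum differential abundance with direction of
  change (optional Benjamini–Hochberg adjustment).
- **Dependency networks** — directed graphs keeping dependencies with
  |w| above a threshold (default 4), edges pointing influencer →
  influenced; Louvain modularity communities on the undirected
  projection; PageRank centrality on the magnitude-weighted digraph;
  species-class composition of the top ranks; GraphML/GEXF/TSV export.
- **Four-group statistics** — ordered interactions split by a focal set
  (e.g. probiotics, or disease-enriched species) into background /
  within / affecting / affected, compared pairwise by chi-square tests
  on inhibitory or promoting proportions and rank-sum tests on weight
  distributions.
- **Inbound Influence Index** — for each network node,
  II = Σ (w × a) over inbound neighbors (edge weight times neighbor mean
  relative abundance); the sign of II_patient − II_control predicts the
  node's direction of abundance change, scored against the observed
  differential-abundance directions.
- **Synthetic studies** — a seeded generator that plants group-level
  weight shifts, differential species, and network-driven abundance
  changes, so every claim above is testable end to end.

## Worked example

`examples/` contains one short script per capability. For instance, the
four-group contrast around probiotics on a synthetic community with
planted within-probiotic and affected-probiotic shifts of −2 log2 units
(`python examples/04_four_group_statistics.py`):

```
group summaries (n, %inhibitory, median w):
  background n=1560  inhibitory= 39.2%  median w=+0.33
  within     n=  90  inhibitory=100.0%  median w=-1.98
  affecting  n= 400  inhibitory= 50.2%  median w=-0.01
  affected   n= 400  inhibitory= 85.0%  median w=-1.68

pairwise chi-square on inhibitory proportions:
  background vs within: chi2=  128.55  p=8.51e-30
  background vs affected: chi2=  266.99  p=5.15e-60
  ...
```

The "within" (probiotic → probiotic) and "affected" (others →
probiotic) groups carry far more inhibitory interactions and lower
weights than background — the planted mutual-restraint pattern, flagged
by the same chi-square/rank-sum machinery the real analysis uses.

Neighbor-based prediction (`python examples/05_influence_prediction.py`)
builds the thresholded network, computes II per node under both
conditions and scores predicted vs. observed directions:

```
accuracy: 1.000 (40/40 species, 12 tie predictions)
```

On noise-free network-driven data every direction is recovered; with
direction-noise rate q the accuracy degrades toward 1 − q.

A thin CLI mirrors the library (`gutnet weights | nodes | diffab |
network | groupstats | influence | simulate`); run `gutnet --help`.

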