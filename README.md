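# fibronet

Systems-biology characterization of fibrosis-related gene sets, built for
researchers studying the genetics of lung fibrosis (and tissue fibrosis more
broadly) in the mouse bleomycin model and its relation to human disease and
to aging.

Genetic evidence about fibrosis accumulates as heterogeneous manipulation
records: a gene is knocked out, overexpressed, inhibited with an antibody,
or its microRNA is perturbed, and the fibrotic outcome is scored. `fibronet`
turns such curated evidence into quantitative statements:

- **Classification.** A gene is *anti-fibrotic* if raising its activity
  reduces fibrosis and/or lowering it promotes fibrosis (pro-fibrotic is the
  mirror case). Each record casts a vote via the direction its manipulation
  implies; genes with conflicting votes are *unclear*. Consistency is scored
  across manipulations of the same gene and against the expression direction
  of the human ortholog in idiopathic pulmonary fibrosis (IPF).
- **Conservation.** From an ortholog presence/absence matrix (genes ×
  species), per-species set fractions are compared with the genome
  background by a 1-df chi-square goodness-of-fit on present/absent counts.
- **Network.** In a cleaned physical interactome, the *interconnectivity*
  of a gene set S is 100·|LCC(G[S])|/|S∩V|: the percentage of in-graph set
  members inside the largest connected component of the subgraph induced by
  the set alone. Significance comes from a resampling null (random node
  sets of equal size, default 1000 draws), summarised as
  Z = (observed − mean)/SD. The module also computes the subset-size vs
  interconnectivity curve and a GSEA-style running-sum enrichment score for
  degree connectivity (hits weighted by degree, misses by 1/(N−n), ES = the
  signed deviation of largest magnitude).
- **Longevity links.** Fibrosis calls are cross-classified against
  pro-/anti-longevity gene annotations with a two-sided Fisher exact test,
  and per-gene OLS models of species-level lung expression on log10 maximum
  lifespan (MLS) are fitted across mammals with Benjamini–Hochberg
  correction, plus the fold-enrichment of significant correlations in a set
  over the genome background.
- **Overrepresentation.** Query sets are scored against GMT libraries with
  one-sided Fisher exact p, a permutation rank z-score, and the combined
  score ln(p)·z (sign folded so enrichment is positive).
- **Synthetic data.** Every input has a generator with planted ground truth
  (module density, conservation shifts, evidence concordance, lifespan
  slopes), so the whole pipeline is testable offline.

## Worked example

`examples/03_network_interconnectivity.py` simulates a 3000-node scale-free
interactome with a planted 100-gene module at 8× internal edge density and
asks whether the module is more wired-together than chance:

```
interactome: 3000 nodes, 54059 edges
module interconnectivity: 100/100 = 100.0%
random sets of 100: mean 40.2%, SD 15.1% -> Z = 3.97
degree-connectivity enrichment score: 0.52 (module mean degree 45.3 vs interactome 36.0)
```

All 100 module members sit in one connected component, while random
100-node sets average 40.2% — a Z-score of 3.97, so the planted wiring is
recovered. The other examples cover classification and consistency
(`01`), conservation profiling (`02`), longevity contingency and lifespan
models (`04`, which prints the curated 18-gene overlap table's
[[11, 1], [0, 5]] split with Fisher p = 0.00097 and a 2.34-fold enrichment
of lifespan-correlated genes), and overrepresentation scoring (`05`).

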