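# Methods

This note documents the models and procedures implemented in `fibronet`,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Classification of fibrosis effects

Each manipulation record carries a manipulation type whose implied activity
direction is fixed by a lookup table: knockout, knockdown, protein
inhibition (inhibitors, antibodies) and microRNA knockout push activity
*down*; overexpression, protein agonists/external protein and microRNA
overexpression push it *up*. Direction is derived, never stored, so a row
cannot contradict itself.

A record votes *anti-fibrotic* when (up, reduced fibrosis) or (down,
promoted fibrosis), *pro-fibrotic* on the mirrored pairs, and abstains on
no-effect or mixed outcomes. The gene-level call is the unanimous vote,
*unclear* when both kinds of evidence exist, *no effect* when every record
abstains. This rule is symmetric: swapping an (up, reduced) record for a
(down, promoted) one never changes a call. Records from non-bleomycin
fibrosis models participate by default — in the curated evidence their
effects track the bleomycin model — with a `bleomycin_only` switch to
restrict.

**Consistency across manipulations.** Only genes probed by two or more
distinct manipulation types are scored. Records of the same type are pooled
and must agree to cast that type's vote. A gene is *full* when all types
vote the same way and *not clear* when any type cannot vote. The remaining
category, *partial*, is not defined in the source summaries; here it means
*agreement with dissent*, and a 1–1 tie between two types also counts as
partial so that the three categories partition the scored genes. Summaries
can be tallied per gene (default) or per manipulation (`weight_by`),
since published tallies are sometimes phrased in numbers of manipulations.
Percentages are always recomputed as 100·count/total, rounded to one
decimal.

**Consistency with IPF.** A call and a human-disease expression direction
are *fully* consistent when pro-fibrotic meets up-regulation or
anti-fibrotic meets down-regulation in IPF, *inconsistent* on the crossed
pairs, *partial* when the IPF direction is mixed, and *not clear* when the
call is unclear/no-effect, the IPF direction is unchanged, or the gene is
missing from the IPF table (missing genes are logged).

## Conservation profiling

A gene's overall conservation is the percentage of species (matrix columns)
with at least one ortholog. For a gene set, each species is tested with a
two-category (present/absent), 1-df chi-square goodness-of-fit of the
observed set count against the expectation from the background fraction,
without continuity correction. The background defaults to all matrix genes,
emulating a genome-wide reference. Degenerate expectations (background
fraction 0 or 1) are resolved by limits — a matching observation gives
chi2 = 0, p = 1, any discrepancy p = 0 — and expected counts below 5 warn
rather than fail, since small synthetic sets are legitimate inputs. Query
ids missing from the matrix are dropped and reported, mirroring how curated
sets lose members when mapped into an orthology resource. Profiles are
sorted by set fraction, descending, with a stable sort so equal fractions
keep the input species order.

## Interconnectivity statistics

The interactome is cleaned before analysis: only physical interactions, one
species, no self-loops, duplicate edges collapsed with (a, b) ≡ (b, a).
Interconnectivity of a set S is 100·|LCC(G[S])|/|S∩V| — neighbours outside
the set do not bridge components ("directly connected"). The denominator is
the number of set genes present in the graph, not the full curated set.
Component search runs on a sparse adjacency sliced to the set, which makes
the resampling loops cheap; a single node is its own component, so a
size-1 sample has interconnectivity 100 by definition.

The null distribution samples equal-size node sets uniformly without
replacement (default 1000 draws) and summarises them as a mean, a
*population* standard deviation (switchable via `ddof`; at 1000 samples the
difference is negligible) and Z = (observed − mean)/SD. The size curve
repeats this over a size grid (default 50 up to the graph size in steps of
50, 100 repetitions each). Each operation takes its own seed and runs one
RNG stream, so results are bit-identical across runs given the seed.

**Degree enrichment.** All nodes are ranked by interactome degree,
descending, ties broken lexicographically by id so the ranking is total and
reproducible. Walking the ranking, set members add degree^w (default w = 1)
normalised over the set; non-members subtract 1/(N − n). The enrichment
score is the signed deviation of largest magnitude, in [−1, 1]. A set
covering every node has no misses and is rejected. If all set members have
degree 0 under w > 0, hit weights fall back to uniform.

## Longevity links

The longevity×fibrosis contingency drops genes unclear on either axis by
default (this is what the curated 18-gene overlap requires to produce its
[[11, 1], [0, 5]] split) and uses the two-sided Fisher exact test — the sum
of hypergeometric probabilities of tables at fixed margins no more likely
than the observed one. A zero margin warns and returns p = 1.

Per-gene lifespan models are ordinary least squares of species-level
expression on log10 maximum lifespan. The log10 transform is the default
because lifespans span more than an order of magnitude across mammals and
the model should not be dominated by the longest-lived species; an
`identity` option is provided. Species-level expression is the median
across a species' replicate samples (mean available). P-values come from
the slope t-test; Benjamini–Hochberg runs across exactly the genes tested
in the call, not the genome, and significance is adjusted p < 0.05.
Constant-expression genes are degenerate: slope 0, p = 1, flagged rather
than dropped. Constant lifespan is an error. Fold-enrichment of significant
correlations compares the set rate with the background rate and tests the
corresponding 2×2 with Fisher's exact test.

## Overrepresentation

Per term: one-sided (greater) Fisher exact p for the query/term overlap
within the background, matching overrepresentation semantics. The rank
z-score is estimated by permutation: terms are ranked by p for the observed
query and for `n_perm` (default 100) random queries of the same size;
z = (expected rank − observed rank)/SD(rank), so terms that rank much
better for the real query score positive. A term whose permuted rank never
varies gets z = 0. The combined score is |ln(p)·z| with the sign of z, so
enrichment is positive, depletion negative, and a disjoint term (p = 1) is
exactly 0. The permutation estimator is an approximation of the combined
score popularised by web enrichment services, whose precomputed rank tables
are not redistributable; with ~100 permutations the z-scores are stable to
about ±0.2.

## Synthetic-data generators

One top-level seed fans out through fixed stream labels
(`SeedSequence((seed, k))`), so regenerating one input never shifts the
others and outputs are byte-identical across platforms. Defaults are the
package's reference study conditions and are not meant to be tuned per run.

- **Interactome** (n = 3000, attachment 18, module 100, multiplier 8): a
  preferential-attachment backbone gives the heavy-tailed degree
  distribution of real interactomes. The planted module is a uniform node
  sample whose absent internal edges are added with probability
  (multiplier − 1)·density, so multiplier 1 plants nothing and the module
  is exactly a random set. The attachment parameter 18 (mean degree ≈ 36,
  the order of a cleaned human interactome's ≈ 45) was chosen because the
  induced-subgraph null for 100-node samples is near-symmetric there, so
  the null Z of an unplanted module is well calibrated (|Z| < 2 for ≈ 97%
  of seeds); sparser backbones give a right-skewed null and denser ones a
  left-skewed null.
- **Ortholog matrix** (2000 genes × 100 species): two tiers emulate the
  vertebrate/invertebrate split, background presence 0.80 and 0.40, with
  the planted 100-gene set shifted +0.15 and −0.20 respectively. Cells are
  independent Bernoulli draws; no phylogenetic correlation between species
  is modelled.
- **Manipulation records** (216 genes, concordance 0.85): each gene gets
  1–4 distinct manipulation types; every record's outcome, and the gene's
  IPF direction, match the hidden label with the concordance probability
  independently. Outcomes are always informative (no planted no-effect
  genes); no-effect handling is exercised by hand-built fixtures instead.
- **Lifespan panel** (90 genes, 14 species, 2 replicates): lifespans are
  log-uniform on 2–60 years. Every replicate sample of a planted gene reads
  slope·log10(MLS) + Normal(0, noise_sd) with independent noise per
  sample — replicate scatter *is* the noise, and per-species aggregation
  averages over it; null genes are pure noise. With the default
  slope 1.0 / noise 0.5, per-gene power at BH 5% is ≈ 0.8, so the expected
  recovered fraction sits just below the planted 30%. A single 14-species
  lifespan draw carries substantial variance (a clustered draw can halve
  the regression power), which is why recovery checks average over a block
  of generator seeds.

What passing on these generators shows — and does not. They validate the
statistical machinery: vote tallying, goodness-of-fit calibration, null
resampling, FDR behaviour, planted-signal recovery at realistic effect
sizes. They do not emulate curation biases, phylogenetic non-independence,
expression count noise or inter-study heterogeneity, so passing here does
not certify performance on any particular real curated dataset.

## Numerical choices and limitations

- Fisher exact tests, chi-square GOF, OLS and BH all go through
  scipy/statsmodels; independent brute-force oracles (union-find
  components, hypergeometric enumeration, hand tallies) live in the test
  suite only.
- Interconnectivity is reported at full precision and rounded only for
  display (107/190 prints as 56.3% at one decimal).
- Sorting and rankings are made total with explicit tie-breaks
  (lexicographic ids) so outputs are order-independent.
- Network hub flagging beyond degree summaries, graph drawing, directed or
  weighted networks, and phylogenetic regression are out of scope.
- The bundled curated tables are summary-level; record-level curation of
  the underlying literature is not part of the package.
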