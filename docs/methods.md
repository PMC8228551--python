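# Methods

This note documents the models, conventions and design choices behind
`mirnet_pd`, in the order the pipeline runs them, together with what the
synthetic generator does and does not emulate.

## DE-miRNA curation

Inputs are per-study reports `(study_id, mirna_id, region, direction)` plus
a study-characteristics table. miRNA identifiers are normalized by
lower-casing, trimming whitespace, and collapsing the star notation
(`"miR-21 *"` → `mir-21*`). The species prefix and the `-3p`/`-5p` arm
suffixes are preserved verbatim: arm variants are distinct mature miRNAs and
merging them would silently conflate different molecules (`hsa-mir-144`,
`hsa-mir-144-3p` and `hsa-mir-144-5p` are three identifiers here).

Consolidation pools reports across studies and regions into four sets: all
upregulated, all downregulated, and the region projections for substantia
nigra and putamen (the two nigrostriatal regions analyzed separately; other
regions are kept as labels — cortical sub-areas share a `cortex_*` family —
but not projected). A miRNA in both direction sets is a **conflict**; one
reported by more than one distinct study is **multi-study**. Both the
printed total (|up| + |down|) and the distinct union are exposed, since they
differ exactly by the number of conflicts.

Cohort variables are summarized as median and quartiles over non-missing
studies only, with linear interpolation between order statistics (the
"type 7" convention, numpy's default). Medians are robust to the quartile
convention; quartiles are reported but should not be compared across tools
without checking conventions. Zero non-missing observations is an explicit
error, never a NaN. Numeric cells accept both `.` and `,` decimal
separators because transcribed clinical tables mix them.

## Target selection

Two filters, applied in sequence:

1. **Evidence filter.** Only interactions with *strong* experimental
   validation (e.g. reporter assays) are kept; dialect labels such as
   "Functional MTI" are mapped through a configurable table. Duplicate
   (miRNA, gene) edges collapse to one.
2. **Brain-expression filter.** A gene survives iff its median TPM is
   *strictly* greater than the threshold (default 1.0) in **every one** of
   the 13 brain tissues (amygdala, anterior cingulate cortex, caudate,
   cerebellar hemisphere, cerebellum, cortex, frontal cortex, hippocampus,
   hypothalamus, nucleus accumbens, putamen, spinal cord, substantia
   nigra). A boundary gene at exactly TPM = 1.0 in any tissue is excluded.
   The every-tissue reading is deliberate (an aggregate-brain reading would
   change set contents); the tissue list is a config default that users can
   override. Genes in the interaction table but absent from the expression
   matrix are excluded and logged rather than silently passed.

Each DE-miRNA set's target set is the union of strong-evidence targets of
its members intersected with the expression-filtered universe; the filter is
therefore antitone in the threshold, and target sets are monotone in the
miRNA set. Overlaps between named sets are reported as disjoint UpSet-style
membership patterns whose counts partition the union, plus plain named
intersections.

## Network topology

Each DE set yields an undirected simple bipartite graph: miRNA nodes, gene
nodes, one edge per retained interaction; regulatory direction is kept only
as node-kind metadata. Undirected centralities with Cytoscape/CytoNCA-style
conventions reproduce the magnitude and pattern of published hub tables
(e.g. a node with distance-sum 70 in a connected 54-node network has
closeness 53/70 ≈ 0.7571428, and betweenness values reach hundreds in graphs
of that size only when unnormalized):

- **Degree** is the raw integer edge count (no normalization).
- **Betweenness** uses Brandes' dependency accumulation: unnormalized,
  endpoints excluded, each unordered pair counted once, fractional credit
  split equally over all shortest paths. Cost O(VE).
- **Closeness** is (N − 1)/Σ_u d(v,u) with the distance sum over the node's
  connected component and N the whole network's node count. On disconnected
  networks this deflates closeness in small components, which matches the
  whole-network normalization ambiguity of the GUI lineage; a config flag
  switches to within-component normalization ((c − 1)/Σd). An isolated pair
  question does not arise because isolated nodes are never constructed:
  miRNAs with no surviving target and genes with no incoming edge are
  dropped at build time.

Hub tables take the top k by one measure with a fully deterministic tie
rule: higher value, then genes before miRNAs, then lexicographic id. An
optional kind filter restricts rankings to genes only, since published hub
lists may or may not have excluded miRNA nodes by rule. Exports are SIF and
GraphML (with a `kind` attribute) plus a TSV centrality table.

Correctness is established against independent brute-force oracles (explicit
all-pairs BFS and enumeration of every shortest path) on 1000 random
bipartite graphs of ≤ 8 nodes across 5 seeds, against closed-form cases
(star, path, 4-cycle), against networkx, and via structural identities
(Σ dc = 2|E|; on trees Σ bc = Σ_pairs (d(u,v) − 1)).

## Enrichment

Over-representation uses the hypergeometric upper tail
p = P(X ≥ k | N, K, n) (scipy's survival function; k = 0 returns exactly 1),
validated against exhaustive subset enumeration for every parameter
combination with N ≤ 12 and against direct PMF summation at N = 2000.
Benjamini–Hochberg step-up adjustment (statsmodels) runs across all tested
pathways; Bonferroni is available by flag. Results sort ascending by
(q, p, pathway id) — the tie rule is arbitrary but fixed.

The background universe matters more than any other ORA choice, so it is
explicit: by default the collection's genes intersected with the
brain-expressed universe; a flag switches to collection-only. Query genes
outside the universe are dropped with a warning; an empty query after
restriction is an error.

## Expression clustering

Hub-gene × tissue submatrices are clustered agglomeratively on rows and
columns independently (scipy), euclidean distance and complete linkage by
default (the defaults of the pheatmap-style tooling this emulates), with
optional per-gene z-scoring (off by default; both behaviors are exposed
because heatmap conventions vary). Correlation distance on a constant row
is an explicit error. Leaf order is fully deterministic without
optimal-leaf-ordering: at every merge the subtree containing the smaller
original index goes left. Complete and average linkage guarantee monotone
merge heights; the reordered matrix is always a permutation of the input.

## Synthetic data

The generator produces every input dialect the pipeline reads, with recorded
ground truth and canonical serialization (sorted rows, `%.9g` floats), so
one seed reproduces byte-identical files. One integer seed drives a named
independent stream per generator (numpy `default_rng([seed, stream_id])`),
so adding a generator never perturbs the others.

- **Interactions**: i.i.d. Bernoulli edges over a 20 × 50 miRNA × gene grid
  at density 0.1, strong evidence with probability 0.7, and one planted hub
  gene whose edge probability is boosted ×10 (capped at 1). These sizes put
  the networks in the tens-of-nodes, hundreds-of-edges regime of real
  validated-target sets while keeping a single run in milliseconds.
- **Expression**: expressed genes draw 1 + Lognormal(μ = 2, σ = 1) per
  tissue — strictly above the TPM = 1 threshold by construction — and
  unexpressed genes draw Uniform(0, 0.9) everywhere. Real TPM values only
  need to straddle the threshold unambiguously for the filter to be
  testable; no attempt is made to match GTEx marginals. The default
  expressed fraction is 0.6, and in the coordinated scenario the planted hub
  is forced into the expressed set so hub recovery measures the network
  stage, not filter luck.
- **Pathways**: 30 pathways of 10–80 members over a 2000-gene universe.
  With a planted signal, the planted pathway draws round(size × 0.5) members
  from the 50-gene query and background pathways round(size × 0.1); the
  fixed counts make planted recovery a sharp test. With equal rates the
  generator switches to uniform sampling from the universe — an exact
  hypergeometric null used for type-I calibration (fixed-count backgrounds
  would be under-dispersed and unsuitable for that purpose).
- **DE reports**: a configurable number of studies, direction conflicts,
  region overlaps and multi-study attributions whose consolidation equals
  the recorded truth exactly; the miRNA identifiers can be drawn from an
  existing pool so the reports join the interaction table.

What passing the synthetic suite shows: the algebra, filters, centralities
and test statistics are implemented correctly under known truth. What it
does not show: robustness to real-data pathologies — inconsistent miRNA
nomenclature across decades of publications, correlated expression across
brain tissues, evidence-code heterogeneity beyond strong/weak, or pathway
collections with heavy gene overlap.

## Pipeline determinism

The run manifest records the package version, the full config, its SHA-256
hash and the seed; `verify_manifest` re-derives the hash. Stages read their
inputs from disk and write sorted, fixed-format outputs, which is what makes
chained subcommands byte-identical to `run-all`.

## Known limitations

- The published hub tables' exact centrality values and node/edge counts
  depend on a validated-interaction database snapshot that is not shipped
  here; the centralities are therefore validated by oracle equivalence and
  convention-consistency checks, not by reproducing those printed numbers.
- Region provenance in the packaged report fixture uses synthetic study
  identifiers: per-study attribution beyond the multi-study flags is not
  recoverable from the published tables.
- ORA assumes uniform sampling from the universe; it ignores gene length,
  expression level and inter-gene correlation biases.
- The expression filter treats tissues symmetrically; there is no notion of
  region-weighted expression.
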