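# Methods

## Network model

The connectome model treats neuropeptide signaling as a bipartite gene
relationship projected onto neurons. Inputs are binary: a gene is either
called expressed in a neuron or not (the calls come from stringently
thresholded single-cell transcriptomes; the package carries the threshold
level only as a provenance tag). For a gene couple *N* = (NPP, GPCR) the
directed edge *i* → *j* exists iff neuron *i* expresses the precursor and
neuron *j* the receptor:

A^N(i, j) = NPP^N(i) · GPCR^N(j).

A couple enters the analysis when at least one peptide encoded by the
precursor activates the receptor in vitro at EC50 at or below the active
threshold (default 500 nM, stored in molar; 100 nM as the stricter
sensitivity setting). `min_ec50` of a couple is the minimum over its
peptide-level entries. This model deliberately ignores peptide copy number,
receptor efficacy and extracellular geometry: an edge is a *possible*
signaling path, not a measured flux.

Self-connections are retained through construction (they are the substrate
of the autocrine analysis) and the diagonal is zeroed before every topology
metric.

## Spatial diffusion models

Anatomy enters as per-neuron annotations: process-bundle membership (one of
27 fascicles in the full-scale configuration, including the two
structurally special bundles `pharynx` and `nerve_ring`), a single body
region (head / midbody / tail, pharynx counted as head), and the subset of
the four nerve-ring strata a nerve-ring process occupies. Four nested
predicates restrict edges:

| model   | predicate |
|---------|-----------|
| long    | always allowed |
| mid     | same body region |
| short   | share ≥ 1 bundle; pharyngeal neurons connect only to pharyngeal neurons |
| contact | share a nerve-ring stratum, or share a thin (non-nerve-ring) bundle |

Self-loops pass every model (same neuron, same location). The contact
predicate inherits the pharynx separation so the edge sets nest —
contact ⊆ short ⊆ mid ⊆ long — provided strata imply nerve-ring membership
and bundles do not span regions; the synthetic anatomy guarantees both by
construction (regions are assigned per bundle and extra bundles are drawn
within-region). The minimal-range analysis refines this ordering into five
classes (stratum contact < thin-bundle contact < short < mid < long) and
reports, for each neuron expressing the focal gene of a mutually exclusive
couple, the smallest class under which it can reach a partner-expressing
neuron.

## Topology metrics

Density is K/(N²−N). Reciprocity is Σ_{i≠j} A_ij A_ji / K (each
reciprocated directed edge counts). Directed transitivity uses triangle
counts t_i = ½ Σ_{j,h} (A_ij+A_ji)(A_ih+A_hi)(A_jh+A_hj) over the
denominator Σ_i [k_i(k_i−1) − 2 Σ_j A_ij A_ji] with k_i the total degree —
the standard directed clustering normalization, which discounts the
reciprocal pairs that would otherwise count as closed triples. All four
statistics are property-tested against brute-force enumeration on small
digraphs.

### Null model

Degree-preserving randomization uses pairwise edge swaps,
(A→B),(C→D) → (A→D),(C→B), rejecting proposals that would create a
self-loop or duplicate an existing edge. Each null attempts
`swaps_per_edge × K` swaps (default 10·K); rejected proposals count toward
the budget and the realized-swap tally is returned for diagnostics. In- and
out-degree sequences are preserved exactly by construction. Graphs too
small or dense to swap return copies with a warning rather than failing.

### Rich club

For each degree level k, Φ(k) = M_k / (N_k(N_k−1)) over the subgraph of
nodes with total degree > k, on a grid of every integer from 1 to
max degree − 1. Φ is normalized by the ensemble mean, and the onset is the
smallest k with Φ_norm(k) ≥ 1 + σ(k). Two σ conventions are one flag apart
(`sigma_basis`): the default `normalized` uses SD(Φ_rand)/mean(Φ_rand) —
the spread of the null curve on the same scale as Φ_norm — while `raw` uses
SD(Φ_rand) directly. Membership is total degree strictly above the onset.
Two numerical guards: Φ is undefined (NaN) where N_k < 2, and when σ = 0 —
possible only in degenerate ensembles whose degree sequence has a unique
realization — strict excess is required, since Φ_norm ≡ 1 would otherwise
open a vacuous all-node club.

A caveat the tests encode: for a homogeneous random graph the original is
exchangeable with its nulls, so at a 1σ threshold *some* k (almost always
in the noisy tail where N_k < 10) exceeds the band in most seeds. "No rich
club" is therefore asserted as flatness of Φ_norm in the bulk (N_k ≥ 20),
not as absence of an onset.

## Mesoscale cores

Each neuron is described by its incoming-connection profile (the column of
the weighted aggregate matrix; a flag switches to outgoing). t-SNE
(default: Euclidean distance, perplexity 30) or PCA reduces profiles to two
dimensions; t-SNE uses exact gradients for panels up to 500 neurons, which
is cheap at this scale and keeps identical profiles exactly coincident
(the Barnes–Hut approximation breaks that tie). DBSCAN on the embedding
(eps defaulting to 5% of the embedding diagonal, min_samples 5) yields
dense cores; all points outside the three largest cores are labeled
`periphery`, making the diffuse cloud a first-class outcome rather than a
forced cluster. Cores are named by median indegree rank — hubs core >
sensory core > motor core — reflecting the empirical ordering of the groups
this procedure is designed to expose; on synthetic data the names are
labels, not claims about composition. Group indegrees are compared with
Kruskal–Wallis and pairwise Tukey HSD (Tukey–Kramer under unequal sizes) on
rank-transformed values; groups with fewer than two members are excluded
with a warning. A robustness harness reruns the clustering under Euclidean,
Chebyshev, cosine and Mahalanobis distances and reports adjusted-Rand
agreement.

## Co-expression and autocrine analysis

For every (NPP, GPCR) combination in the interaction dataset's gene
universe — all pairs, not only cognate couples — a one-sided Fisher exact
test asks whether the genes co-occur in more neurons than expected from
their marginals over the panel; Benjamini–Hochberg controls FDR across the
universe. The exact conditional p-value of a discrete test is sub-uniform
(conservative) by construction; calibration is therefore verified through
the randomized p-value transform p′ = p − U·pmf(observed), which is exactly
uniform under the null iff the test is valid. Analyses always consume the
exact p.

Enriched pairs become nodes of the cascade network, with an edge u → v when
u's ligand gene activates v's receptor gene at the active threshold.
Linking is at gene level; peptide-level linking is indistinguishable once
interactions are reduced to gene couples, so no separate mode is provided.
Autocrine loops are neurons co-expressing both genes of a cognate couple;
per-neuron loop counts are correlated (Pearson, with optional permutation
p) against degrees in any supplied network.

## Synthetic data

The generator emulates the statistical shape of the three inputs rather
than fitting them, so every ground truth is analytic:

- **expression breadth** per gene: round(lognormal(μ=2.5, σ=1.0)) clipped
  to [1, n] — median ≈ 12 expressing neurons per gene on the 302 panel,
  with the heavy right tail characteristic of neuropeptide genes;
  expressing sets are uniform random subsets, so without motifs
  E[W_ij] = Σ_c b_npp(c)·b_gpcr(c)/n² (tested against realized aggregates);
- **interactions**: ligands per receptor 1 + Poisson(1.6) (mean 2.6,
  matching the promiscuity of the deorphanized receptor set), EC50
  log-uniform over pM–µM, occasional extra peptide entries per gene pair;
- **anatomy**: 27 bundles; the pharynx holds ~6.6% of neurons (20/302) and
  is a closed single-bundle system; the nerve ring takes 60% of the
  remaining neurons (it is the dominant neuropil) and its members get 1–2
  of 4 strata; other bundles split 60/15/25 across head/midbody/tail, and
  each neuron may join one extra same-region bundle (p = 0.3);
- **planted motifs**: broadcaster/integrative couples (breadths 5 vs 120
  against the 50-neuron cutoff), enriched co-expression pairs (two
  non-cognate genes sharing an identical neuron set), an autocrine couple
  expressed in exactly m designated neurons, and a rich-club hub set h
  neurons wired through dedicated cognate couples expressed only within the
  set — coverage q per couple is solved so expected hub-to-hub edge
  coverage equals the requested wiring density.

What the generator does *not* emulate: correlated expression across related
genes, realistic bundle geometry or neuron lineages, anatomical
left/right symmetry, and EC50 structure within peptide families. Passing
the planted-recovery tests therefore demonstrates that the machinery
detects each motif class under controlled conditions, not that the real
nervous system's statistics are reproduced.

## Problem sizes and seeds

Property tests run at the sizes that make their oracles exhaustive (≤ 15
nodes for metric enumeration, ≤ 60-neuron panels for Fisher enumeration).
Planted-recovery checks use 60–302-neuron panels with 40–100 generator
seeds and 50-null ensembles — large enough for stable recovery rates while
keeping the suite and the acceptance script in the minutes range on one
CPU. Every stochastic operation takes an explicit seed; the pipeline
default is 42, echoed into the JSON report along with all parameters, and
the acceptance script derives all of its seeds from its `--seed` argument.

## Known limitations

- Expression calls are binary; graded expression and state-dependent
  transcription are out of scope.
- The spatial predicates are combinatorial, not physical: no diffusion
  PDEs, peptide lifetimes or concentration profiles.
- The mesoscale clustering depends on embedding hyperparameters; the
  distance-robustness harness quantifies, but does not remove, that
  dependence.
- Modularity maximization is intentionally absent: at the densities these
  networks reach it does not produce stable partitions, which is what
  motivates the connectivity-profile approach.
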