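# pepconn

Reconstruction and topological analysis of **neuropeptide ("wireless")
signaling connectomes** in the *C. elegans* nervous system.

Chemical synapses are only one channel of neuronal communication.
Neuropeptides released from dense-core vesicles diffuse through tissue and
activate G protein-coupled receptors (GPCRs) on neurons that may share no
synapse with the sender. `pepconn` infers this extrasynaptic network for the
302-neuron hermaphrodite nervous system by integrating three datasets:

1. a **binary gene × neuron expression matrix** (which neurons make each
   neuropeptide precursor, NPP, and each peptide GPCR),
2. a **ligand–receptor interaction table** from in vitro receptor
   activation assays, with EC50 potencies (a gene couple is kept when some
   peptide of the precursor activates the receptor at EC50 ≤ 500 nM by
   default, 100 nM as a sensitivity setting), and
3. **process anatomy** per neuron: membership in nerve fascicles (process
   bundles), body region, and nerve-ring strata.

For each gene couple *N* = (NPP, GPCR) the directed adjacency over neurons
*i*, *j* is

    A^N(i, j) = NPP^N(i) × GPCR^N(j)

optionally restricted by one of four diffusion models — `long` (anywhere),
`mid` (same body region, pharynx counted as head), `short` (same process
bundle, pharynx a separate system), `contact` (same nerve-ring stratum or
shared thin bundle). Summing the per-couple binary networks yields a
weighted aggregate connectome, W(i, j) = number of distinct NPP–GPCR
channels from *i* to *j*.

On top of the aggregate network the package computes:

- **degree, density K/(N²−N), directed transitivity, reciprocity**;
- **rich-club analysis**: Φ(k) = M_k / (N_k(N_k−1)) over nodes with total
  degree > k, normalized by degree-preserving edge-swap null ensembles
  (swap (A→B),(C→D) → (A→D),(C→B); 10·K attempted swaps, rejections
  resampled), with onset where Φ_norm(k) ≥ 1 + σ;
- **per-couple topology classes** (local / pervasive / broadcaster /
  integrative, by ligand vs receptor breadth at a 50-neuron cutoff) and the
  **minimal diffusion range** each receptor- or ligand-expressing neuron
  needs to reach a partner;
- **mesoscale cores**: t-SNE/PCA embedding of incoming-connectivity
  profiles, density-based clustering into cores plus a diffuse periphery,
  Kruskal–Wallis/Tukey group statistics on indegree;
- **co-expression structure**: one-sided Fisher exact enrichment of
  NPP–GPCR co-occurrence over the neuron panel with Benjamini–Hochberg FDR,
  the cascade network linking enriched pairs through ligand–receptor
  interactions, and **autocrine loops** (a neuron co-expressing a cognate
  couple) with their degree correlations.

A first-class synthetic-data generator (`pepconn.synthetic`) emulates all
three inputs with configurable breadth, promiscuity and anatomy
distributions and plants motifs with known signatures (broadcaster /
integrative couples, a rich-club hub set, enriched co-expressed pairs,
autocrine loops), so the entire pipeline is testable without any deposited
dataset.

## Worked example

```python
import pepconn as pc

# synthetic inputs at full scale with a planted 12-neuron rich club
cfg = pc.SynthConfig(n_neurons=60, n_npp=15, n_gpcr=15, seed=3,
                     breadth_log_mean=1.2, breadth_log_sigma=0.4,
                     rich_club_h=12)
expr, entries, ann, truth = pc.generate(cfg)

couples = pc.couples_at_threshold(entries, ec50_max=500e-9)
nets = [pc.build_pair_network(expr, c) for c in couples]
agg = pc.aggregate(nets, "long")
A = agg.binary()

print("couples:", len(couples), " density:", round(pc.density(A), 4))
nulls, _ = pc.degree_preserving_nulls(A, n=50, swaps_per_edge=10, seed=7)
rc = pc.rich_club(A, nulls, names=expr.roster.names)
print("rich-club onset k:", rc.onset_k, " members:", len(rc.members))
print("planted hubs recovered:",
      set(truth["rich_club_hubs"]) <= set(rc.members))
```

prints

```
couples: 37  density: 0.1438
rich-club onset k: 4  members: 51
planted hubs recovered: True
```

i.e. 37 gene couples survive the 500 nM cutoff, the aggregate network has
14.4% of possible directed edges, and the rich club that opens at total
degree 4 contains all 12 planted hub neurons, whose mutual wiring exceeds
the degree-matched null expectation.

The same pipeline runs end-to-end from files:

```sh
pepconn simulate --seed 4 --out sim/           # writes the three input CSVs
pepconn build --expression sim/expression.csv \
    --interactions sim/interactions.csv --anatomy sim/anatomy.csv \
    --ec50-max 500nM --model short --seed 42 --out run/
```

which leaves `run/report.json` (all stage outputs, parameters and hashes)
plus the aggregate network as edge list, adjacency CSV and GraphML.

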