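# phylosym

Phylosymbiosis analysis of host-associated microbiota: does the
compositional divergence of microbial communities mirror the phylogeny of
their hosts?

`phylosym` re-implements, as a tested and reusable pipeline, the analysis
design used in comparative fecal-microbiome surveys of closely related
host species (a handful of species, a few replicate samples each, 16S OTU
tables rarefied to a common depth):

- **Alpha diversity** per sample: observed OTUs, bias-corrected Chao1
  `S_obs + F1(F1-1)/(2(F2+1))`, Shannon `H = -Σ p_i log2 p_i` (bits),
  Simpson `1 - Σ p_i²`, equitability `H / log2 S_obs`, Good's coverage
  `1 - F1/N`; one-way ANOVA across host species.
- **Core-microbiota accounting**: OTUs present in every replicate of a
  species, their share of the species' OTU richness and of each sample's
  reads, and UpSet-style exclusive intersection counts between species.
- **Beta diversity**: Jaccard dissimilarity
  `d = 1 - |A∩B| / |A∪B|` on presence/absence, unweighted and weighted
  UniFrac against an OTU phylogeny, principal coordinates analysis.
- **Phylosymbiosis test**: a UPGMA dendrogram of per-species community
  profiles is scored against the host phylogeny with the rooted
  Robinson–Foulds distance (symmetric difference of cluster sets) and the
  Matching Cluster distance (minimum-weight perfect matching between
  cluster sets, weight `|C₁ Δ C₂|`). Significance comes from the
  distribution of those distances over random bifurcating topologies —
  exact enumeration of all `(2n-3)!!` labeled topologies for `n ≤ 9`
  leaves, or a uniform Monte-Carlo sample (default 80,000 draws).
  Normalized scores (nRF, nMC) scale 0 (identical) to 1 (maximally
  incongruent).
- **Matrix/grouping tests**: Mantel (host genetic distance vs community
  dissimilarity, 9,999 permutations) and ANOSIM (999 permutations) at
  species, genus and tribe level; Spearman co-occurrence among core
  genera.
- **Synthetic codivergence generator**: host trees (Yule) plus OTU tables
  whose presence/absence evolves along the host tree under a two-state
  gain/loss Markov process, with a phylosymbiosis-strength dial `s`
  (`s = 1` pure codivergence, `s = 0` an exact null). Every stage of the
  pipeline is testable without external sequencing data.

## Worked example

Simulate a seven-species study (three fecal replicates per species,
rarefied depth 9,683 reads) with strong but imperfect phylosymbiosis
signal, then run the full analysis:

```bash
phylosym simulate --out demo --seed 5 --signal 0.9
phylosym run --config demo.yaml --out demo_out
```

with `demo.yaml`:

```yaml
otu_table: demo/otu_table.tsv
metadata: demo/metadata.tsv
host_tree: demo/host_tree.nwk
depth: 9000
seed: 4
```

This prints (numbers from this exact invocation):

```
phylosym analysis summary
=========================

samples: 21  OTUs (post-rarefaction): 1985
congruence RF: raw=6 nRF=0.6 p=0.04089 (exact, null=10395)
congruence MC: raw=9 nMC=0.4091 p=0.08398 (exact, null=10395)
mantel (host distance vs Jaccard): r=0.8663 p=0.0013 (9999 permutations)
anosim/UniFrac: skipped (no OTU tree)
```

Reading it: the microbiota dendrogram shares some but not all clusters
with the host tree (raw RF 6 of a possible 10, nRF 0.6), and about 4.1%
of the 10,395 possible seven-leaf topologies are at least that close to
the host tree — congruence beyond what random branching patterns produce,
though incomplete, exactly the regime such comparative surveys report.
The Mantel test gives the sharper verdict: host genetic distance and
community Jaccard dissimilarity correlate at r = 0.87 (p ≈ 0.001).
`demo_out/` holds the full machine-readable report (`report.json`,
per-stage TSVs, newick trees).

The same operations are available as library functions
(`phylosym.congruence_test`, `phylosym.mantel`, `phylosym.upgma`, ...)
and as focused subcommands (`alpha`, `beta`, `congruence`, `mantel`,
`anosim`).

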