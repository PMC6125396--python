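# Methods

This note documents the models, conventions and design choices behind
`phylosym`, in the spirit of the methods documentation of the simulation
and statistics packages it builds on.

## The question and the test

Phylosymbiosis is the pattern in which the compositional relationships of
host-associated microbial communities mirror the phylogeny of their
hosts. Given an OTU table (samples × OTUs), per-sample host metadata and
a rooted host phylogeny, the pipeline asks two complementary questions:

1. **Matrix association** — do pairwise host genetic distances correlate
   with pairwise community dissimilarities? (Mantel test.)
2. **Topological congruence** — does a dendrogram built from community
   dissimilarities share clusters with the host tree beyond chance?
   (Robinson–Foulds and Matching Cluster scores against a
   random-topology null.)

## Community distances and the dendrogram

Replicate samples are collapsed to one profile per host species before
dendrogram construction (default: mean of replicate relative-abundance
vectors, re-scaled to integer pseudo-counts at the mean sample depth with
presence preserved; `pooled` raw-count summation is available and gives
identical presence/absence when no replicate drops an OTU). Jaccard
dissimilarity on presence/absence feeds UPGMA — size-weighted
average-linkage agglomeration with node height equal to half the merge
distance, hence an ultrametric dendrogram whose cophenetic distances
reproduce ultrametric inputs exactly. Ties in merge distance are broken
toward the lexicographically smallest label pair, so the output is
deterministic.

UniFrac (unweighted and weighted) is computed by scikit-bio against a
rooted OTU phylogeny; weighted UniFrac is reported raw (unnormalized) by
default, with the standard normalization behind a flag. Principal
coordinates analysis uses classical scaling with no negative-eigenvalue
correction; axis signs are canonicalized (first nonzero loading
positive) for reproducibility.

## Tree distances and the null model

Both congruence metrics operate on the non-trivial proper clusters of a
rooted tree (leaf sets below internal nodes, excluding the root's full
set and singletons; a bifurcating tree on `n` leaves has `n − 2`):

- **RF** — the symmetric difference of the two cluster sets, normalized
  by its maximum `2(n − 2)` so nRF ∈ [0, 1].
- **MC** — the minimum total membership disagreement `Σ |C₁ Δ C₂|` over
  one-to-one matchings of the cluster lists (padded with empty clusters
  when lengths differ), solved as a linear assignment problem. The
  normalizer is the metric's true maximum over topology pairs, found by
  exact enumeration for `n ≤ 9` (reduced by label symmetry: one tree
  ranges over unlabeled shapes only); beyond that the analytic bound
  `(n − 2)(n − 1)` is used and the result records which normalizer
  applied. Published normalizations of MC vary; results therefore always
  carry the raw score alongside.

The null distribution is the distance from the host tree to uniformly
random labeled rooted bifurcating topologies. The sampler inserts leaf
`k` on any of the current `2k − 1` edges (including above the root) with
equal probability, which yields the uniform distribution over all
`(2n − 3)!!` topologies; for `n ≤ 9` the null is computed exactly by full
enumeration (10,395 topologies at `n = 7`), otherwise by Monte-Carlo
(default 80,000 draws). The p-value is the probability that a random
topology is *as close or closer* to the host tree than the observed
dendrogram (ties count toward the tail), reported as the plain proportion
`k/N`; a conservative `(k+1)/(N+1)` variant is behind a flag. Internally
clusters are integer bitmasks over a shared leaf ordering, making the
matching weight a popcount of an XOR; an 80,000-draw MC null at `n = 7`
takes a few seconds.

## Permutation tests

- **Mantel**: Pearson correlation (Spearman behind a flag) over
  upper-triangle entries; the null jointly permutes rows and columns of
  one matrix; one-sided for positive association.
- **ANOSIM**: Clarke's `R = (r̄_B − r̄_W) / (M/2)` with `M = n(n−1)/2`
  pairwise distances ranked with average ranks for ties; label
  permutation null, one-sided for `R` at least the observed. `R ∈ [−1, 1]`
  and is invariant to monotone transforms of the distances.
- Both report plain `k/N` p-values by default (add-one variant by flag),
  record their seed and permutation count, and are bit-reproducible.
  Repeated ANOSIM comparisons at species/genus/tribe level are reported
  without multiplicity correction, and the report says so implicitly by
  listing each level separately.
- **One-way ANOVA** on alpha-diversity indices across host species is the
  classical F test with p from the F distribution.

Alpha-diversity conventions follow the legacy-QIIME toolchain the study
design presumes: Shannon and equitability in base 2 (the only base
consistent with equitability = H / log2 S_obs), Simpson as `1 − Σp²`,
Chao1 bias-corrected (`F₂ + 1` denominator, defined when doubletons are
absent), Good's coverage `1 − F₁/N`. Empty samples report missing values,
never zeros. Rarefaction is sampling without replacement (multivariate
hypergeometric), with an explicit seed and no hidden global state;
samples below the target depth are dropped, not padded, and OTUs reduced
to zero total are pruned by default so presence/absence metrics see the
rarefied support.

## The synthetic codivergence generator

The generator emulates the target study design end to end: `n_species`
(7) host species on a Yule tree scaled to unit height, `n_replicates`
(3) fecal replicates per species, `depth` (9,683) reads per sample,
`n_otus` (2,000) OTUs with seven-rank synthetic taxonomy (a fraction
truncated below family/genus to exercise unclassified pooling).

Each OTU's presence evolves along the host tree as a two-state Markov
process with `gain_rate` and `loss_rate` per unit branch length (defaults
0.25/0.25: total rate 0.5 per unit height balances the resolvability of
shallow against deep divergences — faster rates saturate, erasing deep
signal; slower rates leave shallow splits unresolved). The root state is
stationary. The phylosymbiosis dial `s` (default 0.8, mirroring the
strong-but-incomplete congruence such surveys report) leaves each OTU's
species pattern intact with probability `s` and otherwise shuffles it
uniformly across species — so `s = 0` is an *exact* null in which species
labels are exchangeable, and `s = 1` is pure codivergence. Present
(OTU, species) pairs receive log-normal(0, `abundance_sigma`) mean
abundances (default σ = 1.5, a realistically heavy-tailed community);
replicates drop each present OTU independently with probability
`replicate_dropout` (default 0.1) and draw reads multinomially.

Presence, not abundance, carries the phylogenetic signal, because the
headline analyses (Jaccard, unweighted UniFrac, UPGMA + RF/MC) are
presence/absence-driven.

**Host-tree resolvability.** `simulate_host_tree` rejection-samples Yule
trees until all internal node heights are pairwise separated by
`min_height_gap` (default 0.05 on the unit-height scale). Unconstrained
Yule trees frequently place two divergence events so close together that
no finite OTU sample can order them — with a few thousand OTUs the
sampling noise on a Jaccard estimate is roughly 0.006, and node-height
gaps below ~0.05 fall under it. A tree failing that separation measures
tree geometry, not pipeline correctness, and real host radiations used
for phylosymbiosis testing are well-resolved. Set `min_height_gap=0` for
the raw Yule draw.

**What the generator does not emulate:** read-level error, chimeras,
compositional correlations among OTUs, abundance evolution along the
tree, environmental covariates, and uneven sequencing depth. Passing
tests therefore demonstrate correctness and calibration of the
*inference machinery* under a clean codivergence model, not robustness
to every artifact of real amplicon data.

## Experiment sizes and numerical choices

The test suite and the acceptance script use: exact topology enumeration
at 7 leaves (10,395 topologies); 80,000-draw Monte-Carlo nulls checked
against the exact tail at three distance levels; 150,000 draws for the
uniformity test over the 15 four-leaf topologies; 100 random ultrametric
trees (5–9 leaves) for the UPGMA round trip; 500 null simulations each
for Mantel and ANOSIM type-I error (199 permutations, α = 0.05); 100
seeds at `s = 1` and 200 at `s = 0` for power/calibration, under a
low-noise configuration (no dropout, σ = 0.25, an 8,000-OTU pool at the
scale of such a study's total richness, which lowers presence-sampling
noise). The power experiment fixes one host tree across seeds — matching
a real study, where a single host phylogeny is the truth — while the
`s = 0` calibration redraws the host per seed to sample the null
ensemble.

Numerical conventions: distances validated symmetric with zero diagonal;
Jaccard between two empty samples defined as 0 with a warning; UniFrac
refuses OTUs absent from the tree and prunes extra leaves; Spearman
co-occurrence p-values are exact by enumeration for n ≤ 9 observations,
t-approximate beyond; constant vectors yield undefined (NaN)
correlations rather than arbitrary values. A single pipeline seed fans
out to per-stage seeds by hashing the stage name, so any stage can be
reproduced in isolation and a rerun with the same config is byte-identical
in every machine-readable output.

## Known limitations

- The MC normalizer beyond 9 leaves is an upper bound, so nMC is
  conservative there (raw values remain exact).
- The exact congruence null is limited to 9 leaves by `(2n − 3)!!`
  growth; Monte-Carlo mode covers larger trees.
- `k/N` permutation p-values can be 0 when no permutation reaches the
  observed statistic; use the add-one flag where a strictly positive
  p-value is required.
- ANOSIM and Mantel assume exchangeability of labels/objects under the
  null; replicate structure is not nested into the permutation scheme
  (species-level profiles avoid pseudo-replication in the congruence and
  Mantel paths).
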