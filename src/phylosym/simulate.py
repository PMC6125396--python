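"""Synthetic host-microbiome codivergence generator.

Emulates the study design this package analyzes: a handful of related host
species (default 7) sampled with a few fecal replicates each (default 3),
rarefied to a common read depth, with thousands of OTUs whose
presence/absence carries a host-phylogenetic signal.

The generative model:

1. A Yule (pure-birth) host tree with unit height, leaves ``sp1..spN``.
2. Each OTU's presence evolves along that tree as a two-state Markov
   process with per-branch-length ``gain_rate`` / ``loss_rate``; the root
   state is drawn at the stationary frequency gain/(gain+loss).
3. With probability ``1 - signal_strength`` an OTU's species presence
   pattern is shuffled uniformly across species, destroying its host
   structure. ``s = 1`` is pure codivergence; ``s = 0`` is an exact null
   in which species labels are exchangeable.
4. Present (OTU, species) pairs get log-normal(0, ``abundance_sigma``)
   mean abundances; each replicate drops every present OTU independently
   with probability ``replicate_dropout``, renormalizes, and draws reads
   multinomially at ``depth``.

Presence (not abundance) carries the phylogenetic signal because the
analyses this feeds — Jaccard, unweighted UniFrac, UPGMA + RF/MC — are
presence/absence-driven.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .otu import OtuTable

__all__ = [
    "SimulationConfig",
    "simulate_host_tree",
    "simulate_microbiota",
    "null_relabel",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the codivergence generator (defaults mirror the emulated
    study design: 7 species x 3 replicates rarefied to 9,683 reads)."""

    n_species: int = 7
    n_replicates: int = 3
    n_otus: int = 2000
    depth: int = 9683
    signal_strength: float = 0.8
    gain_rate: float = 2.0
    loss_rate: float = 1.0
    abundance_sigma: float = 1.5
    replicate_dropout: float = 0.1
    unassigned_prob: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


def simulate_host_tree(
    n_species: int, seed=None, min_height_gap: float = 0.05
) -> TreeNode:
    """Yule (pure-birth) ultrametric host tree scaled to unit height,
    leaves labeled ``sp1..spN``.

    ``min_height_gap`` rejection-samples until every pair of internal node
    heights (unit-height scale) is at least that far apart, emulating a
    well-resolved radiation: topology recovery from community data is only
    identifiable when divergence events are separated by more than the
    sampling noise. Set 0 for the unconstrained Yule draw. Sampling is
    deterministic given ``seed``; after 1000 rejections the best-separated
    candidate is returned.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    best, best_gap = None, -1.0
    for _ in range(1000):
        tree, heights = _yule_once(n_species, rng)
        gap = (
            min(b - a for a, b in zip(heights, heights[1:]))
            if len(heights) > 1
            else 1.0
        )
        if gap >= min_height_gap:
            return tree
        if gap > best_gap:
            best, best_gap = tree, gap
    return best


def _yule_once(n_species: int, rng) -> tuple[TreeNode, list[float]]:
    root = TreeNode()
    # active lineages: (parent node, height at which the lineage started)
    active = [(root, 0.0), (root, 0.0)]
    height = 0.0
    split_heights = []
    while len(active) < n_species:
        height += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        parent, start = active.pop(idx)
        node = TreeNode(length=height - start)
        parent.append(node)
        active.append((node, height))
        active.append((node, height))
        split_heights.append(height)
    total = height + rng.exponential(1.0 / len(active))
    for i, (parent, start) in enumerate(active, start=1):
        parent.append(TreeNode(name=f"sp{i}", length=total - start))
    for node in root.traverse(include_self=False):
        node.length /= total
    # sorted internal node heights on the unit scale (root at 0)
    heights = sorted([0.0] + [h / total for h in split_heights])
    return root, heights


def _branch_presence(
    parent_state: np.ndarray, length: float, gain: float, loss: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One step of the two-state Markov process along a branch, vectorized
    over OTUs."""
    rate = gain + loss
    if rate == 0:
        return parent_state.copy()
    pi1 = gain / rate
    decay = np.exp(-rate * length)
    p_one = np.where(parent_state, pi1 + (1 - pi1) * decay, pi1 * (1 - decay))
    return rng.random(parent_state.shape) < p_one


def _evolve_presence(
    host: TreeNode, n_otus: int, gain: float, loss: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Presence matrix (species x OTUs) from the Markov process on the
    host tree."""
    rate = gain + loss
    pi1 = gain / rate if rate > 0 else 0.0
    states: dict[int, np.ndarray] = {}
    root = host
    states[id(root)] = rng.random(n_otus) < pi1
    leaf_rows = {}
    for node in root.preorder(include_self=False):
        parent_state = states[id(node.parent)]
        state = _branch_presence(parent_state, node.length or 0.0, gain, loss, rng)
        if node.is_tip():
            leaf_rows[node.name] = state
        else:
            states[id(node)] = state
    species = sorted(leaf_rows)
    return pd.DataFrame(
        np.array([leaf_rows[s] for s in species]), index=species,
        columns=[f"otu{i + 1}" for i in range(n_otus)],
    )


def _synthetic_taxonomy(otu_ids, unassigned_prob: float, rng) -> pd.Series:
    """Nested seven-rank lineage strings; a fraction is truncated below
    the family or genus rank to exercise unclassified pooling."""
    n = len(otu_ids)
    phyla = rng.integers(1, 7, size=n)
    classes = phyla * 10 + rng.integers(1, 3, size=n)
    orders = classes * 10 + rng.integers(1, 3, size=n)
    families = orders * 10 + rng.integers(1, 4, size=n)
    genera = families * 10 + rng.integers(1, 4, size=n)
    cut = rng.random(n)
    rows = []
    for i in range(n):
        parts = [
            "k__Bacteria", f"p__Phylum{phyla[i]}", f"c__Class{classes[i]}",
            f"o__Order{orders[i]}", f"f__Family{families[i]}",
            f"g__Genus{genera[i]}", f"s__",
        ]
        if cut[i] < unassigned_prob / 2:
            parts = parts[:4]  # unassigned from family down
        elif cut[i] < unassigned_prob:
            parts = parts[:5]  # unassigned from genus down
        rows.append(";".join(parts))
    return pd.Series(rows, index=otu_ids, name="taxonomy")


def simulate_microbiota(host: TreeNode, cfg: SimulationConfig) -> OtuTable:
    """OTU table for the species on ``host`` under the codivergence model.

    Sample ids are ``<species>_r<k>``; metadata carries host_species,
    genus (one per species here), tribe (the two clades under the host
    root), and replicate number. Row sums equal ``cfg.depth`` exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    presence = _evolve_presence(
        host, cfg.n_otus, cfg.gain_rate, cfg.loss_rate, rng
    )
    species = list(presence.index)
    n_sp = len(species)

    # signal dial: shuffle a (1-s) fraction of OTU patterns across species
    shuffle_mask = rng.random(cfg.n_otus) >= cfg.signal_strength
    pres = presence.to_numpy()
    for j in np.flatnonzero(shuffle_mask):
        pres[:, j] = pres[rng.permutation(n_sp), j]

    abundance = np.exp(
        rng.normal(0.0, cfg.abundance_sigma, size=pres.shape)
    ) * pres

    # tribes = the two clades under the host root (emulates the two host
    # tribes of the study design)
    children = host.children
    tribe_of = {}
    for ci, child in enumerate(children, start=1):
        for tip in [child] if child.is_tip() else child.tips():
            tribe_of[tip.name] = f"tribe{ci}"

    rows, sample_ids, meta_rows = [], [], []
    for si, sp in enumerate(species):
        for rep in range(1, cfg.n_replicates + 1):
            profile = abundance[si].copy()
            if cfg.replicate_dropout > 0:
                keep = rng.random(cfg.n_otus) >= cfg.replicate_dropout
                profile *= keep
            total = profile.sum()
            if total == 0:  # degenerate replicate: fall back to uniform
                profile = np.ones(cfg.n_otus)
                total = float(cfg.n_otus)
            rows.append(rng.multinomial(cfg.depth, profile / total))
            sample_ids.append(f"{sp}_r{rep}")
            meta_rows.append(
                dict(host_species=sp, genus=f"genus_{sp}",
                     tribe=tribe_of[sp], replicate=str(rep))
            )
    counts = pd.DataFrame(
        np.array(rows, dtype=np.int64), index=sample_ids,
        columns=list(presence.columns),
    )
    metadata = pd.DataFrame(meta_rows, index=sample_ids)
    taxonomy = _synthetic_taxonomy(
        list(presence.columns), cfg.unassigned_prob, rng
    )
    return OtuTable(counts=counts, taxonomy=taxonomy, metadata=metadata)


def null_relabel(table: OtuTable, seed=None, permutation=None) -> OtuTable:
    """Permute which host species each species-block of samples belongs to;
    counts are untouched. This is an exact null for host-association tests.

    ``permutation`` (optional) is an explicit mapping
    ``{old_species: new_species}``; otherwise a uniform permutation is
    drawn from ``seed``.
    """
    species = sorted(table.metadata["host_species"].unique())
    if permutation is None:
        rng = np.random.default_rng(seed)
        target = [species[i] for i in rng.permutation(len(species))]
        permutation = dict(zip(species, target))
    # species-level attributes travel with the new species identity
    attrs = {}
    for sp in species:
        row = table.metadata[table.metadata["host_species"] == sp].iloc[0]
        attrs[sp] = {
            c: row[c] for c in table.metadata.columns if c != "replicate"
        }
    meta = table.metadata.copy()
    for old_sp, new_sp in permutation.items():
        block = table.metadata["host_species"] == old_sp
        for col, val in attrs[new_sp].items():
            meta.loc[block, col] = val
    return OtuTable(counts=table.counts, taxonomy=table.taxonomy, metadata=meta)
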