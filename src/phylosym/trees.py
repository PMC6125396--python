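"""Dendrograms and host-tree congruence.

This module carries the phylosymbiosis test proper: build a UPGMA
dendrogram from a community dissimilarity matrix, score its topological
agreement with the host phylogeny by the rooted Robinson-Foulds (RF) and
Matching Cluster (MC) distances, and calibrate the observed score against
the distribution of those distances over random bifurcating topologies —
either an exact enumeration of all (2n-3)!! labeled rooted topologies
(feasible for n <= 9 leaves) or a uniform Monte-Carlo sample.

Both distances operate on the *clusters* of a rooted tree: the leaf sets
below internal nodes, excluding the root's full set and singletons. RF is
the size of the symmetric difference of the two cluster sets; MC is the
minimum total membership disagreement over a one-to-one matching of the
cluster lists (padded with empty clusters when sizes differ), solved as a
linear assignment problem.

Clusters are represented internally as integer bitmasks over a shared leaf
ordering, which makes the symmetric-difference weight a popcount of an XOR
and keeps 80,000-draw nulls cheap.

Public trees are :class:`skbio.TreeNode`; newick IO goes through it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import linear_sum_assignment
from skbio import DistanceMatrix, TreeNode

MAX_EXACT_LEAVES = 9  # (2n-3)!! = 135,135 at n = 9; refuse beyond


def double_factorial_topologies(n: int) -> int:
    """(2n-3)!!, the number of labeled rooted bifurcating topologies."""
    if n < 2:
        raise ValueError("need at least 2 leaves")
    out = 1
    for k in range(3, 2 * n - 2, 2):
        out *= k
    return out


# -- clusters ------------------------------------------------------------------


def leaf_labels(tree: TreeNode) -> list[str]:
    labels = [t.name for t in tree.tips()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels")
    return labels


def clusters(tree: TreeNode) -> set[frozenset]:
    """Non-trivial proper clusters: one leaf set per internal node,
    excluding the root's full leaf set and singletons."""
    full = frozenset(leaf_labels(tree))
    out = set()
    for node in tree.non_tips(include_self=True):
        c = frozenset(t.name for t in node.tips())
        if 1 < len(c) < len(full):
            out.add(c)
    return out


def _cluster_masks(tree: TreeNode, index: dict[str, int]) -> list[int]:
    """Cluster bitmasks under a shared leaf->bit index (root/singletons
    excluded). Returned sorted for determinism."""
    full = (1 << len(index)) - 1
    masks = []
    for node in tree.non_tips(include_self=True):
        m = 0
        for t in node.tips():
            m |= 1 << index[t.name]
        if m != full and m.bit_count() > 1:
            masks.append(m)
    return sorted(masks)


def _shared_index(t1: TreeNode, t2: TreeNode) -> dict[str, int]:
    l1, l2 = set(leaf_labels(t1)), set(leaf_labels(t2))
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}"
        )
    return {name: i for i, name in enumerate(sorted(l1))}


# -- RF ------------------------------------------------------------------------


def _rf_raw(masks1: list[int], masks2: list[int]) -> int:
    s1, s2 = set(masks1), set(masks2)
    return len(s1 ^ s2)


def rf_distance(t1: TreeNode, t2: TreeNode) -> tuple[int, float]:
    """Rooted Robinson-Foulds distance: (raw, normalized).

    Raw is the symmetric difference of the cluster sets; normalized divides
    by 2(n-2), the maximum over bifurcating topology pairs on n leaves, and
    is clamped to [0, 1] (multifurcating inputs have fewer clusters, never
    more).
    """
    index = _shared_index(t1, t2)
    raw = _rf_raw(_cluster_masks(t1, index), _cluster_masks(t2, index))
    n = len(index)
    denom = 2 * (n - 2)
    norm = min(raw / denom, 1.0) if denom > 0 else 0.0
    return raw, norm


# -- MC ------------------------------------------------------------------------


def _mc_raw(masks1: list[int], masks2: list[int]) -> int:
    """Minimum-weight perfect matching between two cluster lists, padded
    with empty clusters; weight = |C1 xor C2| membership disagreements."""
    k = max(len(masks1), len(masks2))
    if k == 0:
        return 0
    a = masks1 + [0] * (k - len(masks1))
    b = masks2 + [0] * (k - len(masks2))
    cost = np.array(
        [[(x ^ y).bit_count() for y in b] for x in a], dtype=np.int64
    )
    rows, cols = linear_sum_assignment(cost)
    return int(cost[rows, cols].sum())


@lru_cache(maxsize=None)
def max_mc(n: int) -> tuple[int, str]:
    """Maximum MC distance over pairs of rooted bifurcating topologies on
    n leaves: exact (enumerated) for n <= 9, else the analytic upper bound
    (n-2)(n-1). Returns (value, "exact" | "bound").

    The enumeration exploits label symmetry: relabeling both trees jointly
    preserves MC, so the first tree only ranges over distinct unlabeled
    shapes while the second ranges over all labeled topologies.
    """
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if n <= 3:
        # all topologies on <= 3 leaves are one NNI apart: max is 2 for n=3
        return (0, "exact") if n == 2 else (2, "exact")
    if n > MAX_EXACT_LEAVES:
        return (n - 2) * (n - 1), "bound"
    all_masks = [_nested_masks(t, n) for t in _enumerate_nested(n)]
    shapes = {}
    for t in _enumerate_nested(n):
        shapes.setdefault(_nested_shape(t), t)
    best = 0
    for rep in shapes.values():
        m1 = _nested_masks(rep, n)
        for m2 in all_masks:
            d = _mc_raw(m1, m2)
            if d > best:
                best = d
    return best, "exact"


def mc_distance(t1: TreeNode, t2: TreeNode) -> tuple[int, float]:
    """Matching Cluster distance: (raw, normalized).

    Raw is the optimal-assignment total membership disagreement between the
    two cluster lists; normalized divides by the metric's maximum over tree
    pairs with the same leaf count (exact for n <= 9).
    """
    index = _shared_index(t1, t2)
    raw = _mc_raw(_cluster_masks(t1, index), _cluster_masks(t2, index))
    denom, _ = max_mc(len(index))
    norm = min(raw / denom, 1.0) if denom > 0 else 0.0
    return raw, norm


# -- nested-topology engine ----------------------------------------------------
#
# A topology over leaf bits 0..n-1 is either an int (leaf) or a 2-tuple of
# topologies. This is the fast representation behind topology enumeration,
# uniform sampling, and the congruence null; TreeNode conversion happens at
# the API boundary.


def _nested_masks(t, n: int) -> list[int]:
    full = (1 << n) - 1
    masks = []

    def walk(node) -> int:
        if isinstance(node, int):
            return 1 << node
        m = walk(node[0]) | walk(node[1])
        if m != full and m.bit_count() > 1:
            masks.append(m)
        return m

    walk(t)
    return sorted(masks)


def _nested_shape(t):
    if isinstance(t, int):
        return 1
    a, b = _nested_shape(t[0]), _nested_shape(t[1])
    return tuple(sorted((a, b), key=repr))


def _insert_leaf(t, edge_path, leaf):
    """Return a copy of t with `leaf` attached along the edge addressed by
    edge_path (a tuple of 0/1 child choices; empty = above the root)."""
    if not edge_path:
        return (t, leaf)
    head, rest = edge_path[0], edge_path[1:]
    children = list(t)
    children[head] = _insert_leaf(children[head], rest, leaf)
    return tuple(children)


def _edges(t, prefix=()):
    """All edge addresses of nested topology t, including the root edge."""
    yield prefix
    if not isinstance(t, int):
        yield from _edges(t[0], prefix + (0,))
        yield from _edges(t[1], prefix + (1,))


def _enumerate_nested(n: int):
    """Every labeled rooted bifurcating topology on leaves 0..n-1, once."""

    def rec(k):
        if k == 2:
            yield (0, 1)
            return
        for smaller in rec(k - 1):
            for path in _edges(smaller):
                yield _insert_leaf(smaller, path, k - 1)

    yield from rec(n)


def _random_nested(n: int, rng: np.random.Generator):
    """Uniform draw over the (2n-3)!! labeled rooted topologies by
    sequential insertion: leaf k attaches to any of the 2k-1 edges
    (including above the root) with equal probability."""
    t = (0, 1)
    for k in range(2, n):
        paths = list(_edges(t))  # 2k-1 of them
        t = _insert_leaf(t, paths[rng.integers(len(paths))], k)
    return t


def _nested_to_treenode(t, labels: list[str]) -> TreeNode:
    def build(node) -> TreeNode:
        if isinstance(node, int):
            return TreeNode(name=labels[node])
        return TreeNode(children=[build(node[0]), build(node[1])])

    return build(t)


def random_topology(leaves: list[str], rng) -> TreeNode:
    """Uniformly random labeled rooted bifurcating topology (no branch
    lengths). ``rng`` is a numpy Generator or a seed."""
    leaves = list(leaves)
    if len(leaves) < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(rng)
    return _nested_to_treenode(_random_nested(len(leaves), rng), leaves)


def enumerate_topologies(leaves: list[str]):
    """Iterate every labeled rooted bifurcating topology exactly once.

    Refuses n > 9 — the count (2n-3)!! explodes; use Monte-Carlo sampling
    (random_topology / congruence_test monte_carlo mode) instead.
    """
    leaves = list(leaves)
    n = len(leaves)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if n > MAX_EXACT_LEAVES:
        raise ValueError(
            f"exact enumeration limited to {MAX_EXACT_LEAVES} leaves "
            f"((2n-3)!! is {double_factorial_topologies(n)} at n={n}); "
            "use Monte-Carlo sampling"
        )
    for t in _enumerate_nested(n):
        yield _nested_to_treenode(t, leaves)


# -- UPGMA ---------------------------------------------------------------------


def upgma(dm: DistanceMatrix) -> TreeNode:
    """UPGMA dendrogram: size-weighted average-linkage agglomeration.

    Node height is half the merge distance, so the tree is ultrametric and
    its cophenetic distances reproduce ultrametric inputs exactly. Ties in
    the merge distance are broken toward the lexicographically smallest
    (label, label) pair, making the output deterministic.
    """
    ids = list(dm.ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 labels")
    d = {
        (a, b): float(dm[a, b]) for a, b in itertools.combinations(ids, 2)
    }

    def dist(a, b):
        return d[(a, b)] if (a, b) in d else d[(b, a)]

    nodes = {name: TreeNode(name=name) for name in ids}
    heights = {name: 0.0 for name in ids}
    sizes = {name: 1 for name in ids}
    # cluster key: lexicographically smallest member label (stable tie-break)
    active = sorted(ids)
    while len(active) > 1:
        best = min(
            (dist(a, b), a, b)
            for a, b in itertools.combinations(active, 2)
        )
        dd, a, b = best
        h = dd / 2.0
        child_a, child_b = nodes[a], nodes[b]
        child_a.length = h - heights[a]
        child_b.length = h - heights[b]
        parent = TreeNode(children=[child_a, child_b])
        for other in active:
            if other in (a, b):
                continue
            new = (
                sizes[a] * dist(a, other) + sizes[b] * dist(b, other)
            ) / (sizes[a] + sizes[b])
            d[(a, other)] = new
            d.pop((other, a), None)
        key = min(a, b)
        nodes[key] = parent
        heights[key] = h
        sizes[key] = sizes[a] + sizes[b]
        drop = max(a, b)
        active.remove(drop)
        nodes.pop(drop, None)
    root = nodes[active[0]]
    root.length = None
    return root


def cophenetic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Pairwise patristic (branch-length path) distances between leaves."""
    labels = sorted(leaf_labels(tree))
    return DistanceMatrix(tree.tip_tip_distances(endpoints=labels).data, ids=labels)


def is_ultrametric(tree: TreeNode, tol: float = 1e-9) -> bool:
    depths = []
    for tip in tree.tips():
        dsum = 0.0
        node = tip
        while node.parent is not None:
            dsum += node.length or 0.0
            node = node.parent
        depths.append(dsum)
    return max(depths) - min(depths) <= tol


# -- congruence test -----------------------------------------------------------


@dataclass
class CongruenceResult:
    """Host-tree vs dendrogram congruence under a random-topology null.

    ``observed`` is the raw RF or MC distance; ``normalized`` rescales it
    to [0, 1] (0 = identical topology, 1 = maximally incongruent);
    ``p_value`` is the probability that a uniformly random bifurcating
    topology is at least as close to the host tree as the dendrogram is
    ("equivalent or more congruent": distance <= observed).
    """

    metric: str
    observed: int
    normalized: float
    null_size: int
    null_mean: float
    null_sd: float
    p_value: float
    mode: str
    seed: object = None
    normalizer: str = "exact"
    n_leaves: int = 0

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "observed": self.observed,
            "normalized": self.normalized,
            "null_size": self.null_size,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p_value": self.p_value,
            "mode": self.mode,
            "seed": self.seed,
            "normalizer": self.normalizer,
            "n_leaves": self.n_leaves,
        }


def _metric_fn(metric: str):
    metric = metric.lower()
    if metric == "rf":
        return _rf_raw
    if metric == "mc":
        return _mc_raw
    raise ValueError(f"unknown metric {metric!r} (expected 'rf' or 'mc')")


@lru_cache(maxsize=4)
def _exact_null_masks(n: int) -> tuple:
    return tuple(_nested_masks(t, n) for t in _enumerate_nested(n))


def null_distances(
    host: TreeNode,
    metric: str = "rf",
    mode: str = "exact",
    n_random: int = 80_000,
    seed=None,
) -> np.ndarray:
    """Distances from the host tree to null topologies: every topology
    (exact mode, n <= 9) or ``n_random`` uniform draws (monte_carlo)."""
    index = {name: i for i, name in enumerate(sorted(leaf_labels(host)))}
    host_masks = _cluster_masks(host, index)
    n = len(index)
    fn = _metric_fn(metric)
    if mode == "exact":
        if n > MAX_EXACT_LEAVES:
            raise ValueError(f"exact null limited to {MAX_EXACT_LEAVES} leaves")
        return np.array(
            [fn(host_masks, m) for m in _exact_null_masks(n)], dtype=np.int64
        )
    rng = np.random.default_rng(seed)
    out = np.empty(n_random, dtype=np.int64)
    for i in range(n_random):
        out[i] = fn(host_masks, _nested_masks(_random_nested(n, rng), n))
    return out


def congruence_test(
    host: TreeNode,
    dendrogram: TreeNode,
    metric: str = "rf",
    n_random: int = 80_000,
    mode: str = "auto",
    seed=None,
    add_one: bool = False,
) -> CongruenceResult:
    """Test whether a microbiota dendrogram is more congruent with the host
    phylogeny than random bifurcating topologies are.

    The p-value is the fraction of null topologies whose distance to the
    host tree is <= the observed distance (ties count toward the tail). In
    ``exact`` mode the null is the full enumeration over all (2n-3)!!
    topologies; ``monte_carlo`` samples ``n_random`` of them uniformly;
    ``auto`` picks exact whenever n <= 9. ``add_one`` switches the
    Monte-Carlo estimate to the conservative (k+1)/(N+1) convention.
    """
    index = _shared_index(host, dendrogram)
    n = len(index)
    if mode == "auto":
        mode = "exact" if n <= MAX_EXACT_LEAVES else "monte_carlo"
    if mode not in ("exact", "monte_carlo"):
        raise ValueError(f"unknown mode {mode!r}")
    fn = _metric_fn(metric)
    observed = fn(_cluster_masks(host, index), _cluster_masks(dendrogram, index))
    null = null_distances(host, metric=metric, mode=mode, n_random=n_random, seed=seed)
    k = int((null <= observed).sum())
    if mode == "monte_carlo" and add_one:
        p = (k + 1) / (len(null) + 1)
    else:
        p = k / len(null)
    if metric.lower() == "rf":
        denom, kind = 2 * (n - 2), "exact"
    else:
        denom, kind = max_mc(n)
    return CongruenceResult(
        metric=metric.lower(),
        observed=observed,
        normalized=min(observed / denom, 1.0) if denom else 0.0,
        null_size=len(null),
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=0)),
        p_value=p,
        mode=mode,
        seed=seed,
        normalizer=kind,
        n_leaves=n,
    )


# -- newick IO -----------------------------------------------------------------


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
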