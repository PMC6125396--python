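"""UPGMA, cluster extraction, RF/MC distances, topology nulls."""

import itertools

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

from phylosym.trees import (
    MAX_EXACT_LEAVES,
    clusters,
    congruence_test,
    cophenetic_matrix,
    double_factorial_topologies,
    enumerate_topologies,
    is_ultrametric,
    max_mc,
    mc_distance,
    random_topology,
    rf_distance,
    upgma,
)


def nwk(s: str) -> TreeNode:
    return TreeNode.read([s])


# -- independent oracles -------------------------------------------------------


def brute_clusters(tree: TreeNode) -> list[frozenset]:
    """Cluster list straight from the definition (oracle)."""
    tips_all = frozenset(t.name for t in tree.tips())
    out = []
    for node in tree.traverse(include_self=True):
        if node.is_tip():
            continue
        c = frozenset(t.name for t in node.tips())
        if 1 < len(c) < len(tips_all):
            out.append(c)
    return out


def brute_rf(t1, t2) -> int:
    return len(set(brute_clusters(t1)) ^ set(brute_clusters(t2)))


def brute_mc(t1, t2) -> int:
    """Minimum over all perfect matchings by factorial enumeration."""
    c1, c2 = brute_clusters(t1), brute_clusters(t2)
    k = max(len(c1), len(c2))
    c1 = c1 + [frozenset()] * (k - len(c1))
    c2 = c2 + [frozenset()] * (k - len(c2))
    return min(
        sum(len(a ^ b) for a, b in zip(c1, perm))
        for perm in itertools.permutations(c2)
    )


def random_ultrametric(labels, rng) -> TreeNode:
    """Random topology + distinct uniform merge heights -> ultrametric tree."""
    topo = random_topology(labels, rng)
    internals = list(topo.non_tips(include_self=True))
    # heights decreasing from root; assign by depth ordering
    heights = {}
    for node in topo.preorder(include_self=True):
        if node.is_tip():
            continue
        upper = heights.get(id(node.parent), 1.0)
        heights[id(node)] = upper * rng.uniform(0.3, 0.9)
    for node in topo.preorder(include_self=False):
        parent_h = heights.get(id(node.parent))
        node_h = heights.get(id(node), 0.0)
        node.length = parent_h - node_h
    return topo


class TestUpgma:
    def test_hand_execution(self):
        dm = DistanceMatrix([[0, 2, 8], [2, 0, 8], [8, 8, 0]], ids=list("ABC"))
        tree = upgma(dm)
        assert clusters(tree) == {frozenset({"A", "B"})}
        coph = cophenetic_matrix(tree)
        assert coph["A", "B"] == pytest.approx(2.0)
        assert coph["A", "C"] == pytest.approx(8.0)
        assert is_ultrametric(tree)

    def test_two_leaves(self):
        tree = upgma(DistanceMatrix([[0, 3], [3, 0]], ids=["X", "Y"]))
        assert cophenetic_matrix(tree)["X", "Y"] == pytest.approx(3.0)
        assert clusters(tree) == set()

    def test_reproduces_ultrametric_input(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            truth = random_ultrametric([f"t{i}" for i in range(n)], rng)
            dm = cophenetic_matrix(truth)
            rebuilt = upgma(dm)
            assert rf_distance(truth, rebuilt)[0] == 0
            np.testing.assert_allclose(
                cophenetic_matrix(rebuilt).data, dm.data, atol=1e-9
            )

    def test_matches_scipy_average_linkage(self, rng):
        # generic matrices (no exact ties): same topology as scipy 'average'
        for _ in range(15):
            n = int(rng.integers(4, 9))
            pts = rng.normal(size=(n, 3))
            from scipy.spatial.distance import pdist

            cond = pdist(pts)
            ids = [f"t{i}" for i in range(n)]
            mine = upgma(DistanceMatrix(squareform(cond), ids=ids))
            link = hierarchy.linkage(cond, method="average")
            scipy_tree = _scipy_to_treenode(link, ids)
            assert rf_distance(mine, scipy_tree)[0] == 0


def _scipy_to_treenode(link, ids):
    nodes = {i: TreeNode(name=name) for i, name in enumerate(ids)}
    n = len(ids)
    for k, (a, b, dist, _) in enumerate(link):
        parent = TreeNode(children=[nodes.pop(int(a)), nodes.pop(int(b))])
        nodes[n + k] = parent
    (root,) = nodes.values()
    return root


class TestClusters:
    @pytest.mark.parametrize(
        "newick,expected",
        [
            ("((A,B),(C,D));", {frozenset("AB"), frozenset("CD")}),
            (
                "((((A,B),C),D),E);",
                {frozenset("AB"), frozenset("ABC"), frozenset("ABCD")},
            ),
            ("(A,B);", set()),
        ],
    )
    def test_read_off(self, newick, expected):
        assert clusters(nwk(newick)) == expected


class TestRfDistance:
    def test_identical(self):
        t = nwk("((A,B),(C,D));")
        assert rf_distance(t, nwk("((A,B),(C,D));")) == (0, 0.0)

    def test_maximally_different_quartets(self):
        assert rf_distance(nwk("((A,B),(C,D));"), nwk("((A,C),(B,D));")) == (
            4,
            1.0,
        )

    def test_caterpillar_cherry_swap(self):
        raw, norm = rf_distance(
            nwk("((((A,B),C),D),E);"), nwk("((((A,B),D),C),E);")
        )
        assert raw == 2
        assert norm == pytest.approx(2 / 6)

    def test_leaf_mismatch_listed(self):
        with pytest.raises(ValueError, match="E"):
            rf_distance(nwk("((A,B),E);"), nwk("((A,B),C);"))


class TestMcDistance:
    def test_identical(self):
        t = nwk("((((A,B),C),D),E);")
        assert mc_distance(t, t)[0] == 0

    def test_hand_matching(self):
        # {AB}<->{AB}:0, {ABCD}<->{ABCD}:0, {ABC}<->{ABD}:2
        raw, _ = mc_distance(
            nwk("((((A,B),C),D),E);"), nwk("((((A,B),D),C),E);")
        )
        assert raw == 2

    def test_matches_brute_force_on_random_pairs(self, rng):
        labels = list("ABCDEF")
        for _ in range(40):
            t1 = random_topology(labels, rng)
            t2 = random_topology(labels, rng)
            assert mc_distance(t1, t2)[0] == brute_mc(t1, t2)
            assert rf_distance(t1, t2)[0] == brute_rf(t1, t2)

    def test_metric_axioms_on_five_leaf_triples(self, rng):
        trees = list(enumerate_topologies(list("ABCDE")))
        idx = rng.integers(0, len(trees), size=(25, 3))
        for i, j, k in idx:
            a, b, c = trees[i], trees[j], trees[k]
            for fn in (lambda x, y: rf_distance(x, y)[0], lambda x, y: mc_distance(x, y)[0]):
                dab, dbc, dac = fn(a, b), fn(b, c), fn(a, c)
                assert dab >= 0
                assert dab + dbc >= dac  # triangle inequality
            rf_raw = rf_distance(a, b)[0]
            mc_raw = mc_distance(a, b)[0]
            assert (mc_raw == 0) == (rf_raw == 0)
            assert mc_raw <= rf_raw * (5 - 1)


class TestTopologyGeneration:
    def test_counts_match_double_factorial(self):
        assert double_factorial_topologies(3) == 3
        assert double_factorial_topologies(4) == 15
        assert double_factorial_topologies(7) == 10395
        assert len(list(enumerate_topologies(list("ABC")))) == 3
        assert len(list(enumerate_topologies(list("ABCD")))) == 15

    def test_enumeration_has_no_duplicates(self):
        seen = {
            frozenset(clusters(t)) | frozenset({frozenset("ABCDE")})
            for t in enumerate_topologies(list("ABCDE"))
        }
        assert len(seen) == double_factorial_topologies(5)

    def test_seven_leaf_support(self):
        assert (
            sum(1 for _ in enumerate_topologies(list("ABCDEFG"))) == 10395
        )

    def test_refuses_large_n(self):
        with pytest.raises(ValueError, match="Monte-Carlo"):
            list(enumerate_topologies([f"t{i}" for i in range(MAX_EXACT_LEAVES + 1)]))

    def test_two_leaves_unique(self, rng):
        t = random_topology(["A", "B"], rng)
        assert sorted(x.name for x in t.tips()) == ["A", "B"]

    def test_uniformity_chi_square_small(self, rng):
        # 4 leaves: 15 topologies, 15k draws
        counts = {}
        for _ in range(15_000):
            t = random_topology(list("ABCD"), rng)
            key = frozenset(clusters(t))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 15
        from scipy.stats import chisquare

        _, p = chisquare(list(counts.values()))
        assert p > 0.001


class TestMaxMc:
    def test_small_values_by_full_enumeration(self):
        # independent O(T^2) check of the shape-reduced computation
        for n in (4, 5):
            trees = list(enumerate_topologies([f"t{i}" for i in range(n)]))
            best = max(
                brute_mc(a, b) for a, b in itertools.combinations(trees, 2)
            )
            assert max_mc(n) == (best, "exact")

    def test_bound_beyond_exact_range(self):
        val, kind = max_mc(12)
        assert kind == "bound" and val == 10 * 11


class TestCongruenceTest:
    def test_identical_topology_exact_p(self):
        host = random_topology(list("ABCDEFG"), np.random.default_rng(0))
        res = congruence_test(host, host, metric="rf", mode="exact")
        assert res.observed == 0
        assert res.p_value == pytest.approx(1 / 10395)
        assert res.null_size == 10395

    def test_max_distance_gives_p_one(self):
        host = nwk("((A,B),(C,D));")
        res = congruence_test(host, host, metric="rf", mode="exact")
        # whole tail: any topology is at distance <= max
        far = nwk("((A,C),(B,D));")
        res_far = congruence_test(host, far, metric="rf", mode="exact")
        assert res_far.observed == 4
        assert res_far.p_value == pytest.approx(1.0)
        assert res.p_value < res_far.p_value

    def test_monte_carlo_tracks_exact(self):
        host = random_topology(list("ABCDEFG"), np.random.default_rng(3))
        dendro = random_topology(list("ABCDEFG"), np.random.default_rng(4))
        for metric in ("rf", "mc"):
            exact = congruence_test(host, dendro, metric=metric, mode="exact")
            mc = congruence_test(
                host, dendro, metric=metric, mode="monte_carlo",
                n_random=4000, seed=11,
            )
            se = np.sqrt(exact.p_value * (1 - exact.p_value) / 4000)
            assert abs(mc.p_value - exact.p_value) <= 3 * se + 1e-12

    def test_exact_null_is_probability(self):
        host = random_topology(list("ABCDE"), np.random.default_rng(9))
        from phylosym.trees import null_distances

        null = null_distances(host, metric="rf", mode="exact")
        assert len(null) == double_factorial_topologies(5)
        # p at the max distance covers the whole null
        assert (null <= null.max()).mean() == 1.0

    def test_reproducible_given_seed(self):
        host = random_topology(list("ABCDEFG"), np.random.default_rng(5))
        dendro = random_topology(list("ABCDEFG"), np.random.default_rng(6))
        a = congruence_test(host, dendro, mode="monte_carlo", n_random=2000, seed=42)
        b = congruence_test(host, dendro, mode="monte_carlo", n_random=2000, seed=42)
        assert a.p_value == b.p_value
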