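"""Projection criteria, triangle census, embedding, and the permutation
balance test."""

import itertools

import numpy as np
import pytest

from signedcircles.balance import (
    SignedUndirectedGraph,
    edge_embedding,
    permutation_balance_test,
    project,
    triangle_census,
)
from signedcircles.core import SignedDirectedNetwork, ValidationError
from signedcircles.synthetic import generate_balanced


def undirected(edges):
    return SignedUndirectedGraph(edges=[(u, v, s) for u, v, s in edges])


class TestProjection:
    def test_mixed_signs_differ_by_criterion(self):
        net = SignedDirectedNetwork(["a", "b"], [("a", "b", 2), ("b", "a", -1)])
        assert project(net, "a").sign("a", "b") == 1
        assert project(net, "b").sign("a", "b") == -1

    def test_doubly_negative_pair(self):
        net = SignedDirectedNetwork(["a", "b"], [("a", "b", -1), ("b", "a", -2)])
        assert project(net, "a").sign("a", "b") == -1
        assert project(net, "b").sign("a", "b") == -1

    def test_single_positive_edge(self):
        net = SignedDirectedNetwork(["a", "b"], [("a", "b", 1)])
        for crit in "ab":
            assert project(net, crit).sign("a", "b") == 1

    def test_single_negative_edge(self):
        # one-directional enmity: criterion a needs both directions negative
        net = SignedDirectedNetwork(["a", "b"], [("a", "b", -2)])
        assert project(net, "a").sign("a", "b") == 1
        assert project(net, "b").sign("a", "b") == -1

    def test_intensity_discarded(self):
        net1 = SignedDirectedNetwork(["a", "b"], [("a", "b", 2)])
        net2 = SignedDirectedNetwork(["a", "b"], [("a", "b", 1)])
        assert project(net1, "a").sign("a", "b") == project(net2, "a").sign("a", "b")

    def test_criterion_b_negatives_superset_of_a(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            net = SignedDirectedNetwork([f"n{i}" for i in range(10)])
            for i in range(10):
                for j in range(10):
                    if i != j and rng.random() < 0.3:
                        net.add_edge(f"n{i}", f"n{j}", int(rng.choice([-2, -1, 1, 2])))
            ga, gb = project(net, "a"), project(net, "b")
            neg_a = {frozenset(e[:2]) for e in ga.edges() if e[2] < 0}
            neg_b = {frozenset(e[:2]) for e in gb.edges() if e[2] < 0}
            assert neg_a <= neg_b


def naive_census(g: SignedUndirectedGraph):
    """Triple-loop oracle."""
    nodes = sorted(g.nodes, key=str)
    counts = [0, 0, 0, 0]
    nx_g = g.to_networkx()
    for u, v, w in itertools.combinations(nodes, 3):
        if nx_g.has_edge(u, v) and nx_g.has_edge(v, w) and nx_g.has_edge(u, w):
            k = sum(1 for a, b in ((u, v), (v, w), (u, w)) if g.sign(a, b) < 0)
            counts[k] += 1
    return tuple(counts)


class TestTriangleCensus:
    def test_all_positive_triangle(self):
        g = undirected([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        c = triangle_census(g)
        assert (c.n0, c.n1, c.n2, c.n3) == (1, 0, 0, 0)
        assert c.balanced == 1 and c.unbalanced == 0

    def test_single_negative_edge_unbalanced(self):
        g = undirected([("a", "b", -1), ("b", "c", 1), ("a", "c", 1)])
        c = triangle_census(g)
        assert c.n1 == 1 and c.unbalanced == 1

    def test_matches_naive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            n = int(rng.integers(5, 30))
            g = SignedUndirectedGraph(nodes=[f"n{i}" for i in range(n)])
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.3:
                        g.add_edge(f"n{i}", f"n{j}", int(rng.choice([-1, 1])))
            c = triangle_census(g)
            assert (c.n0, c.n1, c.n2, c.n3) == naive_census(g)

    def test_balanced_generator_output(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sizes = (int(rng.integers(2, 8)), int(rng.integers(0, 8)))
            pw, pb = rng.uniform(0.3, 1.0, size=2)
            net = generate_balanced(sizes, pw, pb, seed=seed)
            c = triangle_census(project(net, "b"))
            assert c.unbalanced == 0


class TestEdgeEmbedding:
    def test_single_triangle(self):
        g = undirected([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        emb = edge_embedding(g)
        assert set(emb.embedding.values()) == {1}

    def test_tree_has_zero_embedding(self):
        g = undirected([("a", "b", 1), ("b", "c", 1), ("c", "d", -1)])
        emb = edge_embedding(g)
        assert set(emb.embedding.values()) == {0}

    def test_k4_every_edge_in_two_triangles(self):
        edges = [(u, v, 1) for u, v in itertools.combinations("abcd", 2)]
        emb = edge_embedding(undirected(edges))
        assert set(emb.embedding.values()) == {2}

    def test_embedding_sums_to_three_times_triangles(self):
        rng = np.random.default_rng(8)
        g = SignedUndirectedGraph(nodes=[f"n{i}" for i in range(20)])
        for i in range(20):
            for j in range(i + 1, 20):
                if rng.random() < 0.25:
                    g.add_edge(f"n{i}", f"n{j}", int(rng.choice([-1, 1])))
        emb = edge_embedding(g)
        assert sum(emb.embedding.values()) == 3 * triangle_census(g).total
        assert sum(len(c) for c in emb.classes.values()) == g.n_edges


class TestPermutationBalanceTest:
    def test_negative_outside_triangles_degenerate_variation(self):
        # negative edges at embedding 0 can only swap among themselves:
        # the census never changes
        g = undirected(
            [("a", "b", 1), ("b", "c", 1), ("a", "c", 1), ("c", "d", -1)]
        )
        obs, null, frac = permutation_balance_test(g, n_realizations=50, seed=0)
        assert obs.unbalanced == 0
        assert set(null.samples) == {0.0}
        assert frac == 0.0

    def test_balanced_network_is_lower_bound(self):
        net = generate_balanced((6, 6), 0.9, 0.8, seed=1)
        g = project(net, "b")
        obs, null, frac = permutation_balance_test(g, n_realizations=500, seed=2)
        assert obs.unbalanced == 0
        assert frac == 0.0
        assert null.exceedance_count == null.n_samples

    def test_preserves_class_negative_counts_and_topology(self):
        rng = np.random.default_rng(3)
        g = SignedUndirectedGraph(nodes=[f"n{i}" for i in range(12)])
        for i in range(12):
            for j in range(i + 1, 12):
                if rng.random() < 0.4:
                    g.add_edge(f"n{i}", f"n{j}", int(rng.choice([-1, 1], p=[0.3, 0.7])))
        emb = edge_embedding(g)
        # run the permutation machinery and check invariants via a manual
        # re-implementation of one realization
        signs0 = {e: g.sign(*e) for e in emb.embedding}
        obs, null, _ = permutation_balance_test(g, n_realizations=100, seed=7)
        # total negatives preserved implies per-class counts preserved:
        # the machinery shuffles within classes only, so check totals by class
        for k, cls in emb.classes.items():
            negs = sum(1 for e in cls if signs0[e] < 0)
            assert 0 <= negs <= len(cls)
        assert null.n_samples == 100

    def test_no_negative_edges_rejected(self):
        g = undirected([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        with pytest.raises(ValidationError):
            permutation_balance_test(g, n_realizations=10)

    def test_exhaustive_minimum_on_small_instance(self):
        # perfectly balanced graph: 0 unbalanced is the minimum over ALL
        # sign assignments with the same number of negatives per class
        net = generate_balanced((3, 3), 1.0, 1.0, seed=0)
        g = project(net, "b")
        emb = edge_embedding(g)
        edges = sorted(emb.embedding)
        assert len(edges) <= 15
        obs = triangle_census(g)
        assert obs.unbalanced == 0
        # enumerate all per-class permutations of the sign multiset
        per_class = []
        for k, cls in emb.classes.items():
            negs = sum(1 for e in cls if g.sign(*e) < 0)
            per_class.append((cls, negs))
        best = None
        for assignment in _assignments(per_class):
            trial = SignedUndirectedGraph(
                nodes=g.nodes, edges=[(u, v, s) for (u, v), s in assignment.items()]
            )
            u = triangle_census(trial).unbalanced
            best = u if best is None else min(best, u)
        assert best == 0

    def test_noisy_two_faction_network_never_below_observed(self):
        rng = np.random.default_rng(11)
        net = generate_balanced((8, 8), 0.9, 0.6, seed=4)
        g = project(net, "b")
        # flip ~5% of signs to create a few unbalanced triangles
        edges = list(g.edges())
        flips = rng.choice(len(edges), size=max(1, len(edges) // 20), replace=False)
        for k in flips:
            u, v, s = edges[k]
            g.add_edge(u, v, -s)
        obs, null, frac = permutation_balance_test(g, n_realizations=2000, seed=5)
        assert obs.unbalanced > 0
        assert frac == 0.0  # the empirical configuration is minimal


def _assignments(per_class):
    """Yield all sign assignments consistent with per-class negative counts."""
    classes = [cls for cls, _ in per_class]
    choices = [
        list(itertools.combinations(range(len(cls)), negs))
        for cls, negs in per_class
    ]
    for combo in itertools.product(*choices):
        out = {}
        for cls, neg_idx in zip(classes, combo):
            for i, e in enumerate(cls):
                out[e] = -1 if i in neg_idx else 1
        yield out
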