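"""Structural balance: projection, triangle census, and permutation test.

Balance theory holds that signed triangles with an odd number of negative
edges ("my friend's friend is my enemy") are cognitively dissonant and tend
to be resolved over time, so a socially balanced network should carry fewer
unbalanced triangles than chance allows.

The directed survey network is first projected onto an undirected signed
graph.  Because the two directions of a dyad often disagree in sign, two
projection criteria are supported:

* criterion "a" — a pair is negative only when both directions exist and
  both are negative;
* criterion "b" — a single negative direction already marks the pair as
  negative.

Intensities are discarded before projection.  The null model then reshuffles
edge signs *within embedding classes*: edges are grouped by their embedding
(the number of triangles they belong to) and signs are permuted only among
edges of equal embedding.  This preserves the topology, the embedding of
every edge, and the number of negative edges per class, avoiding the bias of
nulls that mix the structurally different positive and negative subnetworks.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from signedcircles.core import SignedDirectedNetwork, ValidationError
from signedcircles.reciprocity import NullDistribution

__all__ = [
    "SignedUndirectedGraph",
    "TriangleCensus",
    "EmbeddingIndex",
    "project",
    "triangle_census",
    "edge_embedding",
    "permutation_balance_test",
]


class SignedUndirectedGraph:
    """Undirected graph with one signed edge (+1 or -1) per node pair."""

    def __init__(self, nodes=(), edges=()):
        self._g = nx.Graph()
        self._g.add_nodes_from(nodes)
        for u, v, s in edges:
            self.add_edge(u, v, s)

    def add_edge(self, u, v, sign: int) -> None:
        if u == v:
            raise ValidationError(f"self-loop on {u!r}")
        if sign not in (1, -1):
            raise ValidationError(f"sign must be +1 or -1, got {sign}")
        self._g.add_edge(u, v, sign=sign)

    @property
    def nodes(self) -> set:
        return set(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self):
        for u, v, d in self._g.edges(data=True):
            yield u, v, d["sign"]

    def sign(self, u, v) -> int:
        return self._g.edges[u, v]["sign"]

    def neighbors(self, u):
        return self._g.neighbors(u)

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    @property
    def n_negative(self) -> int:
        return sum(1 for _, _, s in self.edges() if s < 0)


@dataclass(frozen=True)
class TriangleCensus:
    """Triangle counts stratified by number of negative edges."""

    n0: int
    n1: int
    n2: int
    n3: int

    @property
    def total(self) -> int:
        return self.n0 + self.n1 + self.n2 + self.n3

    @property
    def balanced(self) -> int:
        return self.n0 + self.n2

    @property
    def unbalanced(self) -> int:
        return self.n1 + self.n3


@dataclass
class EmbeddingIndex:
    """Edge -> embedding (triangle membership count), plus the partition of
    the edge set into equal-embedding classes."""

    embedding: dict[tuple, int]
    classes: dict[int, list[tuple]]


def project(net: SignedDirectedNetwork, criterion: str = "a") -> SignedUndirectedGraph:
    """Project a directed signed network onto an undirected signed graph.

    Every pair connected in at least one direction gets an edge; intensity
    is discarded.  Under criterion "a" the edge is negative only if both
    directions exist and are negative; under "b" one negative direction
    suffices.
    """
    if criterion not in ("a", "b"):
        raise ValueError(f"criterion must be 'a' or 'b', got {criterion!r}")
    pair_signs: dict[tuple, list[int]] = {}
    for u, v, w in net.edges():
        key = (u, v) if u <= v else (v, u)
        pair_signs.setdefault(key, []).append(1 if w > 0 else -1)
    g = SignedUndirectedGraph(nodes=net.nodes)
    for (u, v), signs in pair_signs.items():
        if criterion == "a":
            neg = len(signs) == 2 and all(s < 0 for s in signs)
        else:
            neg = any(s < 0 for s in signs)
        g.add_edge(u, v, -1 if neg else 1)
    return g


def _triangles(g: SignedUndirectedGraph) -> list[tuple]:
    """All triangles, each once, via ordered neighbor intersection."""
    adj = {u: set(g.neighbors(u)) for u in g.nodes}
    order = sorted(g.nodes, key=lambda u: (len(adj[u]), str(u)))
    rank = {u: i for i, u in enumerate(order)}
    tris = []
    for u in order:
        higher = {v for v in adj[u] if rank[v] > rank[u]}
        for v in higher:
            for w in higher & adj[v]:
                if rank[w] > rank[v]:
                    tris.append((u, v, w))
    return tris


def triangle_census(g: SignedUndirectedGraph) -> TriangleCensus:
    """Exact triangle counts by number of negative edges."""
    counts = [0, 0, 0, 0]
    for u, v, w in _triangles(g):
        k = sum(1 for a, b in ((u, v), (v, w), (u, w)) if g.sign(a, b) < 0)
        counts[k] += 1
    return TriangleCensus(*counts)


def edge_embedding(g: SignedUndirectedGraph) -> EmbeddingIndex:
    """Number of triangles each edge belongs to, and the equal-embedding
    classes of the edge set."""
    emb: dict[tuple, int] = {}
    for u, v, _ in g.edges():
        emb[(u, v) if u <= v else (v, u)] = 0
    for u, v, w in _triangles(g):
        for a, b in ((u, v), (v, w), (u, w)):
            key = (a, b) if a <= b else (b, a)
            emb[key] += 1
    classes: dict[int, list[tuple]] = {}
    for e, k in emb.items():
        classes.setdefault(k, []).append(e)
    return EmbeddingIndex(embedding=emb, classes={k: sorted(v) for k, v in sorted(classes.items())})


def permutation_balance_test(
    g: SignedUndirectedGraph,
    n_realizations: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[TriangleCensus, NullDistribution, float]:
    """Embedding-preserving sign-permutation test of structural balance.

    Each realization permutes edge signs uniformly within every equal-
    embedding class (topology and per-class negative counts fixed) and
    recounts unbalanced triangles.  Returns the observed census, the null
    distribution of unbalanced-triangle counts, and the fraction of
    realizations with strictly fewer unbalanced triangles than observed.
    """
    if n_realizations < 1:
        raise ValidationError("n_realizations must be >= 1")
    if g.n_negative == 0:
        raise ValidationError("no negative edges: balance test is vacuous")
    observed = triangle_census(g)
    index = edge_embedding(g)
    edges = sorted(index.embedding)
    edge_pos = {e: i for i, e in enumerate(edges)}
    signs0 = np.array([g.sign(*e) for e in edges], dtype=np.int8)
    # precompute triangle -> edge indices for vectorized recounting
    tris = _triangles(g)
    tri_idx = np.array(
        [
            [
                edge_pos[(a, b) if a <= b else (b, a)]
                for a, b in ((u, v), (v, w), (u, w))
            ]
            for u, v, w in tris
        ],
        dtype=np.int64,
    ).reshape(-1, 3)
    class_idx = [
        np.array([edge_pos[e] for e in cls], dtype=np.int64)
        for k, cls in index.classes.items()
    ]
    degenerate = all(len(c) == 1 for c in class_idx)
    rng = np.random.default_rng(seed)
    samples = np.empty(n_realizations)
    signs = signs0.copy()
    for r in range(n_realizations):
        for ci in class_idx:
            if len(ci) > 1:
                signs[ci] = signs0[ci][rng.permutation(len(ci))]
        if len(tri_idx):
            neg = (signs[tri_idx] < 0).sum(axis=1)
            samples[r] = int(np.count_nonzero(neg % 2 == 1))
        else:
            samples[r] = 0
    lo, hi = np.quantile(samples, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    null = NullDistribution(
        samples=samples,
        mean=float(samples.mean()),
        ci_level=ci_level,
        ci_low=float(lo),
        ci_high=float(hi),
        n_samples=n_realizations,
        seed=seed,
        observed=float(observed.unbalanced),
        exceedance_count=int(np.sum(samples >= observed.unbalanced)),
        degenerate=degenerate,
    )
    fraction_below = float(np.mean(samples < observed.unbalanced))
    return observed, null, fraction_below
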