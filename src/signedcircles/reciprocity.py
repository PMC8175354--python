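"""Reciprocity of nominations and its random-rewiring null model.

Reciprocity is the fraction of directed edges of a given sign whose reverse
edge exists with the same sign, irrespective of intensity.  Nomination
surveys typically reciprocate only about half of the friendship links; to
judge whether an observed value is large, the statistic is compared against
networks whose positive links have been rewired at random.  The default
rewiring keeps each ego's positive out-degree and redraws the targets
uniformly (no self-loops, no duplicate targets); a degree-sequence-
preserving double-edge-swap mode is also available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from signedcircles.core import SignedDirectedNetwork, ValidationError

__all__ = ["NullDistribution", "reciprocity", "rewiring_null"]


@dataclass
class NullDistribution:
    """Samples of a statistic under a null model, with a percentile CI and
    the one-sided exceedance count against the observed value."""

    samples: np.ndarray
    mean: float
    ci_level: float
    ci_low: float
    ci_high: float
    n_samples: int
    seed: int
    observed: float
    exceedance_count: int  # number of samples >= observed
    degenerate: bool = False  # null cannot vary (e.g. nothing to permute)

    @property
    def p_value_upper(self) -> float:
        """One-sided permutation p-value P(null >= observed), with the
        add-one correction."""
        return (self.exceedance_count + 1) / (self.n_samples + 1)


def reciprocity(net: SignedDirectedNetwork, sign: str = "positive") -> float:
    """Fraction of directed edges of ``sign`` whose reverse edge exists with
    the same sign (any intensity)."""
    if sign not in ("positive", "negative"):
        raise ValueError(f"sign must be positive|negative, got {sign!r}")
    wanted = (lambda w: w > 0) if sign == "positive" else (lambda w: w < 0)
    total = mutual = 0
    for u, v, w in net.edges():
        if not wanted(w):
            continue
        total += 1
        rw = net.weight(v, u)
        if rw is not None and wanted(rw):
            mutual += 1
    if total == 0:
        raise ValidationError(f"no {sign} edges: reciprocity undefined")
    return mutual / total


def _rewire_outdegree(
    nodes: list[str], out_deg: dict[str, int], rng: np.random.Generator
) -> dict[str, list[str]]:
    """Redraw each ego's targets uniformly without replacement."""
    n = len(nodes)
    targets: dict[str, list[str]] = {}
    idx = {u: i for i, u in enumerate(nodes)}
    arr = np.array(nodes)
    for u, d in out_deg.items():
        if d == 0:
            continue
        if d > n - 1:
            raise ValidationError(
                f"out-degree {d} of {u!r} exceeds n-1={n - 1}: cannot rewire"
            )
        # sample d distinct targets among the other n-1 nodes
        choice = rng.choice(n - 1, size=d, replace=False)
        i = idx[u]
        choice = np.where(choice >= i, choice + 1, choice)
        targets[u] = arr[choice].tolist()
    return targets


def _rewire_swap(
    edges: list[tuple[str, str]], rng: np.random.Generator, n_swaps: int
) -> list[tuple[str, str]]:
    """Directed double-edge swaps: preserves both in- and out-degrees."""
    edges = list(edges)
    edge_set = set(edges)
    m = len(edges)
    for _ in range(n_swaps):
        a, b = rng.integers(0, m, size=2)
        (u1, v1), (u2, v2) = edges[a], edges[b]
        if len({u1, v1, u2, v2}) < 4:
            continue
        e1, e2 = (u1, v2), (u2, v1)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard((u1, v1))
        edge_set.discard((u2, v2))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[a], edges[b] = e1, e2
    return edges


def _recip_of_pairs(pairs: set[tuple[str, str]]) -> float:
    mutual = sum(1 for (u, v) in pairs if (v, u) in pairs)
    return mutual / len(pairs)


def rewiring_null(
    net: SignedDirectedNetwork,
    n_samples: int = 1000,
    seed: int = 0,
    mode: str = "outdegree_preserving",
    ci_level: float = 0.95,
) -> NullDistribution:
    """Null distribution of positive reciprocity under random rewiring.

    ``mode="outdegree_preserving"`` (default) keeps each ego's positive
    out-degree and redraws targets uniformly; ``mode="double_edge_swap"``
    preserves the full in/out degree sequence via edge swaps.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    if mode not in ("outdegree_preserving", "double_edge_swap"):
        raise ValueError(f"unknown rewiring mode {mode!r}")
    observed = reciprocity(net, "positive")
    nodes = sorted(net.nodes)
    pos_edges = [(u, v) for u, v, w in net.edges() if w > 0]
    out_deg: dict[str, int] = {}
    for u, _ in pos_edges:
        out_deg[u] = out_deg.get(u, 0) + 1
    rng = np.random.default_rng(seed)
    samples = np.empty(n_samples)
    for s in range(n_samples):
        if mode == "outdegree_preserving":
            targets = _rewire_outdegree(nodes, out_deg, rng)
            pairs = {(u, v) for u, vs in targets.items() for v in vs}
        else:
            pairs = set(_rewire_swap(pos_edges, rng, n_swaps=10 * len(pos_edges)))
        samples[s] = _recip_of_pairs(pairs)
    lo, hi = np.quantile(samples, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    return NullDistribution(
        samples=samples,
        mean=float(samples.mean()),
        ci_level=ci_level,
        ci_low=float(lo),
        ci_high=float(hi),
        n_samples=n_samples,
        seed=seed,
        observed=observed,
        exceedance_count=int(np.sum(samples >= observed)),
    )
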