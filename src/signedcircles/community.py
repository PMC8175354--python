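"""Signed, directed, weighted modularity and its heuristic optimization.

The quality of a partition of a signed network combines a positive and a
negative modularity,

    Q = w+/(w+ + |w-|) * Q+  -  |w-|/(w+ + |w-|) * Q-,

where Q+ rewards intra-community positive weight in excess of a directed
null model,

    Q+ = 1/(2 w+) * sum_{i,j} ( w+_ij - w+_i,out * w+_j,in / (2 w+) ) * delta(C_i, C_j),

and Q- is the same expression evaluated on the absolute values of the
negative weights.  Intra-community positive links raise Q, intra-community
negative links lower it, so the optimum balances the cohesive pull of
friendships against the divisive push of enmities.

The printed normalization 2w+ is kept by default; part of the directed
literature divides by w+ instead.  Both are exposed through
``directed_normalization`` so reported Q values can be compared across
conventions (the optimal partition is the same up to the diagonal null
terms, which do not depend on the partition).

Maximizing Q is NP-hard; :func:`optimize_partition` runs a multi-restart
heuristic (greedy local moves, community merges, node-level refinement) that
is agnostic to the number of communities, and
:func:`brute_force_partition` provides the exact optimum by set-partition
enumeration for networks of up to 10 nodes.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from signedcircles.core import (
    NetworkPair,
    Roster,
    SignedDirectedNetwork,
    ValidationError,
    subnetwork,
)

__all__ = [
    "Partition",
    "ModularityResult",
    "CommunityFlow",
    "modularity",
    "optimize_partition",
    "brute_force_partition",
    "community_flows",
    "positive_only_comparison",
]


@dataclass(frozen=True)
class Partition:
    """A node -> community assignment with contiguous ids starting at 1."""

    membership: dict[str, int]

    @staticmethod
    def from_membership(membership: dict[str, int]) -> "Partition":
        """Normalize arbitrary community labels to contiguous ids 1..k
        (ordered by first appearance over sorted nodes)."""
        relabel: dict[int, int] = {}
        out: dict[str, int] = {}
        for node in sorted(membership):
            c = membership[node]
            if c not in relabel:
                relabel[c] = len(relabel) + 1
            out[node] = relabel[c]
        return Partition(out)

    @staticmethod
    def from_communities(communities: Iterable[Iterable[str]]) -> "Partition":
        membership = {}
        for cid, members in enumerate(communities, start=1):
            for node in members:
                membership[node] = cid
        return Partition.from_membership(membership)

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, c in self.membership.items():
            out.setdefault(c, []).append(node)
        return {c: sorted(m) for c, m in sorted(out.items())}

    def __getitem__(self, node: str) -> int:
        return self.membership[node]


@dataclass(frozen=True)
class ModularityResult:
    Q: float
    Q_plus: float
    Q_minus: float
    w_plus: float
    w_minus_abs: float


# ---------------------------------------------------------------------------
# internal indexed representation
# ---------------------------------------------------------------------------


class _Layer:
    """One sign layer in indexed form: adjacency dicts and strengths."""

    def __init__(self, n: int):
        self.out: list[dict[int, float]] = [dict() for _ in range(n)]
        self.inn: list[dict[int, float]] = [dict() for _ in range(n)]
        self.sout = np.zeros(n)
        self.sin = np.zeros(n)
        self.total = 0.0  # sum of (absolute) weights

    def add(self, i: int, j: int, w: float) -> None:
        self.out[i][j] = w
        self.inn[j][i] = w
        self.sout[i] += w
        self.sin[j] += w
        self.total += w


class _Indexed:
    def __init__(self, net: SignedDirectedNetwork, normalization: str):
        if normalization not in ("as_printed", "w_plus"):
            raise ValueError(f"unknown directed_normalization {normalization!r}")
        self.nodes = sorted(net.nodes)
        self.index = {u: i for i, u in enumerate(self.nodes)}
        n = len(self.nodes)
        self.pos = _Layer(n)
        self.neg = _Layer(n)
        for u, v, w in net.edges():
            i, j = self.index[u], self.index[v]
            if w > 0:
                self.pos.add(i, j, w)
            else:
                self.neg.add(i, j, -w)
        # normalization constant per layer: 2w (as printed) or w
        self.factor = 2.0 if normalization == "as_printed" else 1.0
        tot = self.pos.total + self.neg.total
        self.alpha = self.pos.total / tot if tot else 0.0
        self.beta = self.neg.total / tot if tot else 0.0

    def layer_modularity(self, layer: _Layer, comm: np.ndarray) -> float:
        if layer.total == 0:
            return 0.0
        norm = self.factor * layer.total
        w_in = 0.0
        for i, nbrs in enumerate(layer.out):
            ci = comm[i]
            for j, w in nbrs.items():
                if comm[j] == ci:
                    w_in += w
        k = comm.max() + 1
        sout_c = np.zeros(k)
        sin_c = np.zeros(k)
        np.add.at(sout_c, comm, layer.sout)
        np.add.at(sin_c, comm, layer.sin)
        return w_in / norm - float(sout_c @ sin_c) / norm**2

    def quality(self, comm: np.ndarray) -> tuple[float, float, float]:
        qp = self.layer_modularity(self.pos, comm)
        qm = self.layer_modularity(self.neg, comm)
        return self.alpha * qp - self.beta * qm, qp, qm


def _as_comm_array(idx: _Indexed, partition: Partition) -> np.ndarray:
    missing = [u for u in idx.nodes if u not in partition.membership]
    if missing:
        raise ValidationError(f"partition missing node(s) {missing[:5]}")
    labels = sorted(set(partition.membership.values()))
    relabel = {c: i for i, c in enumerate(labels)}
    return np.array([relabel[partition.membership[u]] for u in idx.nodes])


def modularity(
    net: SignedDirectedNetwork,
    partition: Partition,
    directed_normalization: str = "as_printed",
) -> ModularityResult:
    """Evaluate the signed directed modularity of a given partition."""
    if net.n_edges == 0:
        raise ValidationError("modularity undefined: network has no edges")
    idx = _Indexed(net, directed_normalization)
    comm = _as_comm_array(idx, partition)
    q, qp, qm = idx.quality(comm)
    return ModularityResult(
        Q=q, Q_plus=qp, Q_minus=qm, w_plus=idx.pos.total, w_minus_abs=idx.neg.total
    )


# ---------------------------------------------------------------------------
# heuristic optimization
# ---------------------------------------------------------------------------


def _local_moves(idx: _Indexed, comm: np.ndarray, order: list[int]) -> bool:
    """Greedy single-node moves until no move improves Q.  Nodes may move to
    any community adjacent in either layer, or to a fresh empty community.
    Returns True if anything changed."""
    n = len(comm)
    n_comm = comm.max() + 1
    pos, neg = idx.pos, idx.neg
    # community strength totals per layer
    k = n_comm + 1  # reserve one empty slot
    psout = np.zeros(k)
    psin = np.zeros(k)
    nsout = np.zeros(k)
    nsin = np.zeros(k)
    np.add.at(psout, comm, pos.sout)
    np.add.at(psin, comm, pos.sin)
    np.add.at(nsout, comm, neg.sout)
    np.add.at(nsin, comm, neg.sin)
    size = np.zeros(k, dtype=int)
    np.add.at(size, comm, 1)
    empty = n_comm  # index of the reserved empty community

    pnorm = idx.factor * pos.total if pos.total else 1.0
    nnorm = idx.factor * neg.total if neg.total else 1.0
    ca = idx.alpha / pnorm
    cb = idx.beta / nnorm

    changed_any = False
    improved = True
    while improved:
        improved = False
        for i in order:
            c = comm[i]
            # positive/negative weight between i and each candidate community
            wpos: dict[int, float] = {}
            wneg: dict[int, float] = {}
            for j, w in pos.out[i].items():
                wpos[comm[j]] = wpos.get(comm[j], 0.0) + w
            for j, w in pos.inn[i].items():
                wpos[comm[j]] = wpos.get(comm[j], 0.0) + w
            for j, w in neg.out[i].items():
                wneg[comm[j]] = wneg.get(comm[j], 0.0) + w
            for j, w in neg.inn[i].items():
                wneg[comm[j]] = wneg.get(comm[j], 0.0) + w
            # every non-empty community is a candidate (a move to a
            # non-adjacent one can still pay off through the null term),
            # plus a fresh empty community
            candidates = {d for d in range(len(size)) if size[d] > 0}
            candidates.discard(c)
            if size[c] > 1:
                candidates.add(empty)
            if not candidates:
                continue
            pso, psi = pos.sout[i], pos.sin[i]
            nso, nsi = neg.sout[i], neg.sin[i]
            # gain of removing i from c (negated cost of re-adding)
            rm_pos = wpos.get(c, 0.0) - (
                pso * (psin[c] - psi) + psi * (psout[c] - pso)
            ) / pnorm
            rm_neg = wneg.get(c, 0.0) - (
                nso * (nsin[c] - nsi) + nsi * (nsout[c] - nso)
            ) / nnorm
            remove_gain = -(ca * rm_pos - cb * rm_neg)
            best_gain = 0.0
            best_d = -1
            for d in candidates:
                add_pos = wpos.get(d, 0.0) - (pso * psin[d] + psi * psout[d]) / pnorm
                add_neg = wneg.get(d, 0.0) - (nso * nsin[d] + nsi * nsout[d]) / nnorm
                gain = remove_gain + (ca * add_pos - cb * add_neg)
                if gain > best_gain + 1e-13 or (
                    gain > best_gain - 1e-13 and best_d != -1 and d < best_d
                ):
                    best_gain, best_d = gain, d
            if best_d == -1:
                continue
            # apply move
            d = best_d
            psout[c] -= pso
            psin[c] -= psi
            nsout[c] -= nso
            nsin[c] -= nsi
            size[c] -= 1
            psout[d] += pso
            psin[d] += psi
            nsout[d] += nso
            nsin[d] += nsi
            size[d] += 1
            comm[i] = d
            changed_any = improved = True
            if d == empty:
                # grow the arrays: reserve a new empty slot
                empty += 1
                psout = np.append(psout, 0.0)
                psin = np.append(psin, 0.0)
                nsout = np.append(nsout, 0.0)
                nsin = np.append(nsin, 0.0)
                size = np.append(size, 0)
    return changed_any


def _kl_pass(idx: _Indexed, comm: np.ndarray) -> bool:
    """Kernighan-Lin style escape from a local optimum: apply a sequence of
    best single moves, locking each moved node, *allowing negative gains*;
    keep the prefix of the sequence with the highest cumulative gain.  This
    can cross barriers that require two or more coordinated moves.  Returns
    True if comm was improved (modified in place)."""
    n = len(comm)
    pos, neg = idx.pos, idx.neg
    pnorm = idx.factor * pos.total if pos.total else 1.0
    nnorm = idx.factor * neg.total if neg.total else 1.0
    ca = idx.alpha / pnorm
    cb = idx.beta / nnorm
    improved_any = False
    while True:
        cur = comm.copy()
        n_comm = cur.max() + 1
        k = n_comm + 1
        psout = np.zeros(k)
        psin = np.zeros(k)
        nsout = np.zeros(k)
        nsin = np.zeros(k)
        np.add.at(psout, cur, pos.sout)
        np.add.at(psin, cur, pos.sin)
        np.add.at(nsout, cur, neg.sout)
        np.add.at(nsin, cur, neg.sin)
        size = np.zeros(k, dtype=int)
        np.add.at(size, cur, 1)
        empty = n_comm
        locked = np.zeros(n, dtype=bool)
        cum = 0.0
        best_cum = 0.0
        best_state: Optional[np.ndarray] = None
        for _ in range(n):
            step_best = (-np.inf, -1, -1)  # (gain, node, dest)
            for i in range(n):
                if locked[i]:
                    continue
                c = cur[i]
                wpos: dict[int, float] = {}
                wneg: dict[int, float] = {}
                for j, w in pos.out[i].items():
                    wpos[cur[j]] = wpos.get(cur[j], 0.0) + w
                for j, w in pos.inn[i].items():
                    wpos[cur[j]] = wpos.get(cur[j], 0.0) + w
                for j, w in neg.out[i].items():
                    wneg[cur[j]] = wneg.get(cur[j], 0.0) + w
                for j, w in neg.inn[i].items():
                    wneg[cur[j]] = wneg.get(cur[j], 0.0) + w
                pso, psi = pos.sout[i], pos.sin[i]
                nso, nsi = neg.sout[i], neg.sin[i]
                rm_pos = wpos.get(c, 0.0) - (
                    pso * (psin[c] - psi) + psi * (psout[c] - pso)
                ) / pnorm
                rm_neg = wneg.get(c, 0.0) - (
                    nso * (nsin[c] - nsi) + nsi * (nsout[c] - nso)
                ) / nnorm
                remove_gain = -(ca * rm_pos - cb * rm_neg)
                candidates = {d for d in range(len(size)) if size[d] > 0}
                candidates.discard(c)
                if size[c] > 1:
                    candidates.add(empty)
                for d in candidates:
                    add_pos = wpos.get(d, 0.0) - (
                        pso * psin[d] + psi * psout[d]
                    ) / pnorm
                    add_neg = wneg.get(d, 0.0) - (
                        nso * nsin[d] + nsi * nsout[d]
                    ) / nnorm
                    gain = remove_gain + (ca * add_pos - cb * add_neg)
                    if gain > step_best[0]:
                        step_best = (gain, i, d)
            gain, i, d = step_best
            if i == -1:
                break
            c = cur[i]
            pso, psi = pos.sout[i], pos.sin[i]
            nso, nsi = neg.sout[i], neg.sin[i]
            psout[c] -= pso
            psin[c] -= psi
            nsout[c] -= nso
            nsin[c] -= nsi
            size[c] -= 1
            psout[d] += pso
            psin[d] += psi
            nsout[d] += nso
            nsin[d] += nsi
            size[d] += 1
            cur[i] = d
            locked[i] = True
            cum += gain
            if d == empty:
                empty += 1
                psout = np.append(psout, 0.0)
                psin = np.append(psin, 0.0)
                nsout = np.append(nsout, 0.0)
                nsin = np.append(nsin, 0.0)
                size = np.append(size, 0)
            if cum > best_cum + 1e-13:
                best_cum = cum
                best_state = cur.copy()
        if best_state is None:
            return improved_any
        comm[:] = _compact(best_state)
        improved_any = True


def _compact(comm: np.ndarray) -> np.ndarray:
    labels = {c: i for i, c in enumerate(dict.fromkeys(comm.tolist()))}
    return np.array([labels[c] for c in comm])


def _merge_pass(idx: _Indexed, comm: np.ndarray) -> bool:
    """Try merging every pair of communities; apply the best improving merge,
    repeat until none improves."""
    changed = False
    while True:
        comm[:] = _compact(comm)
        k = comm.max() + 1
        if k < 2:
            return changed
        base, _, _ = idx.quality(comm)
        best = (0.0, None)
        for a, b in itertools.combinations(range(k), 2):
            trial = comm.copy()
            trial[trial == b] = a
            q, _, _ = idx.quality(_compact(trial))
            if q - base > best[0] + 1e-13:
                best = (q - base, (a, b))
        if best[1] is None:
            return changed
        a, b = best[1]
        comm[comm == b] = a
        changed = True


def optimize_partition(
    net: SignedDirectedNetwork,
    n_restarts: int = 10,
    seed: int = 0,
    directed_normalization: str = "as_printed",
) -> tuple[Partition, ModularityResult]:
    """Heuristic maximization of signed modularity.

    Each restart shuffles the node order, runs greedy local moves from the
    singleton partition, then alternates community merges with node-level
    refinement until stable.  The number of communities is free: moves to an
    empty community and merges of existing ones are both available.  The
    best partition over restarts is returned; deterministic given ``seed``.
    """
    if net.n_nodes == 0:
        raise ValidationError("cannot partition an empty network")
    if net.n_edges == 0:
        part = Partition.from_membership({u: 1 for u in net.nodes})
        return part, ModularityResult(0.0, 0.0, 0.0, 0.0, 0.0)
    idx = _Indexed(net, directed_normalization)
    n = len(idx.nodes)
    rng = random.Random(seed)
    best_q = -np.inf
    best_comm: Optional[np.ndarray] = None
    def converge(comm: np.ndarray, order: list[int]) -> np.ndarray:
        _local_moves(idx, comm, order)
        comm = _compact(comm)
        for _ in range(20):  # alternate merge and refine until stable
            changed = _merge_pass(idx, comm)
            changed |= _local_moves(idx, comm, order)
            comm = _compact(comm)
            if not changed:
                break
        return comm

    for _ in range(max(1, n_restarts)):
        order = list(range(n))
        rng.shuffle(order)
        comm = converge(np.arange(n), order)
        q, _, _ = idx.quality(comm)
        # iterated local search: kick a few nodes into random communities
        # and re-converge, keeping the kick only if it improves Q
        for _ in range(3):
            trial = comm.copy()
            k = trial.max() + 2
            n_kick = max(1, n // 5)
            for i in rng.sample(range(n), n_kick):
                trial[i] = rng.randrange(k)
            trial = converge(_compact(trial), order)
            tq, _, _ = idx.quality(trial)
            if tq > q + 1e-13:
                comm, q = trial, tq
        if q > best_q + 1e-13:
            best_q, best_comm = q, comm.copy()
    assert best_comm is not None
    # final refinement: (a) extracting one node into its own community and
    # re-converging can unlock splits that single moves cannot reach, and
    # (b) a Kernighan-Lin escape pass can cross barriers that need several
    # coordinated moves; alternate the two until neither improves
    order = list(range(n))
    for _ in range(5):
        improved = False
        for i in range(n):
            trial = best_comm.copy()
            trial[i] = trial.max() + 1
            trial = converge(_compact(trial), order)
            tq, _, _ = idx.quality(trial)
            if tq > best_q + 1e-13:
                best_q, best_comm, improved = tq, trial, True
        trial = best_comm.copy()
        if _kl_pass(idx, trial):
            trial = converge(trial, order)
            tq, _, _ = idx.quality(trial)
            if tq > best_q + 1e-13:
                best_q, best_comm, improved = tq, trial, True
        if not improved:
            break
    membership = {idx.nodes[i]: int(best_comm[i]) + 1 for i in range(n)}
    part = Partition.from_membership(membership)
    return part, modularity(net, part, directed_normalization)


# ---------------------------------------------------------------------------
# exact enumeration oracle
# ---------------------------------------------------------------------------


def _set_partitions(items: Sequence[int]):
    """Yield all set partitions (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1 :]
        yield [[first]] + smaller


def brute_force_partition(
    net: SignedDirectedNetwork,
    max_nodes: int = 10,
    directed_normalization: str = "as_printed",
) -> tuple[Partition, ModularityResult]:
    """Globally optimal partition by exhaustive set-partition enumeration.

    Refuses networks with more than ``max_nodes`` nodes (Bell-number
    growth).  Intended as an oracle for the heuristic optimizer.
    """
    n = net.n_nodes
    if n == 0:
        raise ValidationError("cannot partition an empty network")
    if n > max_nodes:
        raise ValidationError(
            f"brute force limited to {max_nodes} nodes, got {n}"
        )
    if net.n_edges == 0:
        part = Partition.from_membership({u: 1 for u in net.nodes})
        return part, ModularityResult(0.0, 0.0, 0.0, 0.0, 0.0)
    idx = _Indexed(net, directed_normalization)
    best_q = -np.inf
    best_blocks: Optional[list[list[int]]] = None
    comm = np.zeros(n, dtype=int)
    for blocks in _set_partitions(list(range(n))):
        for cid, block in enumerate(blocks):
            for i in block:
                comm[i] = cid
        q, _, _ = idx.quality(comm)
        if q > best_q + 1e-13:
            best_q, best_blocks = q, [list(b) for b in blocks]
    assert best_blocks is not None
    membership = {
        idx.nodes[i]: cid + 1 for cid, block in enumerate(best_blocks) for i in block
    }
    part = Partition.from_membership(membership)
    return part, modularity(net, part, directed_normalization)


# ---------------------------------------------------------------------------
# cross-wave comparison
# ---------------------------------------------------------------------------


@dataclass
class CommunityFlow:
    """Cross-wave membership contingency plus per-community composition."""

    contingency: pd.DataFrame  # wave-1 community x wave-2 community
    composition1: pd.DataFrame  # community x (group | gender) counts, wave 1
    composition2: pd.DataFrame


def _composition(
    partition: Partition, roster: Roster, nodes: Iterable[str]
) -> pd.DataFrame:
    rows = []
    for u in nodes:
        if u not in partition.membership:
            continue
        rows.append(
            {
                "community": partition[u],
                "group": roster.group_of(u),
                "gender": roster.gender_of(u),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    by_group = df.pivot_table(
        index="group", columns="community", aggfunc="size", fill_value=0
    )
    by_gender = df.pivot_table(
        index="gender", columns="community", aggfunc="size", fill_value=0
    )
    return pd.concat({"group": by_group, "gender": by_gender}, names=["attribute"])


def community_flows(
    pair: NetworkPair,
    partition1: Partition,
    partition2: Partition,
    roster: Optional[Roster] = None,
) -> CommunityFlow:
    """Contingency matrix of community membership over common participants,
    plus group and gender composition of each community in each wave."""
    roster = roster or pair.roster
    common = [
        u
        for u in roster.common_participants()
        if u in partition1.membership and u in partition2.membership
    ]
    k1 = sorted(set(partition1.membership.values()))
    k2 = sorted(set(partition2.membership.values()))
    mat = pd.DataFrame(0, index=k1, columns=k2)
    for u in common:
        mat.loc[partition1[u], partition2[u]] += 1
    mat.index.name = "wave1_community"
    mat.columns.name = "wave2_community"
    comp1 = _composition(partition1, roster, partition1.membership)
    comp2 = _composition(partition2, roster, partition2.membership)
    return CommunityFlow(contingency=mat, composition1=comp1, composition2=comp2)


def positive_only_comparison(
    net: SignedDirectedNetwork,
    seed: int = 0,
    n_restarts: int = 10,
    directed_normalization: str = "as_printed",
) -> dict:
    """Partition the signed network and its positive-only subnetwork, and
    report which signed communities merge when negative links are dropped.

    A set of signed communities "merges" when a single positive-only
    community contains (at least 80% of) each of them.
    """
    signed_part, signed_mod = optimize_partition(
        net, n_restarts=n_restarts, seed=seed,
        directed_normalization=directed_normalization,
    )
    pos_net = subnetwork(net, sign="positive")
    pos_part, pos_mod = optimize_partition(
        pos_net, n_restarts=n_restarts, seed=seed,
        directed_normalization=directed_normalization,
    )
    merges: dict[int, list[int]] = {}
    for pc, members in pos_part.communities().items():
        members = set(members)
        absorbed = []
        for sc, smembers in signed_part.communities().items():
            smembers = set(smembers)
            if smembers and len(smembers & members) / len(smembers) >= 0.8:
                absorbed.append(sc)
        if len(absorbed) >= 2:
            merges[pc] = absorbed
    return {
        "signed_partition": signed_part,
        "signed_modularity": signed_mod,
        "positive_partition": pos_part,
        "positive_modularity": pos_mod,
        "merged_communities": merges,
    }
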