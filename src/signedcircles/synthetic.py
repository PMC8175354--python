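"""Synthetic two-wave signed nomination networks.

The generator emulates a school cohort: a handful of class groups, each
with a configurable gender mix and two planted friendship communities, in
which every student nominates an inner circle of best friends (weight +2)
and an outer ring of friends (+1), plus a sparse set of enmities (-1/-2).
Circle sizes are Poisson: C1 ~ Poisson(mean_C1) and the outer ring
l2 = C2 - C1 ~ Poisson(mean_C1 * (circle_ratio - 1)), so the expected
cumulative ratio C2/C1 is ``circle_ratio`` and the layer-ratio parameter
mu = log(l2/l1) concentrates around log(circle_ratio - 1).

Reciprocity is built in by construction rather than by adding reverse
edges: a target fraction of out-slots is consumed by mutual dyads (one slot
at each endpoint) before the remaining slots are filled with one-way
nominations that avoid accidental reciprocation.  This keeps every ego's
drawn (C1, C2) exact, so circle statistics and reciprocity can be
controlled independently.

Positive nominations stay within the ego's group (planted communities are
blocks inside groups); targets are biased toward the ego's own community
(``p_intra_community``) and own gender (``gender_homophily``).  Negative
nominations are biased across communities.  Wave 2 drifts the circle means
and reassigns a churn fraction of students to a different community.

Also provided: a perfectly balanced two-faction network (all triangles
balanced by construction) and a signed planted-partition benchmark for the
community optimizer.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from signedcircles.core import (
    NetworkPair,
    Roster,
    RosterEntry,
    SignedDirectedNetwork,
    ValidationError,
)
from signedcircles.community import Partition

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_wave",
    "generate_pair",
    "generate_balanced",
    "planted_partition_signed",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic nomination cohort.

    Defaults emulate a five-group, 151-student year with wave-1 intra-group
    circle means around C1 ~ 9 and C2 ~ 17, positive reciprocity around
    0.57, about five negative nominations per student, and a wave-2 shift
    toward fewer best friends and relatively more plain friends.
    """

    group_sizes: tuple[int, ...] = (29, 30, 30, 31, 31)
    girl_fraction: tuple[float, ...] = (0.69, 0.44, 0.50, 0.48, 0.52)
    mean_C1: float = 9.0
    circle_ratio: float = 1.9
    p_intra_community: float = 0.7
    gender_homophily: float = 0.7
    reciprocity_target: float = 0.57
    neg_rate: float = 5.0
    neg_cross_community_bias: float = 0.8
    neg_inner_fraction: float = 0.3
    community_gender_bias: float = 0.8
    n_communities_per_group: int = 2
    wave2_drift: tuple[float, float, float] = (-2.5, 0.65, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_sizes or any(n <= 0 for n in self.group_sizes):
            raise ConfigError("group_sizes must be positive")
        if len(self.girl_fraction) != len(self.group_sizes):
            raise ConfigError("girl_fraction must match group_sizes in length")
        props = list(self.girl_fraction) + [
            self.p_intra_community,
            self.gender_homophily,
            self.reciprocity_target,
            self.neg_cross_community_bias,
            self.neg_inner_fraction,
            self.community_gender_bias,
            self.wave2_drift[2],
        ]
        if any(not (0.0 <= p <= 1.0) for p in props):
            raise ConfigError("all proportions must lie in [0, 1]")
        if self.mean_C1 < 1:
            raise ConfigError("mean_C1 must be >= 1")
        if self.circle_ratio <= 1:
            raise ConfigError("circle_ratio must be > 1")
        if self.neg_rate < 0:
            raise ConfigError("neg_rate must be >= 0")
        if self.n_communities_per_group < 1:
            raise ConfigError("need at least one community per group")
        for wave in (1, 2):
            mean_c1, ratio = self.wave_means(wave)
            if mean_c1 < 1 or ratio <= 1:
                raise ConfigError("wave-2 drift makes circle parameters invalid")
            if mean_c1 * ratio > min(self.group_sizes) - 1:
                raise ConfigError(
                    "expected C2 exceeds group size: requested degrees infeasible"
                )

    def wave_means(self, wave: int) -> tuple[float, float]:
        """(mean_C1, circle_ratio) effective in the given wave."""
        if wave == 1:
            return self.mean_C1, self.circle_ratio
        if wave == 2:
            return (
                self.mean_C1 + self.wave2_drift[0],
                self.circle_ratio + self.wave2_drift[1],
            )
        raise ValueError(f"wave must be 1 or 2, got {wave}")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated wave."""

    communities: dict[str, str]  # node -> planted community label (group-scoped)
    intended_circles: dict[str, tuple[int, int]]  # node -> (C1, C2)
    realized_reciprocity: float

    def partition(self, nodes: Optional[Sequence[str]] = None) -> Partition:
        labels = {c: i + 1 for i, c in enumerate(sorted(set(self.communities.values())))}
        members = nodes if nodes is not None else self.communities
        return Partition.from_membership(
            {u: labels[self.communities[u]] for u in members}
        )


def _group_labels(k: int) -> list[str]:
    letters = string.ascii_uppercase
    return [letters[i] if i < 26 else f"G{i}" for i in range(k)]


def _make_roster(config: GeneratorConfig) -> Roster:
    rng = np.random.default_rng([config.seed, 977])
    entries = []
    sid = 0
    for g, (n, gf) in enumerate(zip(config.group_sizes, config.girl_fraction)):
        label = _group_labels(len(config.group_sizes))[g]
        n_girls = int(round(gf * n))
        genders = np.array(["girl"] * n_girls + ["boy"] * (n - n_girls))
        rng.shuffle(genders)
        for gender in genders:
            sid += 1
            entries.append(RosterEntry(f"s{sid:03d}", label, str(gender), True, True))
    return Roster(entries)


def _plant_communities(
    config: GeneratorConfig, roster: Roster, wave: int
) -> dict[str, str]:
    """Assign each student to a gender-biased block within their group; for
    wave 2, churn a fraction of students to a different block."""
    rng = np.random.default_rng([config.seed, 571])
    comms: dict[str, str] = {}
    k = config.n_communities_per_group
    for label in sorted(roster.groups):
        members = [e for e in roster if e.group == label]
        girls = [e.student_id for e in members if e.gender == "girl"]
        boys = [e.student_id for e in members if e.gender != "girl"]
        rng.shuffle(girls)
        rng.shuffle(boys)
        n = len(members)
        sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
        # alternate gender bias across blocks: odd blocks girl-heavy
        bias = [
            config.community_gender_bias if i % 2 == 0 else 1 - config.community_gender_bias
            for i in range(k)
        ]
        for i, (size, b) in enumerate(zip(sizes, bias)):
            want_girls = min(len(girls), int(round(b * size)))
            want_girls = max(want_girls, size - len(boys))
            block = [girls.pop() for _ in range(want_girls)]
            block += [boys.pop() for _ in range(size - want_girls)]
            for u in block:
                comms[u] = f"{label}:{i + 1}"
    if wave == 2 and k > 1 and config.wave2_drift[2] > 0:
        churn_rng = np.random.default_rng([config.seed, 733])
        ids = sorted(comms)
        n_churn = int(round(config.wave2_drift[2] * len(ids)))
        movers = churn_rng.choice(len(ids), size=n_churn, replace=False)
        for m in movers:
            u = ids[m]
            group = comms[u].split(":")[0]
            options = [f"{group}:{i + 1}" for i in range(k) if f"{group}:{i + 1}" != comms[u]]
            comms[u] = options[churn_rng.integers(len(options))]
    return comms


def _weighted_choice(rng: np.random.Generator, items: list, weights: np.ndarray):
    total = weights.sum()
    if total <= 0:
        return items[rng.integers(len(items))]
    return items[rng.choice(len(items), p=weights / total)]


def generate_wave(
    config: GeneratorConfig, wave: int = 1
) -> tuple[Roster, SignedDirectedNetwork, SyntheticTruth]:
    """Generate one survey wave of the synthetic cohort.

    Deterministic given ``config.seed`` and ``wave``; the roster and the
    wave-1 planted communities are shared across waves of the same config.
    """
    mean_c1, ratio = config.wave_means(wave)
    roster = _make_roster(config)
    comms = _plant_communities(config, roster, wave)
    rng = np.random.default_rng([config.seed, wave, 131])
    net = SignedDirectedNetwork(roster.ids)
    intended: dict[str, tuple[int, int]] = {}

    for label in sorted(roster.groups):
        members = sorted(e.student_id for e in roster if e.group == label)
        n_g = len(members)
        gender = {u: roster.gender_of(u) for u in members}
        # --- draw circle sizes, truncated to feasible range
        c1 = rng.poisson(mean_c1, size=n_g)
        l2 = rng.poisson(mean_c1 * (ratio - 1.0), size=n_g)
        c1 = np.minimum(c1, n_g - 1)
        l2 = np.minimum(l2, n_g - 1 - c1)
        for u, a, b in zip(members, c1, l2):
            intended[u] = (int(a), int(a + b))
        rem_inner = dict(zip(members, (int(x) for x in c1)))
        rem_outer = dict(zip(members, (int(x) for x in l2)))

        def take_slot(u: str) -> int:
            """Consume one random remaining out-slot of u; return weight."""
            ri, ro = rem_inner[u], rem_outer[u]
            if ri and (not ro or rng.random() < ri / (ri + ro)):
                rem_inner[u] -= 1
                return 2
            rem_outer[u] -= 1
            return 1

        def pref_weight(u: str, v: str) -> float:
            w = (
                config.p_intra_community
                if comms[u] == comms[v]
                else 1 - config.p_intra_community
            )
            w *= (
                config.gender_homophily
                if gender[u] == gender[v]
                else 1 - config.gender_homophily
            )
            return w

        # --- mutual dyads
        total_slots = int(c1.sum() + l2.sum())
        n_mutual = int(round(config.reciprocity_target * total_slots / 2))
        dyads: set[tuple[str, str]] = set()
        failures = 0
        for _ in range(n_mutual):
            active = [u for u in members if rem_inner[u] + rem_outer[u] > 0]
            if len(active) < 2:
                break
            wts = np.array([rem_inner[u] + rem_outer[u] for u in active], dtype=float)
            ego = _weighted_choice(rng, active, wts)
            cands = [
                v
                for v in active
                if v != ego and (min(ego, v), max(ego, v)) not in dyads
            ]
            if not cands:
                failures += 1
                if failures > 20:
                    break
                continue
            cw = np.array([pref_weight(ego, v) for v in cands])
            alter = _weighted_choice(rng, cands, cw)
            dyads.add((min(ego, alter), max(ego, alter)))
            net.add_edge(ego, alter, take_slot(ego))
            net.add_edge(alter, ego, take_slot(alter))

        # --- one-way fill (skipped when full reciprocity was requested)
        if config.reciprocity_target < 1.0:
            order = list(members)
            rng.shuffle(order)
            for ego in order:
                while rem_inner[ego] + rem_outer[ego] > 0:
                    cands = [
                        v for v in members if v != ego and not net.has_edge(ego, v)
                    ]
                    # avoid accidental reciprocation where possible
                    unrequited = [v for v in cands if not net.has_edge(v, ego)]
                    pool = unrequited or cands
                    if not pool:
                        rem_inner[ego] = rem_outer[ego] = 0
                        break
                    cw = np.array([pref_weight(ego, v) for v in pool])
                    alter = _weighted_choice(rng, pool, cw)
                    net.add_edge(ego, alter, take_slot(ego))

        # --- negative nominations
        if config.neg_rate > 0:
            for ego in members:
                k = int(rng.poisson(config.neg_rate))
                cands = [v for v in members if v != ego and not net.has_edge(ego, v)]
                k = min(k, len(cands))
                if k == 0:
                    continue
                cw = np.array(
                    [
                        config.neg_cross_community_bias
                        if comms[ego] != comms[v]
                        else 1 - config.neg_cross_community_bias
                        for v in cands
                    ]
                )
                total = cw.sum()
                p = cw / total if total > 0 else None
                if p is not None:
                    k = min(k, int(np.count_nonzero(cw)))
                    if k == 0:
                        continue
                chosen = rng.choice(len(cands), size=k, replace=False, p=p)
                for ci in chosen:
                    w = -2 if rng.random() < config.neg_inner_fraction else -1
                    net.add_edge(ego, cands[ci], w)

    pos_edges = [(u, v) for u, v, w in net.edges() if w > 0]
    mutual = sum(1 for u, v in pos_edges if (net.weight(v, u) or 0) > 0)
    realized = mutual / len(pos_edges) if pos_edges else float("nan")
    truth = SyntheticTruth(
        communities=comms, intended_circles=intended, realized_reciprocity=realized
    )
    return roster, net, truth


def generate_pair(
    config: GeneratorConfig,
) -> tuple[NetworkPair, SyntheticTruth, SyntheticTruth]:
    """Generate both waves: wave 2 uses the drifted circle parameters and a
    churned community assignment over the same roster."""
    roster, net1, truth1 = generate_wave(config, 1)
    _, net2, truth2 = generate_wave(config, 2)
    return NetworkPair(net1, net2, roster), truth1, truth2


def generate_balanced(
    two_faction_sizes: tuple[int, int],
    p_within: float = 1.0,
    p_between: float = 1.0,
    seed: int = 0,
) -> SignedDirectedNetwork:
    """Perfectly balanced network: two all-positive factions joined only by
    negative links, every edge reciprocated.  By construction every triangle
    has an even number of negative edges."""
    n1, n2 = two_faction_sizes
    if n1 < 0 or n2 < 0 or n1 + n2 < 1:
        raise ConfigError("faction sizes must be nonnegative, at least one node")
    for p in (p_within, p_between):
        if not 0 <= p <= 1:
            raise ConfigError("densities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    faction = {f"a{i:03d}": 0 for i in range(n1)}
    faction.update({f"b{i:03d}": 1 for i in range(n2)})
    nodes = sorted(faction)
    net = SignedDirectedNetwork(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if faction[u] == faction[v]:
                if rng.random() < p_within:
                    net.add_edge(u, v, 1)
                    net.add_edge(v, u, 1)
            elif rng.random() < p_between:
                net.add_edge(u, v, -1)
                net.add_edge(v, u, -1)
    return net


def planted_partition_signed(
    block_sizes: Sequence[int],
    p_in_pos: float,
    p_out_pos: float,
    p_in_neg: float,
    p_out_neg: float,
    seed: int = 0,
) -> tuple[SignedDirectedNetwork, Partition]:
    """Directed signed planted-partition benchmark.

    Every ordered pair gets independently a positive edge (probability
    depending on whether the pair shares a block), otherwise possibly a
    negative edge.  Recoverable signal needs denser positive links inside
    blocks and denser negative links between them.
    """
    for p in (p_in_pos, p_out_pos, p_in_neg, p_out_neg):
        if not 0 <= p <= 1:
            raise ConfigError("probabilities must lie in [0, 1]")
    if p_in_pos + p_in_neg > 1 or p_out_pos + p_out_neg > 1:
        raise ConfigError("per-pair positive+negative probability exceeds 1")
    rng = np.random.default_rng(seed)
    block = {}
    nodes = []
    for b, size in enumerate(block_sizes):
        for i in range(size):
            u = f"n{len(nodes):03d}"
            nodes.append(u)
            block[u] = b + 1
    net = SignedDirectedNetwork(nodes)
    for u in nodes:
        for v in nodes:
            if u == v:
                continue
            same = block[u] == block[v]
            pp = p_in_pos if same else p_out_pos
            pn = p_in_neg if same else p_out_neg
            r = rng.random()
            if r < pp:
                net.add_edge(u, v, 1)
            elif r < pp + pn:
                net.add_edge(u, v, -1)
    return net, Partition.from_membership(block)
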