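"""Domain types, survey-record ingestion, link-weight resolution and I/O.

A nomination survey yields directed, signed, weighted links between students.
Each student answers, per wave, which classmates are friends (two intensity
levels: "friend" and "best friend") and which are enemies ("enemy" and
"worst enemy").  A resolved link carries weight in {-2, -1, 1, 2}:

====================  =========  ======
report                intensity  weight
====================  =========  ======
best friend           1 (inner)    +2
friend                2 (outer)    +1
enemy                 2 (outer)    -1
worst enemy           1 (inner)    -2
====================  =========  ======

When the same ordered pair is reported at both intensities of one sign, the
most intense report wins; when it is reported with both signs, the two
resolved signed weights are summed and the link is dropped if the sum is
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "RosterEntry",
    "Roster",
    "NominationRecord",
    "SignedDirectedNetwork",
    "NetworkPair",
    "load_roster",
    "load_nominations",
    "load_premerge_nominations",
    "resolve_weights",
    "subnetwork",
    "write_graphml",
    "read_graphml",
]

VALID_WEIGHTS = frozenset({-2, -1, 1, 2})

#: Question number -> (sign, merged intensity).  The survey asked three
#: nested questions per sign; the two broader levels are merged, so the
#: broadest two questions map to the outer level and the narrowest to the
#: inner one.
QUESTION_MAP = {
    1: ("positive", 2),
    2: ("positive", 2),
    3: ("positive", 1),
    4: ("negative", 2),
    5: ("negative", 2),
    6: ("negative", 1),
}


class FormatError(ValueError):
    """Malformed input file (missing column, bad value domain)."""


class ValidationError(ValueError):
    """Input violates a domain invariant (duplicate id, self-nomination...)."""


@dataclass(frozen=True)
class RosterEntry:
    student_id: str
    group: str
    gender: str
    participated_wave1: bool
    participated_wave2: bool


class Roster:
    """Immutable table of surveyed students with group and gender labels."""

    def __init__(self, entries: Iterable[RosterEntry]):
        self._entries: dict[str, RosterEntry] = {}
        for e in entries:
            if e.student_id in self._entries:
                raise ValidationError(f"duplicate student id {e.student_id!r}")
            if not e.group or not e.gender:
                raise ValidationError(
                    f"student {e.student_id!r}: group and gender must be non-empty"
                )
            self._entries[e.student_id] = e

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, student_id: str) -> bool:
        return student_id in self._entries

    def __iter__(self) -> Iterator[RosterEntry]:
        return iter(self._entries.values())

    def __getitem__(self, student_id: str) -> RosterEntry:
        try:
            return self._entries[student_id]
        except KeyError:
            raise KeyError(f"unknown student id {student_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return list(self._entries)

    @property
    def groups(self) -> set[str]:
        return {e.group for e in self._entries.values()}

    def group_of(self, student_id: str) -> str:
        return self[student_id].group

    def gender_of(self, student_id: str) -> str:
        return self[student_id].gender

    def participants(self, wave: int) -> list[str]:
        if wave == 1:
            return [e.student_id for e in self if e.participated_wave1]
        if wave == 2:
            return [e.student_id for e in self if e.participated_wave2]
        raise ValueError(f"wave must be 1 or 2, got {wave}")

    def common_participants(self) -> list[str]:
        return [
            e.student_id
            for e in self
            if e.participated_wave1 and e.participated_wave2
        ]


@dataclass(frozen=True)
class NominationRecord:
    """One survey answer: ego names alter with a sign and an intensity.

    Intensity 1 is the inner level ("best friend" / "worst enemy",
    |weight| = 2), intensity 2 the outer one ("friend" / "enemy",
    |weight| = 1).
    """

    ego: str
    alter: str
    wave: int
    sign: str  # "positive" | "negative"
    intensity: int  # 1 (inner) | 2 (outer)

    def __post_init__(self) -> None:
        if self.ego == self.alter:
            raise ValidationError(f"self-nomination by {self.ego!r}")
        if self.wave not in (1, 2):
            raise FormatError(f"wave must be 1 or 2, got {self.wave!r}")
        if self.sign not in ("positive", "negative"):
            raise FormatError(f"sign must be positive|negative, got {self.sign!r}")
        if self.intensity not in (1, 2):
            raise FormatError(f"intensity must be 1 or 2, got {self.intensity!r}")

    @property
    def weight(self) -> int:
        """Signed weight of this single report."""
        mag = 2 if self.intensity == 1 else 1
        return mag if self.sign == "positive" else -mag


class SignedDirectedNetwork:
    """Directed network with edge weights in {-2, -1, 1, 2}.

    Caches the totals w+ (sum of positive weights) and w- (sum of negative
    weights, non-positive) and per-node in/out strengths per sign, the
    quantities the signed modularity needs.
    """

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Mapping[tuple[str, str], int] | Iterable[tuple[str, str, int]] = (),
    ):
        self._nodes: set[str] = set(nodes)
        self._succ: dict[str, dict[str, int]] = {u: {} for u in self._nodes}
        self._pred: dict[str, dict[str, int]] = {u: {} for u in self._nodes}
        if isinstance(edges, Mapping):
            items = ((u, v, w) for (u, v), w in edges.items())
        else:
            items = iter(edges)
        for u, v, w in items:
            self.add_edge(u, v, w)

    def add_edge(self, u: str, v: str, w: int) -> None:
        if u == v:
            raise ValidationError(f"self-loop on {u!r}")
        if w not in VALID_WEIGHTS:
            raise ValidationError(f"weight must be in {{-2,-1,1,2}}, got {w}")
        for x in (u, v):
            if x not in self._nodes:
                self._nodes.add(x)
                self._succ[x] = {}
                self._pred[x] = {}
        self._succ[u][v] = w
        self._pred[v][u] = w

    # -- basic queries -------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return sum(len(d) for d in self._succ.values())

    def __contains__(self, node: str) -> bool:
        return node in self._nodes

    def edges(self) -> Iterator[tuple[str, str, int]]:
        for u, nbrs in self._succ.items():
            for v, w in nbrs.items():
                yield u, v, w

    def weight(self, u: str, v: str) -> Optional[int]:
        return self._succ.get(u, {}).get(v)

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._succ.get(u, {})

    def out_edges(self, u: str) -> dict[str, int]:
        return dict(self._succ[u])

    def in_edges(self, v: str) -> dict[str, int]:
        return dict(self._pred[v])

    # -- cached totals -------------------------------------------------

    @property
    def w_plus(self) -> int:
        """Total positive strength (sum of positive weights)."""
        return sum(w for _, _, w in self.edges() if w > 0)

    @property
    def w_minus(self) -> int:
        """Total negative strength (sum of negative weights, <= 0)."""
        return sum(w for _, _, w in self.edges() if w < 0)

    def out_strength(self, u: str, sign: str = "positive") -> int:
        ws = self._succ[u].values()
        if sign == "positive":
            return sum(w for w in ws if w > 0)
        return sum(-w for w in ws if w < 0)

    def in_strength(self, v: str, sign: str = "positive") -> int:
        ws = self._pred[v].values()
        if sign == "positive":
            return sum(w for w in ws if w > 0)
        return sum(-w for w in ws if w < 0)

    def copy(self) -> "SignedDirectedNetwork":
        return SignedDirectedNetwork(self._nodes, list(self.edges()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedDirectedNetwork):
            return NotImplemented
        return self._nodes == other._nodes and self._succ == other._succ

    def __repr__(self) -> str:
        return (
            f"SignedDirectedNetwork(n={self.n_nodes}, m={self.n_edges}, "
            f"w+={self.w_plus}, w-={self.w_minus})"
        )


@dataclass
class NetworkPair:
    """The two survey waves of one cohort plus the shared roster."""

    wave1: SignedDirectedNetwork
    wave2: SignedDirectedNetwork
    roster: Roster

    def __post_init__(self) -> None:
        ids = set(self.roster.ids)
        for wave, net in ((1, self.wave1), (2, self.wave2)):
            extra = net.nodes - ids
            if extra:
                raise ValidationError(
                    f"wave {wave} contains nodes absent from roster: {sorted(extra)[:5]}"
                )


# ---------------------------------------------------------------------------
# file ingestion
# ---------------------------------------------------------------------------

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", ""}


def _as_bool(value: object, column: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY or s == "nan":
        return False
    raise FormatError(f"column {column!r}: cannot parse boolean from {value!r}")


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def load_roster(path) -> Roster:
    """Read a roster CSV with columns id, group, gender, wave1, wave2."""
    df = _read_csv(path, ["id", "group", "gender", "wave1", "wave2"])
    entries = [
        RosterEntry(
            student_id=str(row["id"]).strip(),
            group=str(row["group"]).strip(),
            gender=str(row["gender"]).strip(),
            participated_wave1=_as_bool(row["wave1"], "wave1"),
            participated_wave2=_as_bool(row["wave2"], "wave2"),
        )
        for _, row in df.iterrows()
    ]
    return Roster(entries)


def load_nominations(
    path, roster: Roster
) -> tuple[list[NominationRecord], list[dict]]:
    """Read a nominations CSV (ego, alter, wave, sign, intensity).

    Rows referencing ids absent from the roster are rejected and reported;
    the second return value lists the rejected rows with reasons.
    """
    df = _read_csv(path, ["ego", "alter", "wave", "sign", "intensity"])
    records: list[NominationRecord] = []
    rejected: list[dict] = []
    for i, row in df.iterrows():
        ego = str(row["ego"]).strip()
        alter = str(row["alter"]).strip()
        try:
            wave = int(row["wave"])
            intensity = int(row["intensity"])
        except ValueError as exc:
            raise FormatError(f"row {i}: {exc}") from exc
        unknown = [x for x in (ego, alter) if x not in roster]
        if unknown:
            rejected.append({"row": int(i), "reason": f"unknown id(s) {unknown}"})
            continue
        records.append(
            NominationRecord(
                ego=ego,
                alter=alter,
                wave=wave,
                sign=str(row["sign"]).strip().lower(),
                intensity=intensity,
            )
        )
    return records, rejected


def load_premerge_nominations(
    path, roster: Roster
) -> tuple[list[NominationRecord], list[dict]]:
    """Read pre-merge answers keyed by question number (1-6).

    Columns: ego, alter, wave, question.  Questions 1-3 are the nested
    positive levels, 4-6 the negative ones; the two broader levels of each
    sign are merged to the outer intensity.
    """
    df = _read_csv(path, ["ego", "alter", "wave", "question"])
    records: list[NominationRecord] = []
    rejected: list[dict] = []
    for i, row in df.iterrows():
        q = int(row["question"])
        if q not in QUESTION_MAP:
            raise FormatError(f"row {i}: question must be 1-6, got {q}")
        sign, intensity = QUESTION_MAP[q]
        ego, alter = str(row["ego"]).strip(), str(row["alter"]).strip()
        unknown = [x for x in (ego, alter) if x not in roster]
        if unknown:
            rejected.append({"row": int(i), "reason": f"unknown id(s) {unknown}"})
            continue
        records.append(
            NominationRecord(ego, alter, int(row["wave"]), sign, intensity)
        )
    return records, rejected


# ---------------------------------------------------------------------------
# weight resolution
# ---------------------------------------------------------------------------


def resolve_weights(
    records: Iterable[NominationRecord],
    wave: int,
    nodes: Optional[Iterable[str]] = None,
) -> SignedDirectedNetwork:
    """Collapse raw nominations of one wave into a resolved signed network.

    Per ordered pair and sign the most intense report wins (|w| = 2 beats
    |w| = 1); if both signs were reported the two resolved weights are
    summed, and the link is removed when the sum is zero.  The result
    therefore always has weights in {-2, -1, 1, 2}.

    ``nodes`` optionally seeds the node set (e.g. all wave participants),
    so isolated students remain present in the network.
    """
    if wave not in (1, 2):
        raise ValueError(f"wave must be 1 or 2, got {wave}")
    best: dict[tuple[str, str], dict[str, int]] = {}
    for rec in records:
        if rec.wave != wave:
            continue
        slot = best.setdefault((rec.ego, rec.alter), {})
        mag = abs(rec.weight)
        slot[rec.sign] = max(slot.get(rec.sign, 0), mag)
    net = SignedDirectedNetwork(nodes or ())
    for (ego, alter), per_sign in best.items():
        w = per_sign.get("positive", 0) - per_sign.get("negative", 0)
        if w != 0:
            net.add_edge(ego, alter, w)
    return net


def subnetwork(
    net: SignedDirectedNetwork,
    roster: Optional[Roster] = None,
    groups: Optional[set[str]] = None,
    sign: Optional[str] = None,
) -> SignedDirectedNetwork:
    """Induced subgraph restricted to groups and/or a single edge sign."""
    if groups is not None:
        if roster is None:
            raise ValidationError("group restriction requires a roster")
        unknown = set(groups) - roster.groups
        if unknown:
            raise ValidationError(f"unknown group label(s) {sorted(unknown)}")
        keep = {u for u in net.nodes if u in roster and roster.group_of(u) in groups}
    else:
        keep = net.nodes
    if sign is not None and sign not in ("positive", "negative"):
        raise ValueError(f"sign must be positive|negative, got {sign!r}")
    out = SignedDirectedNetwork(keep)
    for u, v, w in net.edges():
        if u not in keep or v not in keep:
            continue
        if sign == "positive" and w < 0:
            continue
        if sign == "negative" and w > 0:
            continue
        out.add_edge(u, v, w)
    return out


# ---------------------------------------------------------------------------
# GraphML round-trip
# ---------------------------------------------------------------------------


def to_networkx(
    net: SignedDirectedNetwork, roster: Optional[Roster] = None
) -> nx.DiGraph:
    g = nx.DiGraph()
    for u in sorted(net.nodes):
        attrs = {}
        if roster is not None and u in roster:
            attrs = {"group": roster.group_of(u), "gender": roster.gender_of(u)}
        g.add_node(u, **attrs)
    for u, v, w in net.edges():
        g.add_edge(u, v, weight=int(w))
    return g


def write_graphml(
    net: SignedDirectedNetwork, path, roster: Optional[Roster] = None
) -> None:
    """Write the network as GraphML with integer edge weights and optional
    group/gender node attributes."""
    nx.write_graphml(to_networkx(net, roster), path)


def read_graphml(path) -> tuple[SignedDirectedNetwork, dict[str, dict]]:
    """Read a GraphML file written by :func:`write_graphml`.

    Returns the network and a map node -> attribute dict (group, gender when
    present).
    """
    try:
        g = nx.read_graphml(path)
    except Exception as exc:
        raise FormatError(f"cannot read GraphML {path}: {exc}") from exc
    net = SignedDirectedNetwork(g.nodes())
    for u, v, data in g.edges(data=True):
        net.add_edge(str(u), str(v), int(data["weight"]))
    attrs = {str(u): dict(data) for u, data in g.nodes(data=True)}
    return net, attrs
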