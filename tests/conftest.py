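from pathlib import Path

import numpy as np
import pytest

from signedcircles.core import SignedDirectedNetwork

DATA = Path(__file__).parent / "data"


@pytest.fixture
def toy_roster_path() -> Path:
    return DATA / "toy_roster.csv"


@pytest.fixture
def toy_nominations_path() -> Path:
    return DATA / "toy_nominations.csv"


def random_signed_network(
    rng: np.random.Generator,
    n: int,
    p: float = 0.4,
    weights=(-2, -1, 1, 2),
) -> SignedDirectedNetwork:
    """Erdos-Renyi directed network with random signed weights."""
    net = SignedDirectedNetwork([f"n{i}" for i in range(n)])
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                net.add_edge(f"n{i}", f"n{j}", int(rng.choice(weights)))
    return net


def naive_signed_modularity(net: SignedDirectedNetwork, membership: dict) -> tuple:
    """Independent double-loop evaluation of the signed directed modularity.

    Literal transcription of the defining sums: for each sign layer,
    Q_layer = 1/(2w) * sum_{i,j} (w_ij - sout_i * sin_j / (2w)) * [C_i == C_j]
    over all ordered node pairs including i == j, combined as
    Q = w+/(w+ + |w-|) Q+ - |w-|/(w+ + |w-|) Q-.
    """
    nodes = sorted(net.nodes)

    def layer(sign):
        w = {}
        for u, v, wt in net.edges():
            if (wt > 0) == (sign == "positive"):
                w[(u, v)] = abs(wt)
        total = sum(w.values())
        if total == 0:
            return 0.0, 0.0
        sout = {u: sum(wt for (a, _), wt in w.items() if a == u) for u in nodes}
        sin = {u: sum(wt for (_, b), wt in w.items() if b == u) for u in nodes}
        q = 0.0
        for i in nodes:
            for j in nodes:
                if membership[i] == membership[j]:
                    q += w.get((i, j), 0) - sout[i] * sin[j] / (2 * total)
        return q / (2 * total), total

    qp, wp = layer("positive")
    qm, wm = layer("negative")
    tot = wp + wm
    q = (wp / tot) * qp - (wm / tot) * qm if tot else 0.0
    return q, qp, qm
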