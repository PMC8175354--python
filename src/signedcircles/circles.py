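"""Per-ego circle sizes and the mu/rho layer-ratio parameters.

An ego's positive nominations split into an inner circle (C1, the "best
friend" reports, |weight| = 2) and a cumulative outer circle (C2, all
positive reports).  Under the resource-allocation model of layered personal
networks, consecutive rings satisfy l_{k+1}/l_k = e^{mu |Delta s_k|}; with
two elicited layers and unit cost increments this reduces to the closed form

    mu = log(l2 / l1) = log((C2 - C1) / C1)

(natural log).  mu > 0 means a typical top-light circle structure (each ring
about e^mu times the previous; mu ~ 0.7 for the canonical ratio-3 scaling),
mu < 0 means most relations are already in the inner circle.  rho is the
same statistic computed on received nominations (in-degrees).

mu is undefined when C1 = 0 or C2 = C1; such egos are flagged and excluded
from aggregates rather than imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from signedcircles.core import NetworkPair, Roster, SignedDirectedNetwork

__all__ = [
    "CircleProfile",
    "GroupMuSummary",
    "IncrementTestReport",
    "circle_sizes",
    "compute_mu",
    "compute_rho",
    "circle_profile",
    "cohort_profiles",
    "mu_increment",
    "group_mu_table",
    "increment_tests",
]


@dataclass(frozen=True)
class CircleProfile:
    ego: str
    wave: int
    scope: str  # "all" | "intra_group"
    sign: str  # "positive" | "negative"
    direction: str  # "out" | "in"
    C1: int
    C2: int

    @property
    def mu(self) -> Optional[float]:
        return compute_mu(self.C1, self.C2)


@dataclass(frozen=True)
class GroupMuSummary:
    group: str
    wave: str  # "1", "2" or "increment"
    mean: float
    sd: float
    n: int
    n_excluded: int = 0


@dataclass
class IncrementTestReport:
    """Normality, per-group mean shift, and between-group comparisons of
    the per-student change in mu."""

    shapiro: dict[str, tuple[float, float]]
    one_sample_t: dict[str, tuple[float, float]]
    anova_F: Optional[float]
    anova_df: Optional[tuple[int, int]]
    anova_p: Optional[float]
    tukey: Optional[pd.DataFrame]
    skipped: dict[str, str]


def circle_sizes(
    net: SignedDirectedNetwork,
    ego: str,
    sign: str = "positive",
    scope: str = "all",
    direction: str = "out",
    roster: Optional[Roster] = None,
) -> tuple[int, int]:
    """Inner (C1) and cumulative (C2) circle counts for one ego.

    C1 counts edges of the given sign and direction with |weight| = 2,
    C2 all edges of that sign and direction.  ``scope="intra_group"``
    restricts alters to the ego's own group (requires a roster).
    """
    if ego not in net:
        raise KeyError(f"ego {ego!r} not in network")
    if direction == "out":
        nbrs = net.out_edges(ego)
    elif direction == "in":
        nbrs = net.in_edges(ego)
    else:
        raise ValueError(f"direction must be out|in, got {direction!r}")
    if sign == "positive":
        nbrs = {a: w for a, w in nbrs.items() if w > 0}
    elif sign == "negative":
        nbrs = {a: w for a, w in nbrs.items() if w < 0}
    else:
        raise ValueError(f"sign must be positive|negative, got {sign!r}")
    if scope == "intra_group":
        if roster is None:
            raise ValueError("scope='intra_group' requires a roster")
        own = roster.group_of(ego)
        nbrs = {
            a: w for a, w in nbrs.items() if a in roster and roster.group_of(a) == own
        }
    elif scope != "all":
        raise ValueError(f"scope must be all|intra_group, got {scope!r}")
    c1 = sum(1 for w in nbrs.values() if abs(w) == 2)
    return c1, len(nbrs)


def compute_mu(C1: int, C2: int) -> Optional[float]:
    """log((C2 - C1)/C1), or None when the ratio is undefined.

    Undefined when the inner circle is empty (C1 = 0) or the outer ring is
    empty (C2 = C1); C2 < C1 violates the cumulative-count invariant.
    """
    if C1 < 0 or C2 < 0:
        raise ValueError("circle counts must be nonnegative")
    if C2 < C1:
        raise ValueError(f"C2 must be >= C1 (cumulative), got C1={C1}, C2={C2}")
    if C1 == 0 or C2 == C1:
        return None
    return math.log((C2 - C1) / C1)


def compute_rho(
    net: SignedDirectedNetwork,
    ego: str,
    roster: Optional[Roster] = None,
    scope: str = "all",
    sign: str = "positive",
) -> Optional[float]:
    """mu computed on received nominations (in-degree circle sizes)."""
    c1, c2 = circle_sizes(net, ego, sign=sign, scope=scope, direction="in", roster=roster)
    return compute_mu(c1, c2)


def circle_profile(
    net: SignedDirectedNetwork,
    ego: str,
    wave: int,
    sign: str = "positive",
    scope: str = "all",
    direction: str = "out",
    roster: Optional[Roster] = None,
) -> CircleProfile:
    c1, c2 = circle_sizes(net, ego, sign=sign, scope=scope, direction=direction, roster=roster)
    return CircleProfile(ego, wave, scope, sign, direction, c1, c2)


def cohort_profiles(
    net: SignedDirectedNetwork,
    wave: int,
    roster: Roster,
    sign: str = "positive",
    scope: str = "all",
    direction: str = "out",
) -> list[CircleProfile]:
    """Circle profiles for every wave participant present in the network."""
    return [
        circle_profile(net, ego, wave, sign, scope, direction, roster)
        for ego in roster.participants(wave)
        if ego in net
    ]


def mu_increment(
    pair: NetworkPair,
    scope: str = "all",
    sign: str = "positive",
    direction: str = "out",
) -> tuple[dict[str, float], dict[str, int]]:
    """Per-student change mu(wave 2) - mu(wave 1).

    Only students who participated in both waves and have a defined mu in
    both are included.  The second return value reports eligibility counts:
    common participants, defined in each wave, and retained.
    """
    increments: dict[str, float] = {}
    common = pair.roster.common_participants()
    n_def1 = n_def2 = 0
    for ego in common:
        mus = []
        for net in (pair.wave1, pair.wave2):
            if ego not in net:
                mus.append(None)
                continue
            c1, c2 = circle_sizes(
                net, ego, sign=sign, scope=scope, direction=direction, roster=pair.roster
            )
            mus.append(compute_mu(c1, c2))
        n_def1 += mus[0] is not None
        n_def2 += mus[1] is not None
        if mus[0] is not None and mus[1] is not None:
            increments[ego] = mus[1] - mus[0]
    counts = {
        "common_participants": len(common),
        "defined_wave1": n_def1,
        "defined_wave2": n_def2,
        "retained": len(increments),
    }
    return increments, counts


def _summary(values: Sequence[float], group: str, wave: str, n_excluded: int) -> GroupMuSummary:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return GroupMuSummary(group, wave, float(arr.mean()), sd, int(arr.size), n_excluded)


def group_mu_table(
    profiles_by_wave: dict[int, Iterable[CircleProfile]],
    increments: Optional[dict[str, float]] = None,
    roster: Optional[Roster] = None,
) -> pd.DataFrame:
    """Per-group and TOTAL mean(SD) of mu per wave, plus the increment column.

    Egos with undefined mu are excluded from the statistics and counted in
    ``n_excluded``.  Empty cells are reported as missing (NaN), never zero.
    """
    rows: list[GroupMuSummary] = []
    for wave, profiles in sorted(profiles_by_wave.items()):
        by_group: dict[str, list[float]] = {}
        excluded: dict[str, int] = {}
        for p in profiles:
            if roster is not None:
                g = roster.group_of(p.ego)
            else:
                g = "TOTAL"
            mu = p.mu
            if mu is None:
                excluded[g] = excluded.get(g, 0) + 1
                if g != "TOTAL":
                    excluded["TOTAL"] = excluded.get("TOTAL", 0) + 1
                continue
            by_group.setdefault(g, []).append(mu)
            if g != "TOTAL":
                by_group.setdefault("TOTAL", []).append(mu)
        for g in sorted(by_group):
            rows.append(_summary(by_group[g], g, str(wave), excluded.get(g, 0)))
    if increments is not None:
        by_group = {}
        for ego, d in increments.items():
            g = roster.group_of(ego) if roster is not None else "TOTAL"
            by_group.setdefault(g, []).append(d)
            if g != "TOTAL":
                by_group.setdefault("TOTAL", []).append(d)
        for g in sorted(by_group):
            rows.append(_summary(by_group[g], g, "increment", 0))
    df = pd.DataFrame(
        [
            {
                "group": r.group,
                "wave": r.wave,
                "mean": r.mean,
                "sd": r.sd,
                "n": r.n,
                "n_excluded": r.n_excluded,
            }
            for r in rows
        ]
    )
    return df


def increment_tests(
    increments_by_group: dict[str, Sequence[float]],
    min_n: int = 3,
) -> IncrementTestReport:
    """Standard test battery on the per-group mu increments.

    Per group: Shapiro-Wilk normality and a one-sample t-test of mean zero.
    Across groups: one-way ANOVA and Tukey HSD pairwise comparisons.
    Groups with fewer than ``min_n`` values are skipped with a reason.
    """
    shapiro: dict[str, tuple[float, float]] = {}
    ttests: dict[str, tuple[float, float]] = {}
    skipped: dict[str, str] = {}
    usable: dict[str, np.ndarray] = {}
    for g, vals in increments_by_group.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < min_n:
            skipped[g] = f"n={arr.size} < {min_n}"
            continue
        usable[g] = arr
        if np.ptp(arr) == 0:
            skipped[f"shapiro[{g}]"] = "zero variance"
            shapiro[g] = (float("nan"), float("nan"))
            # all values identical: t is 0 (mean 0) or infinite (mean != 0)
            if arr.mean() == 0:
                ttests[g] = (0.0, 1.0)
            else:
                ttests[g] = (math.copysign(float("inf"), arr.mean()), 0.0)
            continue
        w, p = stats.shapiro(arr)
        shapiro[g] = (float(w), float(p))
        t, p = stats.ttest_1samp(arr, 0.0)
        ttests[g] = (float(t), float(p))

    anova_F = anova_p = None
    anova_df = None
    tukey_df = None
    if len(usable) >= 2:
        groups = sorted(usable)
        samples = [usable[g] for g in groups]
        if np.ptp(np.concatenate(samples)) == 0:
            skipped["anova"] = "zero variance across all groups"
        else:
            F, p = stats.f_oneway(*samples)
            k = len(samples)
            N = sum(a.size for a in samples)
            anova_F, anova_p, anova_df = float(F), float(p), (k - 1, N - k)
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            data = np.concatenate(samples)
            labels = np.concatenate([[g] * usable[g].size for g in groups])
            res = pairwise_tukeyhsd(data, labels)
            tukey_df = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )
    else:
        skipped["anova"] = "fewer than 2 groups with enough data"
    return IncrementTestReport(
        shapiro=shapiro,
        one_sample_t=ttests,
        anova_F=anova_F,
        anova_df=anova_df,
        anova_p=anova_p,
        tukey=tukey_df,
        skipped=skipped,
    )
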