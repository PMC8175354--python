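"""End-to-end orchestration: ingest -> circles -> communities -> reciprocity
-> balance over a two-wave network pair, with per-stage sub-seeds, persisted
intermediates and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from signedcircles import __version__
from signedcircles.balance import permutation_balance_test, project
from signedcircles.circles import cohort_profiles, group_mu_table, increment_tests, mu_increment
from signedcircles.community import community_flows, modularity, optimize_partition
from signedcircles.core import (
    NetworkPair,
    NominationRecord,
    Roster,
    SignedDirectedNetwork,
    ValidationError,
    load_nominations,
    load_roster,
    resolve_weights,
    write_graphml,
)
from signedcircles.reciprocity import reciprocity, rewiring_null
from signedcircles.synthetic import GeneratorConfig, generate_pair

__all__ = ["RunConfig", "run", "stage_seed", "nominations_from_network", "write_simulation"]

_WEIGHT_TO_RECORD = {2: ("positive", 1), 1: ("positive", 2), -1: ("negative", 2), -2: ("negative", 1)}


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed: hashing keeps one stage's stream
    independent of whether another stage runs."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def nominations_from_network(net: SignedDirectedNetwork, wave: int) -> list[NominationRecord]:
    """Expand a resolved network back into one nomination record per edge
    (valid because generated networks carry single-report weights)."""
    return [
        NominationRecord(u, v, wave, *_WEIGHT_TO_RECORD[w]) for u, v, w in net.edges()
    ]


def write_simulation(pair: NetworkPair, truths, outdir: Path) -> None:
    """Persist a generated pair as roster.csv + nominations.csv + truth.json."""
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "id": e.student_id,
                "group": e.group,
                "gender": e.gender,
                "wave1": int(e.participated_wave1),
                "wave2": int(e.participated_wave2),
            }
            for e in pair.roster
        ]
    ).to_csv(outdir / "roster.csv", index=False)
    records = nominations_from_network(pair.wave1, 1) + nominations_from_network(
        pair.wave2, 2
    )
    pd.DataFrame(
        [
            {
                "ego": r.ego,
                "alter": r.alter,
                "wave": r.wave,
                "sign": r.sign,
                "intensity": r.intensity,
            }
            for r in records
        ]
    ).to_csv(outdir / "nominations.csv", index=False)
    truth_payload = {
        f"wave{i + 1}": {
            "communities": t.communities,
            "intended_circles": {u: list(c) for u, c in t.intended_circles.items()},
            "realized_reciprocity": t.realized_reciprocity,
        }
        for i, t in enumerate(truths)
    }
    (outdir / "truth.json").write_text(json.dumps(truth_payload, indent=2, sort_keys=True))


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``roster``/``nominations`` paths or ``generator`` must be
    given.  Stage toggles default to running everything.
    """

    seed: int = 0
    outdir: str = "signedcircles_out"
    roster: Optional[str] = None
    nominations: Optional[str] = None
    generator: Optional[dict] = None
    stages: dict = field(
        default_factory=lambda: {
            "circles": True,
            "communities": True,
            "reciprocity": True,
            "balance": True,
        }
    )
    circles: dict = field(default_factory=lambda: {"scope": "all", "direction": "out"})
    communities: dict = field(default_factory=lambda: {"n_restarts": 10})
    reciprocity: dict = field(
        default_factory=lambda: {"n_samples": 1000, "mode": "outdegree_preserving"}
    )
    balance: dict = field(
        default_factory=lambda: {"criterion": "a", "n_realizations": 10_000}
    )

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = RunConfig(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        has_files = self.roster is not None and self.nominations is not None
        if has_files == (self.generator is not None):
            raise ValidationError(
                "config needs either roster+nominations paths or a generator block"
            )


def _load_pair(cfg: RunConfig) -> tuple[NetworkPair, Optional[tuple]]:
    if cfg.generator is not None:
        gen = GeneratorConfig(**{**cfg.generator, "seed": cfg.generator.get("seed", cfg.seed)})
        pair, t1, t2 = generate_pair(gen)
        return pair, (t1, t2)
    roster = load_roster(cfg.roster)
    records, rejected = load_nominations(cfg.nominations, roster)
    if rejected:
        print(f"warning: rejected {len(rejected)} nomination rows")  # noqa: T201
    nets = {
        w: resolve_weights(records, w, nodes=roster.participants(w)) for w in (1, 2)
    }
    return NetworkPair(nets[1], nets[2], roster), None


def run(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the report bundle and writes
    CSV/JSON outputs plus a manifest under ``cfg.outdir``."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pair, truths = _load_pair(cfg)
    if truths is not None:
        write_simulation(pair, truths, outdir / "inputs")
    for w, net in ((1, pair.wave1), (2, pair.wave2)):
        write_graphml(net, outdir / f"wave{w}.graphml", pair.roster)

    bundle: dict = {"stages": {}}
    seeds: dict[str, int] = {}

    if cfg.stages.get("circles", True):
        scope = cfg.circles.get("scope", "all")
        direction = cfg.circles.get("direction", "out")
        profiles = {
            w: cohort_profiles(net, w, pair.roster, scope=scope, direction=direction)
            for w, net in ((1, pair.wave1), (2, pair.wave2))
        }
        incs, counts = mu_increment(pair, scope=scope, direction=direction)
        table = group_mu_table(profiles, incs, pair.roster)
        table.to_csv(outdir / "mu_table.csv", index=False)
        per_student = pd.DataFrame(
            [
                {
                    "ego": p.ego,
                    "wave": p.wave,
                    "scope": p.scope,
                    "sign": p.sign,
                    "direction": p.direction,
                    "C1": p.C1,
                    "C2": p.C2,
                    "mu": p.mu,
                }
                for w in (1, 2)
                for p in profiles[w]
            ]
        )
        per_student.to_csv(outdir / "circle_profiles.csv", index=False)
        by_group: dict[str, list[float]] = {}
        for ego, d in incs.items():
            by_group.setdefault(pair.roster.group_of(ego), []).append(d)
        tests = increment_tests(by_group)
        bundle["stages"]["circles"] = {
            "eligibility": counts,
            "anova_F": tests.anova_F,
            "anova_p": tests.anova_p,
            "one_sample_t": tests.one_sample_t,
            "skipped": tests.skipped,
        }

    if cfg.stages.get("communities", True):
        seeds["communities"] = stage_seed(cfg.seed, "communities")
        n_restarts = cfg.communities.get("n_restarts", 10)
        parts = {}
        for w, net in ((1, pair.wave1), (2, pair.wave2)):
            part, mod = optimize_partition(net, n_restarts=n_restarts, seed=seeds["communities"] + w)
            parts[w] = part
            pd.DataFrame(
                sorted(part.membership.items()), columns=["id", "community"]
            ).to_csv(outdir / f"communities_wave{w}.csv", index=False)
            bundle["stages"].setdefault("communities", {})[f"wave{w}"] = {
                "n_communities": part.n_communities,
                "Q": mod.Q,
                "Q_plus": mod.Q_plus,
                "Q_minus": mod.Q_minus,
            }
        flow = community_flows(pair, parts[1], parts[2])
        flow.contingency.to_csv(outdir / "community_flows.csv")
        flow.composition1.to_csv(outdir / "community_composition_wave1.csv")
        flow.composition2.to_csv(outdir / "community_composition_wave2.csv")

    if cfg.stages.get("reciprocity", True):
        seeds["reciprocity"] = stage_seed(cfg.seed, "reciprocity")
        rep = {}
        for w, net in ((1, pair.wave1), (2, pair.wave2)):
            null = rewiring_null(
                net,
                n_samples=cfg.reciprocity.get("n_samples", 1000),
                seed=seeds["reciprocity"] + w,
                mode=cfg.reciprocity.get("mode", "outdegree_preserving"),
            )
            rep[f"wave{w}"] = {
                "observed": null.observed,
                "null_mean": null.mean,
                "ci_low": null.ci_low,
                "ci_high": null.ci_high,
            }
        bundle["stages"]["reciprocity"] = rep

    if cfg.stages.get("balance", True):
        seeds["balance"] = stage_seed(cfg.seed, "balance")
        rep = {}
        for w, net in ((1, pair.wave1), (2, pair.wave2)):
            if sum(1 for _, _, wt in net.edges() if wt < 0) == 0:
                rep[f"wave{w}"] = {"skipped": "no negative edges"}
                continue
            g = project(net, cfg.balance.get("criterion", "a"))
            census, null, frac_below = permutation_balance_test(
                g,
                n_realizations=cfg.balance.get("n_realizations", 10_000),
                seed=seeds["balance"] + w,
            )
            rep[f"wave{w}"] = {
                "census": [census.n0, census.n1, census.n2, census.n3],
                "balanced": census.balanced,
                "unbalanced": census.unbalanced,
                "null_mean": null.mean,
                "null_ci": [null.ci_low, null.ci_high],
                "fraction_below": frac_below,
            }
        bundle["stages"]["balance"] = rep

    cfg_text = yaml.safe_dump(asdict(cfg), sort_keys=True)
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": cfg.seed,
        "stage_seeds": seeds,
    }
    bundle["manifest"] = manifest
    (outdir / "report.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return bundle
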