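"""Candidate-vs-effector-set relationship scoring on the interaction network.

The relationship score is a transparent 0-100 measure of how mechanistically
close a candidate protein sits to an effector set.  The default method decays
geometrically with shortest-path distance:

    score = 100 * (1/|E'|) * sum_{e in E'} lambda**d(c, e)

over the network-present effectors E', with lambda**inf == 0 for unreachable
effectors.  A candidate that *is* the sole effector scores 100; a candidate
disconnected from every effector scores 0.  A random-walk-with-restart
variant is provided for graphs where path multiplicity matters.

Scores are binned into the four published categories:
very high (>=92), high (78-92), medium (38-78), low (<38).
"""
from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np

from .network import InteractionNetwork, NetworkError, shortest_distances
from .characterization import CandidatePanel


class Category(enum.Enum):
    VERY_HIGH = "very_high"
    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"

    def __ge__(self, other: "Category") -> bool:
        order = [Category.LOW, Category.MEDIUM, Category.HIGH, Category.VERY_HIGH]
        return order.index(self) >= order.index(other)


@dataclass(frozen=True)
class ScoringConfig:
    method: Literal["decay_shortest_path", "random_walk_restart"] = "decay_shortest_path"
    decay: float = 0.5         # per-hop contribution factor (lambda)
    restart: float = 0.15      # random-walk restart probability
    mode: Literal["undirected", "directed"] = "undirected"
    t_very_high: float = 92.0
    t_high: float = 78.0
    t_medium: float = 38.0

    def __post_init__(self) -> None:
        if not 0 < self.decay < 1:
            raise ValueError("decay must be in (0, 1)")
        if not 0 < self.restart < 1:
            raise ValueError("restart must be in (0, 1)")
        if not self.t_very_high > self.t_high > self.t_medium > 0:
            raise ValueError("thresholds must satisfy t_very_high > t_high > t_medium > 0")


@dataclass
class RelationshipScore:
    candidate: str
    target_id: str
    score: float
    category: Category
    perm_p: float | None = None


def classify_relationship(score: float, cfg: ScoringConfig = ScoringConfig()) -> Category:
    """Bin a 0-100 score into the four published categories (lower bounds
    inclusive)."""
    if not 0 <= score <= 100:
        raise ValueError(f"score {score} outside [0, 100]")
    if score >= cfg.t_very_high:
        return Category.VERY_HIGH
    if score >= cfg.t_high:
        return Category.HIGH
    if score >= cfg.t_medium:
        return Category.MEDIUM
    return Category.LOW


def _present_effectors(net: InteractionNetwork, effectors: Iterable[str]) -> list[str]:
    present = [e for e in effectors if e in net]
    missing = sorted(set(effectors) - set(present))
    if missing:
        warnings.warn(f"effectors absent from network dropped: {missing}", stacklevel=3)
    if not present:
        raise NetworkError("no effector is present in the network")
    return present


def _decay_score(net: InteractionNetwork, candidate: str, present: Sequence[str],
                 cfg: ScoringConfig) -> float:
    dist = shortest_distances(net, candidate, mode=cfg.mode)
    total = sum(cfg.decay ** dist[e] for e in present if e in dist)
    return 100.0 * total / len(present)


def _rwr_score(net: InteractionNetwork, candidate: str, present: Sequence[str],
               cfg: ScoringConfig) -> float:
    g = net.graph(cfg.mode)
    pr = nx.pagerank(g, alpha=1.0 - cfg.restart, personalization={candidate: 1.0})
    p_self = pr.get(candidate, 0.0)
    if p_self <= 0:
        return 0.0
    mass = sum(pr.get(e, 0.0) for e in present) / len(present)
    # normalized so the trivial self-case (candidate == sole effector) is 100
    return min(100.0, 100.0 * mass / p_self)


def relationship_score(net: InteractionNetwork, candidate: str,
                       effectors: Iterable[str], cfg: ScoringConfig = ScoringConfig(),
                       target_id: str = "") -> RelationshipScore:
    """Score one candidate against an effector set.

    Effectors absent from the network are dropped with a warning (mirroring
    the exclusion of candidates without reported interactions); the candidate
    itself must be present.
    """
    if candidate not in net:
        raise NetworkError(f"candidate {candidate!r} not in network; "
                           "run validate_candidates first")
    present = _present_effectors(net, effectors)
    if cfg.method == "decay_shortest_path":
        score = _decay_score(net, candidate, present, cfg)
    elif cfg.method == "random_walk_restart":
        score = _rwr_score(net, candidate, present, cfg)
    else:  # pragma: no cover - config validation
        raise ValueError(f"unknown scoring method {cfg.method!r}")
    score = min(100.0, max(0.0, score))
    return RelationshipScore(candidate=candidate, target_id=target_id, score=score,
                             category=classify_relationship(score, cfg))


def rank_panel(net: InteractionNetwork, panel: CandidatePanel | Sequence[str],
               effectors: Iterable[str], cfg: ScoringConfig = ScoringConfig(),
               target_id: str = "") -> list[RelationshipScore]:
    """Score every retained candidate against the effector set and order the
    records by descending score, ties broken by gene symbol."""
    symbols = panel.symbols if isinstance(panel, CandidatePanel) else list(panel)
    if not symbols:
        raise ValueError("empty candidate panel")
    records = [relationship_score(net, c, effectors, cfg, target_id=target_id)
               for c in symbols]
    records.sort(key=lambda r: (-r.score, r.candidate))
    return records


def permutation_p(net: InteractionNetwork, candidate: str, effectors: Iterable[str],
                  cfg: ScoringConfig = ScoringConfig(), n_perm: int = 1000,
                  seed: int = 0) -> float:
    """Permutation p-value for a candidate's score under a random-node null.

    Null scores are computed for nodes drawn uniformly from the non-effector
    nodes of the network (the candidate itself excluded).  When the null
    population has at most ``n_perm`` members it is enumerated exhaustively
    (each node once); otherwise ``n_perm`` draws are sampled.  Add-one
    smoothing: p = (1 + #null >= observed) / (1 + #null).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    eff = set(effectors)
    observed = relationship_score(net, candidate, eff, cfg).score
    population = sorted(net.nodes - eff - {candidate})
    if not population:
        return 1.0
    if len(population) <= n_perm:
        draws = population
    else:
        rng = np.random.default_rng(seed)
        draws = list(rng.choice(population, size=n_perm, replace=False))
    exceed = 0
    for node in draws:
        if relationship_score(net, node, eff, cfg).score >= observed:
            exceed += 1
    return (1 + exceed) / (1 + len(draws))


def write_scores(records: Sequence[RelationshipScore], path) -> None:
    """Score table TSV: candidate, target_id, score, category, perm_p."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("candidate\ttarget_id\tscore\tcategory\tperm_p\n")
        for r in records:
            p = "" if r.perm_p is None else f"{r.perm_p:.6g}"
            fh.write(f"{r.candidate}\t{r.target_id}\t{r.score:.4f}\t{r.category.value}\t{p}\n")
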