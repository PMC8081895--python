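"""Triggering analysis: which candidates can activate the disease effectors.

"Activation" is operationalized as reachability on the interaction network: a
protein's *trigger set* is the subset of effectors it can reach (optionally
within a path-length bound, optionally restricted to net-activating sign
parity).  The individual probability of a protein is the fraction of
network-present effectors it triggers, displayed on a one-to-five star scale.
An ordered greedy maximum-coverage pass then reports how much of the effector
set a growing protein combination covers.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np

from .characterization import CandidatePanel
from .network import EdgeSign, InteractionNetwork


@dataclass(frozen=True)
class TriggerConfig:
    mode: Literal["undirected", "directed"] = "undirected"
    max_path_len: int | None = None       # None = unbounded
    sign_aware: bool = False
    star_breaks: tuple[float, ...] | None = None  # None = panel quintiles

    def __post_init__(self) -> None:
        if self.star_breaks is not None:
            b = self.star_breaks
            if len(b) != 4 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
                raise ValueError("star_breaks must be 4 strictly increasing cutpoints")
            if b[0] < 0 or b[-1] > 1:
                raise ValueError("star_breaks must lie in [0, 1]")


@dataclass
class TriggerResult:
    protein: str
    trigger_set: frozenset[str]
    individual_prob: float
    stars: int = 1
    greedy_rank: int | None = None
    cumulative_pct: float | None = None


def _signed_reachable(net: InteractionNetwork, protein: str,
                      cfg: TriggerConfig) -> set[str]:
    """BFS over (node, parity) states; a node counts as activated when some
    path of net-activating parity (even number of inhibitions) reaches it."""
    arcs: dict[str, list[tuple[str, int]]] = {}
    for e in net.edges:
        flip = 1 if e.sign is EdgeSign.INHIBITING else 0
        arcs.setdefault(e.source, []).append((e.target, flip))
        if not e.directed or cfg.mode == "undirected":
            arcs.setdefault(e.target, []).append((e.source, flip))
    seen = {(protein, 0)}
    frontier = [(protein, 0)]
    depth = 0
    activated = {protein}
    while frontier and (cfg.max_path_len is None or depth < cfg.max_path_len):
        depth += 1
        nxt = []
        for node, par in frontier:
            for tgt, flip in arcs.get(node, ()):
                state = (tgt, par ^ flip)
                if state not in seen:
                    seen.add(state)
                    nxt.append(state)
                    if state[1] == 0:
                        activated.add(tgt)
        frontier = nxt
    return activated


def trigger_set(net: InteractionNetwork, protein: str, effectors: Iterable[str],
                cfg: TriggerConfig = TriggerConfig()) -> frozenset[str]:
    """Effectors reachable from ``protein`` under the configured semantics."""
    eff = {e for e in effectors if e in net}
    if protein not in net:
        return frozenset()
    if cfg.sign_aware:
        reach = _signed_reachable(net, protein, cfg)
    else:
        g = net.graph(cfg.mode)
        reach = set(nx.single_source_shortest_path_length(
            g, protein, cutoff=cfg.max_path_len))
    return frozenset(eff & reach)


def _assign_stars(results: list[TriggerResult], cfg: TriggerConfig) -> None:
    if cfg.star_breaks is not None:
        breaks = cfg.star_breaks
    else:
        # data-driven: quintile cutpoints of the panel's probabilities
        probs = np.array([r.individual_prob for r in results], dtype=float)
        breaks = tuple(np.quantile(probs, [0.2, 0.4, 0.6, 0.8]))
    for r in results:
        stars = 1 + sum(1 for b in breaks if b < r.individual_prob)
        r.stars = min(5, stars)


def individual_scores(net: InteractionNetwork, panel: CandidatePanel | Sequence[str],
                      effectors: Iterable[str],
                      cfg: TriggerConfig = TriggerConfig()) -> list[TriggerResult]:
    """Trigger set, individual probability and star rating per panel protein.

    individual_prob = |trigger set| / |network-present effectors|.
    """
    symbols = panel.symbols if isinstance(panel, CandidatePanel) else list(panel)
    present = {e for e in effectors if e in net}
    if not present:
        raise ValueError("no effector present in the network")
    results = []
    for p in symbols:
        ts = trigger_set(net, p, present, cfg)
        results.append(TriggerResult(protein=p, trigger_set=ts,
                                     individual_prob=len(ts) / len(present)))
    _assign_stars(results, cfg)
    return results


def greedy_cumulative(results: Sequence[TriggerResult], effectors: Iterable[str],
                      cfg: TriggerConfig = TriggerConfig()) -> list[TriggerResult]:
    """Greedy maximum-coverage ordering over the trigger sets.

    At each step the protein adding the most uncovered effectors is taken
    (ties: higher individual probability, then gene symbol); proteins with no
    marginal gain stay unranked.  Returns new result objects with
    ``greedy_rank`` and the non-decreasing ``cumulative_pct`` filled.
    """
    eff = set(effectors)
    if not eff:
        return [replace(r) for r in results]
    remaining = list(results)
    covered: set[str] = set()
    out = {r.protein: replace(r) for r in results}
    rank = 0
    while remaining:
        best = min(remaining,
                   key=lambda r: (-len(r.trigger_set - covered), -r.individual_prob,
                                  r.protein))
        gain = len(best.trigger_set - covered)
        if gain == 0:
            break
        rank += 1
        covered |= best.trigger_set
        out[best.protein].greedy_rank = rank
        out[best.protein].cumulative_pct = 100.0 * len(covered & eff) / len(eff)
        remaining.remove(best)
    return [out[r.protein] for r in results]


def leave_one_in_coverage(results: Sequence[TriggerResult],
                          effectors: Iterable[str]) -> dict[str, float]:
    """Per-protein coverage in % of the effector set, independent of order —
    the companion view to the greedy cumulative curve."""
    eff = set(effectors)
    if not eff:
        return {r.protein: 0.0 for r in results}
    return {r.protein: 100.0 * len(r.trigger_set & eff) / len(eff) for r in results}


def write_triggering(results: Sequence[TriggerResult], path) -> None:
    """Trigger TSV: protein, n_triggered, individual_prob, stars, greedy_rank,
    cumulative_pct."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein\tn_triggered\tindividual_prob\tstars\tgreedy_rank\tcumulative_pct\n")
        for r in results:
            rank = "" if r.greedy_rank is None else str(r.greedy_rank)
            cum = "" if r.cumulative_pct is None else f"{r.cumulative_pct:.2f}"
            fh.write(f"{r.protein}\t{len(r.trigger_set)}\t{r.individual_prob:.4f}\t"
                     f"{r.stars}\t{rank}\t{cum}\n")
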