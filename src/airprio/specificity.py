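"""Specificity ranking and cross-disease overlap of prioritized candidates.

A candidate is *specific* to a disease when (a) it reaches at least a "high"
relationship with that disease — through the whole-disease score or through
one of the disease's differential-weight motifs — and (b) its best score over
the disease's specific motifs strictly exceeds its best score over every
other disease's specific motifs.  The strict inequality makes the flags
mutually exclusive: a candidate tied between two diseases is specific to
neither.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from .characterization import DiseaseCharacterization
from .scoring import Category, RelationshipScore, ScoringConfig, classify_relationship


def high_set(ranking: Sequence[RelationshipScore]) -> set[str]:
    """Candidates with a high-or-stronger category in a ranking."""
    return {r.candidate for r in ranking if r.category >= Category.HIGH}


@dataclass
class OverlapReport:
    """Venn-style overlap of per-disease high-or-stronger sets."""

    high_sets: dict[str, set[str]]
    pairwise: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    full_intersection: set[str] = field(default_factory=set)

    def to_json(self) -> str:
        doc = {
            "high_sets": {d: sorted(s) for d, s in self.high_sets.items()},
            "pairwise": {f"{a}&{b}": sorted(s) for (a, b), s in self.pairwise.items()},
            "full_intersection": sorted(self.full_intersection),
        }
        return json.dumps(doc, indent=2)


def overlap_analysis(high_sets: Mapping[str, set[str]]) -> OverlapReport:
    """All pairwise intersections plus the full intersection."""
    if len(high_sets) < 2:
        raise ValueError("overlap analysis needs at least 2 diseases")
    keys = list(high_sets)
    pairwise = {(a, b): set(high_sets[a]) & set(high_sets[b])
                for a, b in combinations(keys, 2)}
    full = set(high_sets[keys[0]])
    for k in keys[1:]:
        full &= set(high_sets[k])
    return OverlapReport(high_sets={k: set(v) for k, v in high_sets.items()},
                         pairwise=pairwise, full_intersection=full)


@dataclass
class SpecificityRecord:
    candidate: str
    disease: str
    overall_score: float
    motif_scores: dict[str, float]
    relationship_level: Category
    motif_relationship_level: Category
    combined_level: Category          # level of max(overall, motif scores)
    specific: bool

    @property
    def best_score(self) -> float:
        return max([self.overall_score, *self.motif_scores.values()])


def specificity_rank(
    overall_scores: Mapping[str, Mapping[str, float]],
    motif_scores: Mapping[str, Mapping[str, float]],
    characterizations: Sequence[DiseaseCharacterization],
    cfg: ScoringConfig = ScoringConfig(),
    gate: Category = Category.HIGH,
    strict: bool = True,
) -> list[SpecificityRecord]:
    """Combine whole-disease and specific-motif scores into specificity flags.

    Parameters
    ----------
    overall_scores
        ``disease -> candidate -> score``; candidates missing from a disease
        map are treated as scoring below every threshold (0).
    motif_scores
        ``candidate -> motif_id -> score`` over the specific motifs of all
        diseases; a candidate missing a required motif raises.
    gate, strict
        The >=high admission gate and the strict-inequality cross-disease
        rule; both exposed for sensitivity analysis.

    Returns records for every (candidate, disease), sorted by disease then
    descending best score.
    """
    diseases = {c.disease_id: c for c in characterizations}
    for c in characterizations:
        if not c.specific_motifs:
            raise ValueError(f"disease {c.disease_id} has no specific motifs")
    candidates = sorted(motif_scores)

    def motif_max(cand: str, disease_id: str) -> float:
        scores = []
        for mid in diseases[disease_id].specific_motifs:
            if mid not in motif_scores[cand]:
                raise ValueError(f"candidate {cand!r} missing a score for motif {mid!r}")
            scores.append(motif_scores[cand][mid])
        return max(scores)

    records: list[SpecificityRecord] = []
    for cand in candidates:
        for did, char in diseases.items():
            overall = float(overall_scores.get(did, {}).get(cand, 0.0))
            own_best = motif_max(cand, did)   # raises on a missing motif
            own_motifs = {mid: float(motif_scores[cand][mid])
                          for mid in char.specific_motifs}
            level = classify_relationship(overall, cfg)
            motif_level = classify_relationship(own_best, cfg)
            combined = classify_relationship(max(overall, own_best), cfg)
            gate_ok = (level >= gate) or (motif_level >= gate)
            if strict:
                beats = all(own_best > motif_max(cand, other)
                            for other in diseases if other != did)
            else:
                beats = all(own_best >= motif_max(cand, other)
                            for other in diseases if other != did)
            records.append(SpecificityRecord(
                candidate=cand, disease=did, overall_score=overall,
                motif_scores=own_motifs, relationship_level=level,
                motif_relationship_level=motif_level, combined_level=combined,
                specific=bool(gate_ok and beats),
            ))
    records.sort(key=lambda r: (r.disease, -r.best_score, r.candidate))
    return records


def specific_proteins(records: Sequence[SpecificityRecord]) -> dict[str, set[str]]:
    """Per-disease sets of candidates flagged specific."""
    out: dict[str, set[str]] = {}
    for r in records:
        out.setdefault(r.disease, set())
        if r.specific:
            out[r.disease].add(r.candidate)
    return out


def high_nonspecific(records: Sequence[SpecificityRecord]) -> dict[str, set[str]]:
    """Candidates with a high-or-stronger combined level for a disease but no
    specificity flag anywhere (e.g. markers shared between both asthma
    types)."""
    flagged = {r.candidate for r in records if r.specific}
    out: dict[str, set[str]] = {}
    for r in records:
        out.setdefault(r.disease, set())
        if r.candidate not in flagged and r.combined_level >= Category.HIGH:
            out[r.disease].add(r.candidate)
    return out


def write_specificity(records: Sequence[SpecificityRecord], path) -> None:
    """Specificity TSV: candidate, disease, overall, per-motif columns,
    levels, specific flag."""
    motif_ids: list[str] = []
    for r in records:
        for mid in r.motif_scores:
            if mid not in motif_ids:
                motif_ids.append(mid)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        cols = ["candidate", "disease", "overall_score", *motif_ids,
                "relationship_level", "motif_relationship_level", "specific"]
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [r.candidate, r.disease, f"{r.overall_score:.2f}"]
            row += [f"{r.motif_scores[m]:.2f}" if m in r.motif_scores else ""
                    for m in motif_ids]
            row += [r.relationship_level.value, r.motif_relationship_level.value,
                    str(int(r.specific))]
            fh.write("\t".join(row) + "\n")
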