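"""Pipeline drivers tying the analysis stages together.

Two entry points mirror the study workflow: :func:`run_prioritize` executes
candidate validation → scoring (or packaged score tables) → classification →
overlap → specificity → triggering and writes all tables plus a run manifest;
:func:`run_validate` runs the expression layer (differential expression +
ROC) over the configured clinical comparisons.
"""
from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import fixtures
from .characterization import (CandidatePanel, DiseaseCharacterization,
                               load_characterization, load_panel)
from .network import InteractionNetwork, load_network, validate_candidates
from .scoring import RelationshipScore, ScoringConfig, classify_relationship, \
    rank_panel, write_scores
from .specificity import (high_nonspecific, high_set, overlap_analysis,
                          specific_proteins, specificity_rank, write_specificity)
from .triggering import TriggerConfig, greedy_cumulative, individual_scores, \
    leave_one_in_coverage, write_triggering
from .validation import ExpressionDataset, diff_expression, enumerate_comparisons, \
    load_expression, roc_analysis, write_diffexpr, write_roc


@dataclass
class PipelineConfig:
    """Paths + stage configuration for a pipeline run.  Any path left None
    falls back to the packaged fixture."""

    network_path: str | None = None
    network_dialect: str = "tsv"
    characterization_path: str | None = None
    effectors_path: str | None = None
    panel_path: str | None = None
    expression_path: str | None = None
    expression_metadata_path: str | None = None
    use_fixture_scores: bool = True     # packaged score tables instead of scoring
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    triggering: TriggerConfig = field(default_factory=TriggerConfig)
    hub_quantile: float = 1.0
    outdir: str = "airprio_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        scoring = ScoringConfig(**doc.pop("scoring", {}))
        trig = doc.pop("triggering", {})
        if "star_breaks" in trig and trig["star_breaks"] is not None:
            trig["star_breaks"] = tuple(trig["star_breaks"])
        triggering = TriggerConfig(**trig)
        return cls(scoring=scoring, triggering=triggering, **doc)

    def digest(self) -> str:
        doc = {k: (str(v) if isinstance(v, (ScoringConfig, TriggerConfig)) else v)
               for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(doc, sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _manifest(cfg: PipelineConfig, outputs: Sequence[str], outdir: Path) -> None:
    import airprio
    manifest = {
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "version": airprio.__version__,
        "python": platform.python_version(),
        "outputs": sorted(outputs),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_prioritize(cfg: PipelineConfig) -> dict:
    """Execute the prioritization pipeline; returns a result bundle and
    writes TSV/JSON artifacts under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    try:
        if cfg.characterization_path:
            chars = load_characterization(cfg.characterization_path, cfg.effectors_path)
        else:
            chars = fixtures.load_disease_characterizations()
        panel = load_panel(cfg.panel_path) if cfg.panel_path \
            else fixtures.load_candidate_panel()
    except Exception as exc:
        raise StageError("load", exc) from exc

    net: InteractionNetwork | None = None
    report = None
    if cfg.network_path:
        try:
            net = load_network(cfg.network_path, dialect=cfg.network_dialect)
            report = validate_candidates(net, panel, hub_quantile=cfg.hub_quantile)
        except Exception as exc:
            raise StageError("validate", exc) from exc

    try:
        if cfg.use_fixture_scores or net is None:
            overall = fixtures.load_disease_scores()
            motif_scores = fixtures.load_motif_scores()
            rankings = {
                d: sorted((RelationshipScore(g, d, s, classify_relationship(s, cfg.scoring))
                           for g, s in scores.items()),
                          key=lambda r: (-r.score, r.candidate))
                for d, scores in overall.items()
            }
        else:
            retained = report.retained if report else panel.symbols
            rankings = {}
            overall = {}
            for char in chars:
                recs = rank_panel(net, retained, char.all_effectors, cfg.scoring,
                                  target_id=char.disease_id)
                rankings[char.disease_id] = recs
                overall[char.disease_id] = {r.candidate: r.score for r in recs}
            motif_scores = {}
            specific = {m for c in chars for m in c.specific_motifs}
            for cand in retained:
                motif_scores[cand] = {}
                for char in chars:
                    for mid in char.specific_motifs:
                        eff = char.motif_effectors(mid)
                        if not eff & net.nodes:
                            motif_scores[cand][mid] = 0.0
                            continue
                        from .scoring import relationship_score
                        motif_scores[cand][mid] = relationship_score(
                            net, cand, eff, cfg.scoring, target_id=mid).score
        for d, recs in rankings.items():
            path = outdir / f"ranking_{d}.tsv"
            write_scores(recs, path)
            outputs.append(path.name)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("score", exc) from exc

    try:
        highs = {d: high_set(r) for d, r in rankings.items()}
        overlap = None
        if len(highs) >= 2:
            overlap = overlap_analysis(highs)
            (outdir / "overlap.json").write_text(overlap.to_json())
            outputs.append("overlap.json")
    except Exception as exc:
        raise StageError("overlap", exc) from exc

    try:
        records, spec_sets, nonspec = [], {}, {}
        spec_chars = [c for c in chars if c.specific_motifs]
        if spec_chars:
            records = specificity_rank(overall, motif_scores, spec_chars, cfg.scoring)
            write_specificity(records, outdir / "specificity.tsv")
            outputs.append("specificity.tsv")
            spec_sets = specific_proteins(records)
            nonspec = high_nonspecific(records)
    except Exception as exc:
        raise StageError("specificity", exc) from exc

    trigger_results = {}
    if net is not None:
        try:
            for char in chars:
                eff = char.all_effectors & net.nodes
                if not eff:
                    continue
                retained = report.retained if report else panel.symbols
                res = individual_scores(net, retained, eff, cfg.triggering)
                res = greedy_cumulative(res, eff, cfg.triggering)
                write_triggering(res, outdir / f"triggering_{char.disease_id}.tsv")
                outputs.append(f"triggering_{char.disease_id}.tsv")
                trigger_results[char.disease_id] = res
        except Exception as exc:
            raise StageError("triggering", exc) from exc

    _manifest(cfg, outputs, outdir)
    return {
        "characterizations": chars,
        "validation_report": report,
        "rankings": rankings,
        "high_sets": highs,
        "overlap": overlap,
        "specificity": records,
        "specific_proteins": spec_sets,
        "high_nonspecific": nonspec,
        "triggering": trigger_results,
        "outdir": str(outdir),
    }


def run_validate(cfg: PipelineConfig,
                 comparisons: Sequence[tuple[str, str]] | None = None) -> dict:
    """Differential expression + ROC over the configured comparisons;
    comparisons whose groups are unavailable are skipped with a note."""
    if not cfg.expression_path or not cfg.expression_metadata_path:
        raise StageError("load", FileNotFoundError("expression dataset not configured"))
    try:
        ds = load_expression(cfg.expression_path, cfg.expression_metadata_path)
    except Exception as exc:
        raise StageError("load", exc) from exc
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comps = list(comparisons) if comparisons is not None else enumerate_comparisons()
    diffexpr, rocs, skipped = [], [], []
    for comp in comps:
        sizes = [len(ds.group_members(g)) for g in comp]
        if min(sizes) < 3:
            skipped.append({"comparison": comp, "group_sizes": sizes})
            continue
        diffexpr.extend(diff_expression(ds, comp))
        for gene in ds.genes:
            rocs.append(roc_analysis(ds, gene, comp))
    outputs = []
    if diffexpr:
        write_diffexpr(diffexpr, outdir / "diffexpr.tsv")
        outputs.append("diffexpr.tsv")
    if rocs:
        write_roc(rocs, outdir / "roc.tsv")
        outputs.append("roc.tsv")
    _manifest(cfg, outputs, outdir)
    return {"diffexpr": diffexpr, "roc": rocs, "skipped": skipped,
            "outdir": str(outdir)}
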