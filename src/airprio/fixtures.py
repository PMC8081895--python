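"""Accessors for the packaged data fixtures.

The fixtures transcribe the published summary tables of the study the package
operationalizes — the motif characterization matrix, the whole-disease
relationship scores of the top two categories, per-motif effector sets, RQ
fold changes, ROC summaries and the triggering table — plus clearly marked
synthetic stand-ins where the underlying data were not published (the full
94-candidate list, the per-motif score panel outside the printed columns).
Each file carries a provenance header; rows are tagged published/synthetic
where the distinction matters.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .characterization import (CandidatePanel, DiseaseCharacterization,
                               load_characterization, load_panel)

def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture file."""
    return Path(resources.files("airprio") / "fixtures_data" / name)


def load_disease_characterizations() -> list[DiseaseCharacterization]:
    """The packaged motif/implication matrix with per-motif effector sets."""
    return load_characterization(fixture_path("motif_implications.tsv"),
                                 fixture_path("motif_effectors.tsv"))


def load_candidate_panel() -> CandidatePanel:
    """The 94-candidate biomarker panel (80 published symbols + synthetic
    placeholders for the unpublished remainder)."""
    return load_panel(fixture_path("candidate_panel.tsv"))


def load_disease_scores() -> dict[str, dict[str, float]]:
    """Published whole-disease relationship scores: disease -> gene -> score."""
    df = pd.read_csv(fixture_path("disease_scores.tsv"), sep="\t", comment="#",
                     keep_default_na=False)
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples():
        out.setdefault(row.disease, {})[row.gene] = float(row.score)
    return out


def load_motif_scores() -> dict[str, dict[str, float]]:
    """Specific-motif score panel: gene -> motif_id -> score (printed values
    exact, the rest synthetic in-band; see the file header)."""
    df = pd.read_csv(fixture_path("motif_scores_synthetic.tsv"), sep="\t",
                     comment="#", keep_default_na=False)
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples():
        out.setdefault(row.gene, {})[row.motif_id] = float(row.score)
    return out


def load_expression_rq() -> pd.DataFrame:
    """Published RQ fold changes with adjusted p-values ('nd' = missing)."""
    df = pd.read_csv(fixture_path("expression_rq.tsv"), sep="\t", comment="#",
                     na_values=["nd"], keep_default_na=False)
    return df


def load_published_roc() -> pd.DataFrame:
    return pd.read_csv(fixture_path("roc_published.tsv"), sep="\t", comment="#",
                       keep_default_na=False)


def load_published_triggering() -> pd.DataFrame:
    return pd.read_csv(fixture_path("triggering_published.tsv"), sep="\t",
                       comment="#", keep_default_na=False)


def load_experimental_panel() -> set[str]:
    """Biomarkers proposed by the prior experimental expression studies."""
    genes = set()
    for line in fixture_path("experimental_panel.txt").read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line)
    return genes


def prioritized_set() -> set[str]:
    """Candidates with a high-or-stronger association with at least one
    condition — overall disease score or any per-motif score."""
    out = set()
    for scores in load_disease_scores().values():
        out |= {g for g, s in scores.items() if s >= 78}
    for gene, motifs in load_motif_scores().items():
        if any(s >= 78 for s in motifs.values()):
            out.add(gene)
    # per-motif high-or-stronger proteins equal the per-motif effector sets
    # (every published high motif protein was reported as a motif effector)
    for char in load_disease_characterizations():
        for motif in char.motifs.values():
            out |= motif.effectors
        break  # motif catalogue is shared across diseases
    return out
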