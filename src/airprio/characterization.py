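"""Disease → molecular motif → effector-protein characterization.

A disease (respiratory allergy, allergic or non-allergic asthma) is described
as a set of pathophysiological *molecular motifs* — sub-processes such as
neutrophil infiltration or bronchoconstriction — each carrying the set of
*effector proteins* through which it acts.  Every motif is marked, per
disease, as strongly implicated, weakly implicated (relevant but weaker than
in the sister condition) or not implicated.  This hierarchy is the target
against which candidate biomarkers are scored: whole-disease scores use the
union of effectors over all implicated motifs, motif scores use a single
motif's effectors.
"""
from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class MotifImplication(enum.Enum):
    """Implication level of a motif in a disease."""

    STRONG = "strong"
    WEAK = "weak"
    NONE = "none"

    @property
    def implicated(self) -> bool:
        return self is not MotifImplication.NONE


class MotifClass(enum.Enum):
    CAUSAL = "causal"
    MANIFESTATIVE = "manifestative"
    UNKNOWN = "unknown"


#: Disease-specific (differential-weight) motifs used by the specificity layer.
SPECIFIC_MOTIFS: dict[str, tuple[str, ...]] = {
    "RA": ("acute_response", "late_phase_response"),
    "AA": ("th2_pulmonary_inflammation", "goblet_cell_hyperplasia",
           "granulocyte_eosinophil_infiltration"),
    "NA": ("th17_pulmonary_inflammation", "neutrophil_infiltration"),
}


@dataclass
class MolecularMotif:
    motif_id: str
    name: str
    motif_class: MotifClass = MotifClass.UNKNOWN
    effectors: frozenset[str] = frozenset()
    effector_refs: dict[str, str] = field(default_factory=dict)


@dataclass
class DiseaseCharacterization:
    """One disease column of the characterization: motifs with implication
    levels plus the motif catalogue shared across diseases."""

    disease_id: str
    motifs: dict[str, MolecularMotif]
    motif_implications: dict[str, MotifImplication]
    specific_motifs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for mid in self.specific_motifs:
            if not self.motif_implications.get(mid, MotifImplication.NONE).implicated:
                raise ValueError(
                    f"specific motif {mid!r} is not implicated in {self.disease_id}"
                )

    @property
    def implicated_motifs(self) -> list[str]:
        return [mid for mid, imp in self.motif_implications.items() if imp.implicated]

    @property
    def all_effectors(self) -> frozenset[str]:
        """Union of effector sets over implicated motifs (weak counts at full
        weight; see the package methods note)."""
        out: set[str] = set()
        for mid in self.implicated_motifs:
            out |= self.motifs[mid].effectors
        return frozenset(out)

    def motif_effectors(self, motif_id: str) -> frozenset[str]:
        return self.motifs[motif_id].effectors


@dataclass
class CandidatePanel:
    """Ordered candidate-protein panel: (uniprot_id, gene_symbol) pairs."""

    proteins: list[tuple[str | None, str]]

    def __post_init__(self) -> None:
        symbols = [g for _, g in self.proteins]
        if len(symbols) != len(set(symbols)):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"duplicate panel entries: {dupes}")

    @property
    def size(self) -> int:
        return len(self.proteins)

    @property
    def symbols(self) -> list[str]:
        return [g for _, g in self.proteins]

    def __iter__(self):
        return iter(self.proteins)


class CharacterizationError(ValueError):
    """Raised for malformed characterization files."""


_SYMBOLS = {v.value: v for v in MotifImplication}


def _read_tsv(path: Path) -> tuple[list[str], list[list[str]]]:
    header: list[str] | None = None
    rows = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cells = raw.rstrip("\n").split("\t")
        if header is None:
            header = cells
        else:
            if len(cells) != len(header):
                raise CharacterizationError(
                    f"{path.name}:{lineno}: expected {len(header)} columns, got {len(cells)}"
                )
            rows.append(cells)
    if header is None:
        return [], []
    return header, rows


def load_characterization(
    implications_path: str | Path,
    effectors_path: str | Path | None = None,
) -> list[DiseaseCharacterization]:
    """Load disease characterizations from the motif-implication TSV
    (``motif_id, motif_name, <disease>...``) and an optional effector TSV
    (``motif_id, protein, reference``).

    Returns one :class:`DiseaseCharacterization` per disease column, in file
    order.  An empty file yields an empty list.
    """
    implications_path = Path(implications_path)
    header, rows = _read_tsv(implications_path)
    if not header:
        return []
    if header[:2] != ["motif_id", "motif_name"]:
        raise CharacterizationError(
            f"{implications_path.name}: first columns must be motif_id, motif_name"
        )
    diseases = header[2:]

    effectors: dict[str, set[str]] = {}
    refs: dict[str, dict[str, str]] = {}
    if effectors_path is not None:
        eff_header, eff_rows = _read_tsv(Path(effectors_path))
        if eff_header and eff_header[:2] != ["motif_id", "protein"]:
            raise CharacterizationError(
                f"{Path(effectors_path).name}: first columns must be motif_id, protein"
            )
        for cells in eff_rows:
            mid, prot = cells[0], cells[1]
            effectors.setdefault(mid, set()).add(prot)
            refs.setdefault(mid, {})[prot] = cells[2] if len(cells) > 2 else ""

    motifs: dict[str, MolecularMotif] = {}
    implications: dict[str, dict[str, MotifImplication]] = {d: {} for d in diseases}
    for cells in rows:
        mid, name = cells[0], cells[1]
        if mid in motifs:
            raise CharacterizationError(f"duplicate motif_id {mid!r}")
        motifs[mid] = MolecularMotif(
            motif_id=mid, name=name,
            effectors=frozenset(effectors.get(mid, ())),
            effector_refs=refs.get(mid, {}),
        )
        for disease, token in zip(diseases, cells[2:]):
            if token not in _SYMBOLS:
                raise CharacterizationError(
                    f"unknown implication symbol {token!r} for motif {mid!r}, "
                    f"disease {disease!r}"
                )
            implications[disease][mid] = _SYMBOLS[token]

    out = []
    for disease in diseases:
        out.append(DiseaseCharacterization(
            disease_id=disease,
            motifs=motifs,
            motif_implications=implications[disease],
            specific_motifs=SPECIFIC_MOTIFS.get(disease, ()),
        ))
    return out


def write_characterization(
    characterizations: Sequence[DiseaseCharacterization],
    implications_path: str | Path,
    effectors_path: str | Path | None = None,
) -> None:
    """Inverse of :func:`load_characterization` (lossless round-trip)."""
    implications_path = Path(implications_path)
    diseases = [c.disease_id for c in characterizations]
    motifs = characterizations[0].motifs if characterizations else {}
    with open(implications_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["motif_id", "motif_name"] + diseases) + "\n")
        for mid, motif in motifs.items():
            row = [mid, motif.name]
            for c in characterizations:
                row.append(c.motif_implications[mid].value)
            fh.write("\t".join(row) + "\n")
    if effectors_path is not None:
        with open(effectors_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("motif_id\tprotein\treference\n")
            for mid, motif in motifs.items():
                for prot in sorted(motif.effectors):
                    fh.write(f"{mid}\t{prot}\t{motif.effector_refs.get(prot, '')}\n")


def load_panel(path: str | Path) -> CandidatePanel:
    """Load a candidate panel TSV with columns ``uniprot_id, gene_symbol``."""
    header, rows = _read_tsv(Path(path))
    if not header:
        return CandidatePanel(proteins=[])
    try:
        iu = header.index("uniprot_id")
        ig = header.index("gene_symbol")
    except ValueError as exc:
        raise CharacterizationError(f"{Path(path).name}: missing column: {exc}") from exc
    proteins = []
    for cells in rows:
        up = cells[iu]
        proteins.append((None if up in ("", "NA") else up, cells[ig]))
    return CandidatePanel(proteins=proteins)


def motif_count(d: DiseaseCharacterization) -> int:
    """Number of motifs implicated (strong or weak) in the disease."""
    return len(d.implicated_motifs)


def shared_motifs(d1: DiseaseCharacterization, d2: DiseaseCharacterization) -> set[str]:
    """Motifs implicated in both diseases."""
    return set(d1.implicated_motifs) & set(d2.implicated_motifs)


def to_json(characterizations: Sequence[DiseaseCharacterization]) -> str:
    """JSON mirror of the characterization (same schema as the TSVs)."""
    motifs = characterizations[0].motifs if characterizations else {}
    doc = {
        "motifs": [
            {
                "motif_id": m.motif_id,
                "motif_name": m.name,
                "effectors": sorted(m.effectors),
                "implications": {
                    c.disease_id: c.motif_implications[m.motif_id].value
                    for c in characterizations
                },
            }
            for m in motifs.values()
        ],
    }
    return json.dumps(doc, indent=2)
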