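"""Expression-based validation of prioritized biomarkers.

Two layers mirror a qPCR validation study: group differential expression
reported as a geometric fold change (RQ = 2**(mean log2 A - mean log2 B))
with an unpaired t-test and Benjamini-Hochberg adjustment across the gene
panel, and ROC discrimination per gene with the rank-statistic AUC, a DeLong
95% CI and a Youden-optimal threshold.  A biomarker counts as significant
when its whole 95% CI lies within [0.70, 1].
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

#: CI rule for calling a biomarker discriminative.
CI_SIGNIFICANCE_BAND = (0.70, 1.0)


@dataclass
class ExpressionDataset:
    """Genes x subjects matrix of log2 expression with group labels.

    ``values`` rows follow ``genes``; columns follow ``subjects``.  ``groups``
    maps subject -> clinical group (control/RA/AA/NA); ``severity`` optionally
    maps asthmatic subjects -> severe / moderate_mild.
    """

    genes: list[str]
    subjects: list[str]
    values: np.ndarray
    groups: dict[str, str]
    severity: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.subjects)):
            raise ValueError("values shape does not match genes x subjects")
        missing = [s for s in self.subjects if s not in self.groups]
        if missing:
            raise ValueError(f"subjects without group label: {missing}")

    def group_members(self, label: str) -> list[str]:
        """Subjects in a group; 'AA_severe'-style labels select a severity
        stratum."""
        if "_" in label and label.split("_", 1)[0] in set(self.groups.values()):
            grp, sev = label.split("_", 1)
            return [s for s in self.subjects
                    if self.groups[s] == grp and self.severity.get(s) == sev]
        return [s for s in self.subjects if self.groups[s] == label]

    def gene_values(self, gene: str, label: str) -> np.ndarray:
        idx = self.genes.index(gene)
        cols = [self.subjects.index(s) for s in self.group_members(label)]
        return self.values[idx, cols]


def load_expression(values_path: str | Path, metadata_path: str | Path) -> ExpressionDataset:
    """Load a genes x subjects TSV plus a subject-metadata TSV
    (subject_id, group, severity)."""
    mat = pd.read_csv(values_path, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(metadata_path, sep="\t", comment="#")
    groups = dict(zip(meta["subject_id"], meta["group"]))
    severity = {}
    if "severity" in meta.columns:
        severity = {s: v for s, v in zip(meta["subject_id"], meta["severity"])
                    if isinstance(v, str) and v}
    return ExpressionDataset(genes=list(mat.index), subjects=list(mat.columns),
                             values=mat.to_numpy(), groups=groups, severity=severity)


@dataclass
class DiffExprResult:
    gene: str
    comparison: tuple[str, str]
    rq: float
    p: float
    adj_p: float


def diff_expression(ds: ExpressionDataset, comparison: tuple[str, str],
                    adjust: str = "fdr_bh") -> list[DiffExprResult]:
    """Per-gene fold change and two-tailed unpaired t-test between two groups.

    RQ is the geometric fold change of group A over group B on the log2
    scale.  Genes with a degenerate design (a group with n < 2, or zero
    variance in both groups) are skipped with a warning.  Adjusted p-values
    are Benjamini-Hochberg across the genes of the comparison.
    """
    a_label, b_label = comparison
    for label in comparison:
        if len(ds.group_members(label)) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 subjects")
    kept, rqs, ps = [], [], []
    for gene in ds.genes:
        a = ds.gene_values(gene, a_label)
        b = ds.gene_values(gene, b_label)
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if np.isclose(a.mean(), b.mean()):
                # identical constant groups: no evidence of change
                kept.append(gene)
                rqs.append(1.0)
                ps.append(1.0)
            else:
                warnings.warn(f"gene {gene}: zero variance in both groups, skipped")
            continue
        rq = float(2.0 ** (a.mean() - b.mean()))
        t, p = stats.ttest_ind(a, b, equal_var=True)
        kept.append(gene)
        rqs.append(rq)
        ps.append(float(p))
    if not kept:
        return []
    adj = multipletests(ps, method=adjust)[1]
    return [DiffExprResult(gene=g, comparison=comparison, rq=rq, p=p, adj_p=float(ap))
            for g, rq, p, ap in zip(kept, rqs, ps, adj)]


@dataclass
class RocResult:
    gene: str
    comparison: tuple[str, str]
    n_a: int
    n_b: int
    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    significant: bool
    degenerate: bool = False


def _auc_rank(neg: np.ndarray, pos: np.ndarray) -> float:
    """Mann-Whitney AUC: P(pos > neg) with ties counted half."""
    ranks = stats.rankdata(np.concatenate([neg, pos]))
    r_pos = ranks[len(neg):].sum()
    n, m = len(neg), len(pos)
    return float((r_pos - m * (m + 1) / 2) / (n * m))


def _delong_variance(neg: np.ndarray, pos: np.ndarray, auc: float) -> float:
    """DeLong structural-component variance of the AUC."""
    m, n = len(pos), len(neg)
    # V10[i]: placement of pos[i] among negatives; V01[j]: of neg[j] among positives
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > x) + 0.5 * np.sum(pos == x)) / m for x in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_analysis(ds: ExpressionDataset, gene: str, comparison: tuple[str, str],
                 alpha: float = 0.05) -> RocResult:
    """ROC discrimination of one gene between two groups.

    The second group of ``comparison`` is the labeled-positive class, matching
    the stated comparison direction; the AUC is not flipped.  CI by DeLong on
    the logit-free scale, clipped to [0, 1]; threshold by Youden's J.
    """
    a_label, b_label = comparison
    neg = ds.gene_values(gene, a_label)
    pos = ds.gene_values(gene, b_label)
    if len(neg) < 3 or len(pos) < 3:
        raise ValueError("both groups need n >= 3 for ROC analysis")
    if np.concatenate([neg, pos]).std() == 0:
        return RocResult(gene=gene, comparison=comparison, n_a=len(neg), n_b=len(pos),
                         auc=0.5, ci_low=0.0, ci_high=1.0, threshold=float(neg[0]),
                         significant=False, degenerate=True)
    auc = _auc_rank(neg, pos)
    var = _delong_variance(neg, pos, auc)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    ci_low, ci_high = max(0.0, auc - half), min(1.0, auc + half)
    y = np.concatenate([np.zeros(len(neg)), np.ones(len(pos))])
    x = np.concatenate([neg, pos])
    fpr, tpr, thresholds = roc_curve(y, x)
    threshold = float(thresholds[np.argmax(tpr - fpr)])
    lo, hi = CI_SIGNIFICANCE_BAND
    significant = bool(ci_low >= lo and ci_high <= hi)
    return RocResult(gene=gene, comparison=comparison, n_a=len(neg), n_b=len(pos),
                     auc=auc, ci_low=float(ci_low), ci_high=float(ci_high),
                     threshold=threshold, significant=significant)


def roc_curve_points(ds: ExpressionDataset, gene: str,
                     comparison: tuple[str, str]) -> pd.DataFrame:
    """FPR/TPR/threshold points for plotting one gene's ROC curve."""
    neg = ds.gene_values(gene, comparison[0])
    pos = ds.gene_values(gene, comparison[1])
    y = np.concatenate([np.zeros(len(neg)), np.ones(len(pos))])
    x = np.concatenate([neg, pos])
    fpr, tpr, thr = roc_curve(y, x)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def common_candidates(experimental_panel: set[str] | Sequence[str],
                      prioritized: set[str] | Sequence[str]) -> list[str]:
    """Sorted intersection of the experimentally supported panel and the
    network-prioritized set — the jointly supported biomarkers."""
    return sorted(set(experimental_panel) & set(prioritized))


def enumerate_comparisons(groups: Sequence[str] = ("control", "RA", "AA", "NA"),
                          severity_groups: Sequence[str] = ("AA", "NA"),
                          strata: Sequence[str] = ("severe", "moderate_mild"),
                          ) -> list[tuple[str, str]]:
    """The clinical comparison design: all pairs of top-level groups, severity
    splits within each asthma group, same-severity cross-asthma contrasts,
    and each asthma severity stratum vs control and vs the allergy-only
    group.  With the default 4 groups and 2 strata this yields 18
    comparisons."""
    comps: list[tuple[str, str]] = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            comps.append((a, b))
    for g in severity_groups:
        comps.append((f"{g}_{strata[0]}", f"{g}_{strata[1]}"))
    if len(severity_groups) >= 2:
        for s in strata:
            comps.append((f"{severity_groups[0]}_{s}", f"{severity_groups[1]}_{s}"))
    others = [g for g in groups if g not in severity_groups]
    for ref in others:
        for g in severity_groups:
            for s in strata:
                comps.append((ref, f"{g}_{s}"))
    return comps


def write_diffexpr(results: Sequence[DiffExprResult], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tgroup_a\tgroup_b\trq\tp\tadj_p\n")
        for r in results:
            fh.write(f"{r.gene}\t{r.comparison[0]}\t{r.comparison[1]}\t"
                     f"{r.rq:.4f}\t{r.p:.4g}\t{r.adj_p:.4g}\n")


def write_roc(results: Sequence[RocResult], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tgroup_a\tgroup_b\tn_a\tn_b\tauc\tci_low\tci_high\t"
                 "threshold\tsignificant\n")
        for r in results:
            fh.write(f"{r.gene}\t{r.comparison[0]}\t{r.comparison[1]}\t{r.n_a}\t{r.n_b}\t"
                     f"{r.auc:.4f}\t{r.ci_low:.4f}\t{r.ci_high:.4f}\t"
                     f"{r.threshold:.4f}\t{int(r.significant)}\n")
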