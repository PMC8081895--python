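"""Differential expression (RQ, t-test, BH) and ROC/AUC with the CI rule."""
import shutil
import subprocess
import textwrap
from itertools import product

import numpy as np
import pytest

from airprio.validation import (ExpressionDataset, _auc_rank, common_candidates,
                                diff_expression, enumerate_comparisons,
                                load_expression, roc_analysis)
from airprio import fixtures as fx


def make_ds(genes, group_values):
    """group_values: {group: {gene: array}} with equal n per group."""
    subjects, groups, cols = [], {}, {}
    for grp, per_gene in group_values.items():
        n = len(next(iter(per_gene.values())))
        for i in range(n):
            sid = f"{grp}{i}"
            subjects.append(sid)
            groups[sid] = grp
            cols[sid] = [per_gene[g][i] for g in genes]
    values = np.array([[cols[s][gi] for s in subjects] for gi in range(len(genes))])
    return ExpressionDataset(genes=list(genes), subjects=subjects, values=values,
                             groups=groups)


class TestDiffExpression:
    def test_identical_groups_give_unit_rq_and_p_one(self):
        ds = make_ds(["g"], {"a": {"g": np.full(5, 3.0)}, "b": {"g": np.full(5, 3.0)}})
        (res,) = diff_expression(ds, ("a", "b"))
        assert res.rq == 1.0 and res.p == 1.0

    def test_one_log2_unit_shift_halves_rq(self):
        rng = np.random.default_rng(0)
        base = rng.normal(8, 0.05, 20)
        ds = make_ds(["g"], {"a": {"g": base - 1.0}, "b": {"g": base + rng.normal(0, 0.05, 20)}})
        (res,) = diff_expression(ds, ("a", "b"))
        assert res.rq == pytest.approx(0.5, rel=0.05)
        assert res.p < 0.001

    def test_rq_inverts_under_comparison_swap(self):
        rng = np.random.default_rng(1)
        ds = make_ds(["g"], {"a": {"g": rng.normal(7, 1, 10)},
                             "b": {"g": rng.normal(9, 1, 10)}})
        (ab,) = diff_expression(ds, ("a", "b"))
        (ba,) = diff_expression(ds, ("b", "a"))
        assert ab.rq == pytest.approx(1 / ba.rq)
        assert ab.p == pytest.approx(ba.p)

    def test_bh_adjustment_preserves_p_ordering_and_dominates_p(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(12)]
        ds = make_ds(genes, {
            "a": {g: rng.normal(8 + 0.2 * i, 1, 15) for i, g in enumerate(genes)},
            "b": {g: rng.normal(8, 1, 15) for g in genes}})
        res = diff_expression(ds, ("a", "b"))
        res_by_p = sorted(res, key=lambda r: r.p)
        adj = [r.adj_p for r in res_by_p]
        assert adj == sorted(adj)
        assert all(r.adj_p >= r.p for r in res)

    def test_small_group_rejected(self):
        ds = make_ds(["g"], {"a": {"g": np.array([1.0])}, "b": {"g": np.ones(4)}})
        with pytest.raises(ValueError, match="fewer than 2"):
            diff_expression(ds, ("a", "b"))

    def test_planted_fold_change_is_recovered(self):
        """Generator planted at the published TNF fold change (0.13) is
        recovered by the estimator within 20% on average."""
        from airprio.synthetic import generate_expression, table6_ra_preset
        ests = []
        for seed in range(20):
            ds = generate_expression(table6_ra_preset(seed=seed))
            res = {r.gene: r for r in diff_expression(ds, ("RA", "control"))}
            ests.append(res["TNF"].rq)
        assert np.mean(ests) == pytest.approx(0.13, rel=0.2)


class TestRocAnalysis:
    def test_perfect_separation_has_auc_one(self):
        ds = make_ds(["g"], {"a": {"g": np.array([1.0, 2, 3])},
                             "b": {"g": np.array([4.0, 5, 6])}})
        res = roc_analysis(ds, "g", ("a", "b"))
        assert res.auc == 1.0
        assert 3.0 < res.threshold <= 4.0

    def test_auc_flips_under_label_swap(self):
        rng = np.random.default_rng(3)
        ds = make_ds(["g"], {"a": {"g": rng.normal(6, 1, 12)},
                             "b": {"g": rng.normal(8, 1, 12)}})
        ab = roc_analysis(ds, "g", ("a", "b"))
        ba = roc_analysis(ds, "g", ("b", "a"))
        assert ab.auc == pytest.approx(1 - ba.auc)

    def test_auc_equals_exhaustive_pairwise_comparison(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n_a = int(rng.integers(3, 9))
            n_b = int(rng.integers(3, 13 - n_a)) if n_a < 10 else 3
            neg = rng.integers(0, 5, n_a).astype(float)  # ties likely
            pos = rng.integers(0, 5, n_b).astype(float)
            wins = sum((p > n) + 0.5 * (p == n) for p, n in product(pos, neg))
            assert _auc_rank(neg, pos) == pytest.approx(wins / (n_a * n_b))

    def test_null_auc_concentrates_near_half(self):
        rng = np.random.default_rng(5)
        inside = 0
        for _ in range(40):
            ds = make_ds(["g"], {"a": {"g": rng.normal(0, 1, 50)},
                                 "b": {"g": rng.normal(0, 1, 50)}})
            auc = roc_analysis(ds, "g", ("a", "b")).auc
            inside += 0.35 <= auc <= 0.65
        assert inside >= 34  # ~95% of replicates

    def test_ci_contains_auc_and_significance_rule(self):
        rng = np.random.default_rng(6)
        ds = make_ds(["g"], {"a": {"g": rng.normal(6, 1, 25)},
                             "b": {"g": rng.normal(9, 1, 25)}})
        res = roc_analysis(ds, "g", ("a", "b"))
        assert res.ci_low <= res.auc <= res.ci_high
        assert res.significant == (res.ci_low >= 0.70 and res.ci_high <= 1.0)

    def test_ci_narrows_with_sample_size(self):
        rng = np.random.default_rng(7)
        widths = []
        for n in (10, 40, 160):
            ds = make_ds(["g"], {"a": {"g": rng.normal(6, 1, n)},
                                 "b": {"g": rng.normal(7.5, 1, n)}})
            r = roc_analysis(ds, "g", ("a", "b"))
            widths.append(r.ci_high - r.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_constant_gene_flagged_degenerate(self):
        ds = make_ds(["g"], {"a": {"g": np.full(5, 2.0)}, "b": {"g": np.full(5, 2.0)}})
        res = roc_analysis(ds, "g", ("a", "b"))
        assert res.auc == 0.5 and res.degenerate and not res.significant

    def test_tiny_group_rejected(self):
        ds = make_ds(["g"], {"a": {"g": np.array([1.0, 2])}, "b": {"g": np.ones(5)}})
        with pytest.raises(ValueError, match="n >= 3"):
            roc_analysis(ds, "g", ("a", "b"))

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_delong_ci_matches_pROC(self, tmp_path):
        """Independent cross-check of the hand-coded DeLong CI against R's pROC."""
        rng = np.random.default_rng(8)
        neg = rng.normal(6, 1, 15).round(3)
        pos = rng.normal(7.2, 1, 12).round(3)
        ds = make_ds(["g"], {"a": {"g": neg}, "b": {"g": pos}})
        ours = roc_analysis(ds, "g", ("a", "b"))
        script = tmp_path / "delong.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(pROC))
            neg <- c({','.join(map(str, neg))})
            pos <- c({','.join(map(str, pos))})
            r <- roc(controls=neg, cases=pos, direction="<", quiet=TRUE)
            ci <- ci.auc(r, method="delong")
            cat(sprintf("%.6f %.6f %.6f", ci[1], ci[2], ci[3]))
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                             timeout=120)
        assert out.returncode == 0, out.stderr
        lo, auc, hi = map(float, out.stdout.split())
        assert ours.auc == pytest.approx(auc, abs=1e-6)
        assert ours.ci_low == pytest.approx(lo, abs=1e-3)
        assert ours.ci_high == pytest.approx(hi, abs=1e-3)


class TestDesign:
    def test_eighteen_clinical_comparisons(self):
        comps = enumerate_comparisons()
        assert len(comps) == 18
        assert len(set(comps)) == 18
        assert ("control", "NA") in comps
        assert ("AA_severe", "AA_moderate_mild") in comps
        assert ("AA_severe", "NA_severe") in comps
        assert ("RA", "NA_moderate_mild") in comps

    def test_severity_strata_selected_from_metadata(self, tmp_path):
        (tmp_path / "expr.tsv").write_text(
            "gene\ts1\ts2\ts3\ts4\ng\t1\t2\t3\t4\n")
        (tmp_path / "meta.tsv").write_text(
            "subject_id\tgroup\tseverity\ns1\tAA\tsevere\ns2\tAA\tmoderate_mild\n"
            "s3\tcontrol\t\ns4\tAA\tsevere\n")
        ds = load_expression(tmp_path / "expr.tsv", tmp_path / "meta.tsv")
        assert ds.group_members("AA_severe") == ["s1", "s4"]
        assert ds.group_members("control") == ["s3"]


class TestCommonCandidates:
    def test_thirteen_jointly_supported_biomarkers(self):
        common = common_candidates(fx.load_experimental_panel(), fx.prioritized_set())
        assert common == ["ALOX5", "CCL5", "CHI3L1", "IFNG", "IL10", "IL1R2", "IL4R",
                          "IL8", "SELL", "SERPINB2", "TGFB1", "TLR4", "TNF"]

    def test_disjoint_and_subset_cases(self):
        assert common_candidates({"a"}, {"b"}) == []
        assert common_candidates({"a", "b"}, {"a", "b", "c"}) == ["a", "b"]
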