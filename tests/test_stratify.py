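"""Percentile stratification, PC screening, risk-orthogonal filters, LD clumping."""

import numpy as np
import pandas as pd
import pytest

from polyres.errors import StrataError
from polyres.stratify import (
    LdPanel,
    exclude_risk_linked,
    ld_clump,
    qc_filter,
    select_covariate_pcs,
    stratify_by_percentile,
)
from tests.conftest import exact_corr_columns, make_panel


def scores_frame(control_scores, case_scores, study="s1"):
    return pd.DataFrame({
        "study_id": study,
        "subject_id": [f"c{i}" for i in range(len(control_scores))]
        + [f"k{i}" for i in range(len(case_scores))],
        "phenotype": [0] * len(control_scores) + [1] * len(case_scores),
        "z": list(control_scores) + list(case_scores),
    })


class TestStratify:
    def test_hand_example(self):
        """Controls 1..10 -> threshold 9.1; cases (8.5, 9.5, 10.5, 12) split
        into matched {9.5} and ultra-high {10.5, 12}."""
        strata = stratify_by_percentile(
            scores_frame(np.arange(1.0, 11.0), [8.5, 9.5, 10.5, 12.0]), pct=90)
        assert strata.threshold == pytest.approx(9.1)
        assert {s for (_st, s) in strata.resilient_controls} == {"c9"}  # score 10
        matched = strata.table.loc[strata.table.group == "matched_case", "z"].tolist()
        assert matched == [9.5]
        ultra = sorted(strata.table.loc[strata.table.group == "ultra_high_case", "z"])
        assert ultra == [10.5, 12.0]
        strata.check_partition()

    def test_all_controls_tied(self):
        strata = stratify_by_percentile(scores_frame([2.0] * 8, [1.5, 2.0, 3.0]), pct=90)
        assert strata.threshold == pytest.approx(2.0)
        assert len(strata.resilient_controls) == 8
        assert len(strata.matched_cases) == 1       # the case at 2.0
        assert len(strata.ultra_high_cases) == 1    # the case at 3.0

    def test_resilient_fraction_large_sample(self, rng):
        z = rng.normal(size=10_000)
        strata = stratify_by_percentile(scores_frame(z, rng.normal(0.5, 1, 2000)), pct=90)
        frac = len(strata.resilient_controls) / 10_000
        assert frac == pytest.approx(0.10, abs=0.01)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_partition_invariants_randomized(self, seed):
        rng = np.random.default_rng(seed)
        n_ctrl, n_case = rng.integers(20, 200, 2)
        df = scores_frame(rng.normal(size=n_ctrl), rng.normal(0.4, 1.2, n_case))
        strata = stratify_by_percentile(df, pct=90)
        strata.check_partition()
        t = strata.table
        res = t[t.group == "resilient_control"]
        assert (res.z >= strata.threshold).all() and (res.phenotype == 0).all()
        mat = t[t.group == "matched_case"]
        assert ((mat.z >= strata.threshold) & (mat.z <= strata.max_control)).all()
        assert (t[t.group == "ultra_high_case"].z > strata.max_control).all()

    def test_input_order_invariance(self, rng):
        df = scores_frame(rng.normal(size=100), rng.normal(0.5, 1, 80))
        s1 = stratify_by_percentile(df, 90)
        s2 = stratify_by_percentile(df.sample(frac=1, random_state=1), 90)
        for g in ("resilient_control", "matched_case", "ultra_high_case"):
            assert s1.ids(g) == s2.ids(g)

    def test_single_class_raises(self):
        with pytest.raises(StrataError):
            stratify_by_percentile(scores_frame([1.0, 2.0], []), 90)


class TestSelectPcs:
    def test_identical_pc_never_selected(self, rng):
        pcs = np.column_stack([np.ones(100), rng.normal(size=100)])
        idx1, idx2 = np.arange(50), np.arange(50, 100)
        assert 0 not in select_covariate_pcs(pcs, idx1, idx2, alpha=0.99)

    @pytest.mark.parametrize("seed", range(10))
    def test_one_sd_shift_detected(self, seed):
        rng = np.random.default_rng(seed)
        pcs = rng.normal(size=(400, 3))
        pcs[:200, 1] += 1.0  # 1-SD mean shift on PC2
        sel = select_covariate_pcs(pcs, np.arange(200), np.arange(200, 400), alpha=0.1)
        assert 1 in sel

    def test_alpha_zero_selects_nothing(self, rng):
        pcs = rng.normal(size=(60, 4))
        pcs[:30] += 5
        assert select_covariate_pcs(pcs, np.arange(30), np.arange(30, 60), alpha=0.0) == []

    def test_too_few_subjects_raises(self, rng):
        with pytest.raises(ValueError):
            select_covariate_pcs(rng.normal(size=(10, 2)), [0], [1, 2], alpha=0.1)

    def test_order_preserved(self, rng):
        pcs = rng.normal(size=(400, 4))
        pcs[:200, 3] += 1.0
        pcs[:200, 0] += 1.0
        sel = select_covariate_pcs(pcs, np.arange(200), np.arange(200, 400), alpha=0.1)
        assert sel == sorted(sel)


def ld_fixture(rng, n=400):
    """Reference panel with exact correlations to a risk SNP.

    Columns: risk (pos 1e6), cand_hi r^2=0.25 at 500 kb, cand_lo r^2=0.15 at
    500 kb, cand_far r^2=0.25 at 1.5 Mb, cand_null r^2=0 nearby.
    """
    cols = exact_corr_columns(rng, n, [0.5, np.sqrt(0.15), 0.5, 0.0])
    pos = [1_000_000, 1_500_000, 1_480_000, 2_500_000, 1_400_000]
    ids = ["risk", "cand_hi", "cand_lo", "cand_far", "cand_null"]
    panel = make_panel(cols, np.zeros(n), pos=pos)
    panel.variants["id"] = ids
    return LdPanel(panel)


def assoc_frame(ids, pos, ps, chrom=1):
    return pd.DataFrame({
        "snp": ids, "chrom": chrom, "pos": pos, "a1": "A", "a2": "G",
        "frq": 0.3, "info": 1.0, "beta": 0.1, "se": 0.05, "p": ps, "n_studies": 1,
    })


class TestExcludeRiskLinked:
    def _risk_meta(self):
        # the "risk" SNP is risk-significant; candidates are not
        return assoc_frame(["risk", "cand_hi", "cand_lo", "cand_far", "cand_null", "cand_p"],
                           [1_000_000, 1_500_000, 1_480_000, 2_500_000, 1_400_000, 3_000_000],
                           [0.001, 0.5, 0.6, 0.7, 0.8, 0.04])

    def test_rules_fire_as_specified(self, rng):
        ld = ld_fixture(rng)
        candidates = assoc_frame(
            ["cand_hi", "cand_lo", "cand_far", "cand_null", "cand_p"],
            [1_500_000, 1_480_000, 2_500_000, 1_400_000, 3_000_000],
            [0.2, 0.2, 0.2, 0.2, 0.2])
        surv, report = exclude_risk_linked(candidates, self._risk_meta(), ld,
                                           p_thresh=0.05, r2_thresh=0.2, window_kb=1000)
        assert report.removed_ids["risk_p"] == ["cand_p"]       # risk p = 0.04 < 0.05
        assert report.removed_ids["ld_with_risk"] == ["cand_hi"]  # r^2 = 0.25 within 1 Mb
        assert set(surv["snp"]) == {"cand_lo", "cand_far", "cand_null"}
        report.audit()

    def test_window_boundary(self, rng):
        """r^2 = 0.25 at 1.5 Mb is outside the 1 Mb window -> retained."""
        ld = ld_fixture(rng)
        candidates = assoc_frame(["cand_far"], [2_500_000], [0.2])
        surv, _rep = exclude_risk_linked(candidates, self._risk_meta(), ld)
        assert list(surv["snp"]) == ["cand_far"]

    def test_strict_mode_requires_ld_coverage(self, rng):
        ld = ld_fixture(rng)
        candidates = assoc_frame(["unknown"], [1_600_000], [0.2])
        risk = self._risk_meta()
        with pytest.raises(KeyError):
            exclude_risk_linked(candidates, risk, ld, strict=True)
        surv, _rep = exclude_risk_linked(candidates, risk, ld, strict=False)
        assert list(surv["snp"]) == ["unknown"]


class TestQcFilter:
    def _variants(self, **overrides):
        base = dict(id="rs1", chrom=1, pos=1000, a1="A", a2="G", maf=0.3,
                    info=1.0, n_studies=20)
        base.update(overrides)
        return pd.DataFrame([base])

    @pytest.mark.parametrize("overrides,rule", [
        (dict(chrom=6, pos=30_000_000), "mhc"),
        (dict(chrom=6, pos=25_000_000), "mhc"),          # inclusive lower bound
        (dict(chrom=6, pos=34_000_000), "mhc"),          # inclusive upper bound
        (dict(chrom=8, pos=10_000_000), "chr8_inversion"),
        (dict(info=0.89), "low_info"),
        (dict(a1="A", a2="T"), "ambiguous_or_indel"),
        (dict(a1="C", a2="G"), "ambiguous_or_indel"),
        (dict(a1="AG", a2="A"), "ambiguous_or_indel"),
        (dict(maf=0.049), "low_maf"),
        (dict(n_studies=10), "few_studies"),
    ])
    def test_removal_rules(self, overrides, rule):
        _surv, report = qc_filter(self._variants(**overrides))
        assert report.removed_ids[rule] == ["rs1"]

    @pytest.mark.parametrize("overrides", [
        dict(chrom=6, pos=24_999_999),
        dict(chrom=6, pos=34_000_001),
        dict(info=0.90),
        dict(a1="A", a2="C"),
        dict(maf=0.05),
        dict(n_studies=11),
    ])
    def test_retention_boundaries(self, overrides):
        surv, report = qc_filter(self._variants(**overrides))
        assert report.survivors == ["rs1"]

    def test_first_rule_attribution_and_audit(self):
        # in the MHC *and* ambiguous: attributed to the region rule (listed first)
        v = self._variants(chrom=6, pos=30_000_000, a1="A", a2="T")
        _surv, report = qc_filter(v)
        assert report.removed_ids["mhc"] == ["rs1"]
        assert "ambiguous_or_indel" not in report.removed
        report.audit()


def clump_fixture(rng):
    """Three variants within 500 kb: r^2(1,2)=0.5, r^2(1,3)=0.1."""
    cols = exact_corr_columns(rng, 400, [np.sqrt(0.5), np.sqrt(0.1)])
    panel = make_panel(cols, np.zeros(400), pos=[1_000_000, 1_100_000, 1_200_000])
    panel.variants["id"] = ["v1", "v2", "v3"]
    return LdPanel(panel)


def clump_oracle(assoc, r2mat, ids, pos, chrom, kb, r2):
    """Independent greedy reference implementation on a precomputed r^2 matrix."""
    order = assoc.sort_values(["p", "chrom", "pos", "snp"], kind="mergesort")
    claimed, out = set(), []
    loc = {s: i for i, s in enumerate(ids)}
    for _, row in order.iterrows():
        if row.snp in claimed:
            continue
        out.append(row.snp)
        claimed.add(row.snp)
        for other in ids:
            if other in claimed:
                continue
            j, i = loc[other], loc[row.snp]
            same_chrom = chrom[j] == chrom[i]
            if same_chrom and abs(pos[j] - pos[i]) <= kb * 1000 and r2mat[i, j] > r2:
                claimed.add(other)
    return set(out)


class TestLdClump:
    def test_single_variant(self, rng):
        ld = clump_fixture(rng)
        assoc = assoc_frame(["v1"], [1_000_000], [0.01])
        assert ld_clump(assoc, ld) == ["v1"]

    def test_hand_greedy_trace(self, rng):
        ld = clump_fixture(rng)
        assoc = assoc_frame(["v1", "v2", "v3"], [1_000_000, 1_100_000, 1_200_000],
                            [1e-6, 1e-4, 1e-3])
        assert set(ld_clump(assoc, ld, kb=500, r2=0.2)) == {"v1", "v3"}

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(4, 13))
        dosage = rng.integers(0, 3, size=(300, m)).astype(float)
        pos = np.sort(rng.integers(1, 2_000_000, m))
        chrom = rng.integers(1, 3, m)
        panel = make_panel(dosage, np.zeros(300), pos=pos, chrom=chrom)
        ids = list(panel.variants["id"])
        ld = LdPanel(panel)
        ps = rng.uniform(1e-8, 1, m)
        assoc = assoc_frame(ids, pos, ps, chrom=chrom)
        with np.errstate(invalid="ignore"):
            r2mat = np.nan_to_num(np.corrcoef(dosage.T) ** 2)
        expected = clump_oracle(assoc, r2mat, ids, pos, chrom, kb=500, r2=0.2)
        assert set(ld_clump(assoc, ld, kb=500, r2=0.2)) == expected

    def test_p1_threshold_limits_indices(self, rng):
        ld = clump_fixture(rng)
        assoc = assoc_frame(["v1", "v2", "v3"], [1_000_000, 1_100_000, 1_200_000],
                            [0.5, 0.9, 0.95])
        assert ld_clump(assoc, ld, p1=0.6) == ["v1"]


class TestFilterReportMerge:
    def test_chained_reports_reconcile(self, rng):
        ld = ld_fixture(rng)
        candidates = assoc_frame(
            ["cand_hi", "cand_lo", "cand_far", "cand_null", "cand_p"],
            [1_500_000, 1_480_000, 2_500_000, 1_400_000, 3_000_000],
            [0.2] * 5)
        risk = TestExcludeRiskLinked()._risk_meta()
        surv, rep1 = exclude_risk_linked(candidates, risk, ld)
        v = pd.DataFrame({
            "id": surv["snp"], "chrom": 1, "pos": surv["pos"], "a1": "A", "a2": "G",
            "maf": [0.3, 0.02, 0.3], "info": 1.0, "n_studies": 20,
        })
        _s2, rep2 = qc_filter(v, min_studies=1)
        merged = rep1.merge(rep2)
        assert merged.n_input == 5
        assert sum(merged.removed.values()) + len(merged.survivors) == 5
        assert merged.removed["low_maf"] == 1
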