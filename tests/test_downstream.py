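"""Correlation/interaction/decile analyses, LD diagnostics, power, gene-level ops."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyres.downstream import (
    decile_analysis,
    gene_enrichment_regression,
    gene_scores,
    group_correlations,
    interaction_model,
    ld_vs_assoc_correlation,
    map_snps_to_genes,
    power_allelic,
)
from polyres.errors import DesignError
from tests.conftest import exact_corr_columns, make_panel
from polyres.stratify import LdPanel


class TestGroupCorrelations:
    def test_identical_scores_r_one(self, rng):
        z = rng.normal(size=500)
        y = rng.integers(0, 2, 500)
        t = group_correlations(z, z, y).set_index("group")
        for g in ("cases", "controls"):
            assert t.loc[g, "r"] == pytest.approx(1.0)

    def test_independent_scores_near_zero(self, rng):
        n = 5000
        t = group_correlations(rng.normal(size=n), rng.normal(size=n),
                               rng.integers(0, 2, n)).set_index("group")
        for g in ("cases", "controls"):
            assert abs(t.loc[g, "r"]) < 0.04
        ok = t[t.status == "ok"]
        # smaller split groups: within 4 sampling SEs of zero
        assert (ok["r"].abs() < 4.0 / np.sqrt(ok["n"])).all()

    def test_groups_partition_after_ultra_exclusion(self, rng):
        n = 1000
        risk = rng.normal(size=n)
        y = rng.integers(0, 2, n)
        excl = risk > 2.5
        t = group_correlations(risk, rng.normal(size=n), y, exclude=excl).set_index("group")
        kept = (~excl).sum()
        assert t.loc["cases", "n"] + t.loc["controls", "n"] == kept
        assert (t.loc["low_risk_cases", "n"] + t.loc["low_risk_controls", "n"]
                + t.loc["high_risk_cases", "n"] + t.loc["high_risk_controls", "n"]) == kept

    def test_small_group_flagged(self, rng):
        y = np.r_[np.ones(2), np.zeros(50)].astype(int)
        t = group_correlations(rng.normal(size=52), rng.normal(size=52), y).set_index("group")
        assert t.loc["cases", "status"] == "too_few"
        assert np.isnan(t.loc["cases", "r"])


class TestInteractionModel:
    def test_known_interaction_recovered(self, rng):
        n = 20_000
        r, s = rng.normal(size=n), rng.normal(size=n)
        eta = -1.0 + 1.0 * r - 0.5 * r * s
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        t = interaction_model(r, s, y)
        b, se = t.loc["interaction", "beta"], t.loc["interaction", "se"]
        assert b < 0
        assert abs(b - (-0.5)) < 1.96 * se * 1.5

    def test_constant_resilience_dropped_with_warning(self, rng):
        n = 500
        r = rng.normal(size=n)
        y = rng.integers(0, 2, n)
        with pytest.warns(UserWarning, match="constant"):
            t = interaction_model(r, np.zeros(n), y)
        assert np.isnan(t.loc["interaction", "beta"])
        assert t.loc["interaction", "status"] == "dropped"
        assert np.isfinite(t.loc["risk", "beta"])


class TestDecileAnalysis:
    def test_null_risk_gives_or_near_one(self, rng):
        n = 5000
        t = decile_analysis(rng.normal(size=n), rng.integers(0, 2, n))
        upper = t[t.decile > 1]
        covered = ((np.log(upper.or_vs_bottom) - 1.96 * upper.or_se <= 0)
                   & (np.log(upper.or_vs_bottom) + 1.96 * upper.or_se >= 0))
        assert covered.mean() >= 0.8

    def test_strong_risk_monotone_ors(self, rng):
        n = 8000
        risk = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1.5 + 1.5 * risk)))).astype(int)
        t = decile_analysis(risk, y)
        rho = stats.spearmanr(t.decile, t.or_vs_bottom).statistic
        assert rho > 0.9
        assert t.or_vs_bottom.iloc[-1] > t.or_vs_bottom.iloc[1]

    def test_resilience_effect_in_upper_deciles(self, rng):
        """With a pure risk x resilience interaction, the within-decile
        resilience effect concentrates in the upper risk deciles."""
        n = 30_000
        risk, res = rng.normal(size=n), rng.normal(size=n)
        eta = -1.2 + 1.2 * risk - 0.6 * risk * res
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        t = decile_analysis(risk, y, resilience_z=res)
        # res_beta is the log-odds of being a *control* per resilience SD
        assert t.res_beta.iloc[-3:].mean() > t.res_beta.iloc[:3].mean()
        assert (t.res_beta.iloc[-2:] > 0).all()

    def test_ties_land_in_lower_decile_and_small_n_raises(self, rng):
        z = np.repeat(np.arange(10.0), 10)  # exactly 10 per decile with ties
        y = (rng.random(100) < 0.4).astype(int)
        y[:3] = [1, 0, 1]
        t = decile_analysis(z, y)
        assert (t["n"] == 10).all()
        with pytest.raises(DesignError):
            decile_analysis(rng.normal(size=50), rng.integers(0, 2, 50))


class TestLdVsAssoc:
    def _fixture(self, rng):
        cols = exact_corr_columns(rng, 400, [0.5, np.sqrt(0.15), 0.0])
        panel = make_panel(cols, np.zeros(400),
                           pos=[1_000_000, 1_200_000, 1_300_000, 1_400_000])
        panel.variants["id"] = ["risk", "c1", "c2", "c3"]
        return LdPanel(panel)

    def _assoc(self, betas):
        return pd.DataFrame({
            "snp": ["c1", "c2", "c3"], "chrom": 1,
            "pos": [1_200_000, 1_300_000, 1_400_000],
            "a1": "A", "a2": "G", "frq": 0.3, "info": 1.0,
            "beta": betas, "se": 1.0,
            "p": 2 * stats.norm.sf(np.abs(betas)), "n_studies": 1,
        })

    def test_stat_equal_to_ld_gives_r_one(self, rng):
        ld = self._fixture(rng)
        risk = pd.DataFrame({"snp": ["risk"], "chrom": [1], "pos": [1_000_000]})
        # |z| constructed equal to each candidate's max r^2 (0.25, 0.15, 0.0)
        r, _p = ld_vs_assoc_correlation(self._assoc(np.array([0.25, 0.15, 0.0])),
                                        risk, ld)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_strong_assoc_far_from_risk_gives_negative_r(self, rng):
        ld = self._fixture(rng)
        risk = pd.DataFrame({"snp": ["risk"], "chrom": [1], "pos": [1_000_000]})
        r, _p = ld_vs_assoc_correlation(self._assoc(np.array([0.1, 0.5, 2.0])),
                                        risk, ld)
        assert r < 0

    def test_no_risk_variants_raises(self, rng):
        ld = self._fixture(rng)
        with pytest.raises(ValueError):
            ld_vs_assoc_correlation(self._assoc(np.array([0.1, 0.2, 0.3])),
                                    pd.DataFrame(columns=["snp", "chrom", "pos"]), ld)


class TestPowerAllelic:
    def test_null_or_gives_alpha(self):
        for alpha in (0.05, 0.01):
            assert power_allelic(500, 500, 0.3, 1.0, alpha) == pytest.approx(alpha, abs=1e-6)

    def test_monotone_in_n_to_one(self):
        powers = [power_allelic(n, n, 0.3, 1.5, 0.05) for n in (50, 200, 1000, 10_000)]
        assert all(a < b for a, b in zip(powers, powers[1:]))
        assert powers[-1] > 0.999

    def test_monte_carlo_oracle(self, rng):
        """n=500/500, freq 0.3, OR 1.5: analytic power within +/-0.02 of simulation."""
        n1 = n2 = 500
        p2 = 0.3
        odds = 1.5 * p2 / (1 - p2)
        p1 = odds / (1 + odds)
        reps = 100_000
        x1 = rng.binomial(2 * n1, p1, reps) / (2 * n1)
        x2 = rng.binomial(2 * n2, p2, reps) / (2 * n2)
        pbar = (x1 * n1 + x2 * n2) / (n1 + n2)
        se = np.sqrt(x1 * (1 - x1) / (2 * n1) + x2 * (1 - x2) / (2 * n2))
        z = np.abs(x1 - x2) / np.where(se > 0, se, np.inf)
        mc_power = float(np.mean(z > stats.norm.isf(0.025)))
        del pbar
        assert power_allelic(n1, n2, 0.3, 1.5, 0.05) == pytest.approx(mc_power, abs=0.02)

    def test_anchor_options_and_domain(self):
        for anchor in ("reference", "cases", "pooled"):
            p = power_allelic(800, 800, 0.94, 1.32, 0.05, anchor=anchor)
            assert 0 < p < 1
        with pytest.raises(ValueError):
            power_allelic(100, 100, 0.3, -1.0)
        with pytest.raises(ValueError):
            power_allelic(100, 100, 0.3, 1.5, anchor="bogus")


GENES = pd.DataFrame({
    "gene_id": ["G1", "G2", "G3"],
    "gene_name": ["G1", "G2", "G3"],
    "chrom": [1, 1, 2],
    "start": [100, 450, 100],
    "end": [500, 900, 200],
    "biotype": "protein_coding",
})


def variants_at(positions, chrom=1):
    return pd.DataFrame({
        "id": [f"s{i}" for i in range(len(positions))],
        "chrom": chrom, "pos": positions, "a1": "A", "a2": "G",
        "maf": 0.3, "info": 1.0, "n_studies": 2,
    })


class TestGeneMapping:
    def test_boundaries_inclusive_no_flank(self):
        v = variants_at([100, 500, 501, 99])
        a = map_snps_to_genes(v, GENES[GENES.gene_id == "G1"])
        assigned = set(a["snp"])
        assert "s0" in assigned     # at gene start
        assert "s1" in assigned     # at gene end
        assert "s2" not in assigned  # 1 bp past end
        assert "s3" not in assigned  # 1 bp before start

    def test_overlapping_genes_multi_assignment(self):
        v = variants_at([480])
        a = map_snps_to_genes(v, GENES)
        assert set(a["gene_id"]) == {"G1", "G2"}

    def test_chromosome_respected(self):
        v = variants_at([150], chrom=2)
        a = map_snps_to_genes(v, GENES)
        assert set(a["gene_id"]) == {"G3"}


def assoc_for_genes(snps, zscores, ps, frq=0.3):
    z = np.asarray(zscores, dtype=float)
    return pd.DataFrame({
        "snp": snps, "chrom": 1, "pos": np.arange(len(snps)) * 10 + 100,
        "a1": "A", "a2": "G", "frq": frq, "info": 1.0,
        "beta": z * 0.1, "se": 0.1, "p": ps, "n_studies": 2,
    })


class TestGeneScores:
    def test_hand_mean_and_risk_p_filter(self):
        v = variants_at([110, 120, 130, 140])
        genes = GENES[GENES.gene_id == "G1"]
        assign = map_snps_to_genes(v, genes)
        risk = assoc_for_genes(["s0", "s1", "s2", "s3"], [1.0, -0.5, 0.5, 9.9],
                               [0.01, 0.02, 0.03, 0.06])
        resil = assoc_for_genes(["s0", "s1", "s2", "s3"], [1.0, -0.5, 0.5, 0.2],
                                [0.5, 0.5, 0.5, 0.5])
        t = gene_scores(assign, risk, resil, genes).set_index("gene_id")
        # s3 (risk p=0.06) excluded from the risk mean; all four in resilience
        assert t.loc["G1", "risk_score"] == pytest.approx(1.0 / 3, abs=1e-9)
        assert t.loc["G1", "resilience_score"] == pytest.approx(0.3, abs=1e-9)
        assert t.loc["G1", "n_snps"] == 4
        assert t.loc["G1", "length_kb"] == pytest.approx(0.401)

    def test_single_snp_gene(self):
        v = variants_at([110])
        genes = GENES[GENES.gene_id == "G1"]
        assign = map_snps_to_genes(v, genes)
        risk = assoc_for_genes(["s0"], [2.0], [0.01])
        t = gene_scores(assign, risk, risk, genes).set_index("gene_id")
        assert t.loc["G1", "risk_score"] == pytest.approx(2.0)

    def test_gene_without_qualifying_snp_is_nan(self):
        v = variants_at([110])
        genes = GENES[GENES.gene_id == "G1"]
        assign = map_snps_to_genes(v, genes)
        risk = assoc_for_genes(["s0"], [1.0], [0.5])  # p >= 0.05: no risk SNP
        t = gene_scores(assign, risk, risk, genes).set_index("gene_id")
        assert np.isnan(t.loc["G1", "risk_score"])


def synthetic_gene_frame(rng, n_genes=400, beta=0.0, n_chroms=22):
    chrom = rng.integers(1, n_chroms + 1, n_genes)
    resil = rng.normal(size=n_genes)
    length = rng.uniform(1, 100, n_genes)
    snps_kb = rng.uniform(0.1, 5, n_genes)
    maf = rng.uniform(0.05, 0.5, n_genes)
    risk = beta * resil + 0.01 * length / 50 + rng.normal(size=n_genes)
    return pd.DataFrame({
        "gene_id": [f"G{i}" for i in range(n_genes)], "chrom": chrom,
        "start": 1, "end": 2, "biotype": "protein_coding",
        "length_kb": length, "risk_score": risk, "resilience_score": resil,
        "n_snps": 5, "snps_per_kb": snps_kb, "mean_maf": maf,
    })


def sandwich_oracle(y, X, groups):
    """Explicit cluster-sum sandwich with the G/(G-1)*(n-1)/(n-k) factor."""
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    u = y - X @ beta
    meat = np.zeros((k, k))
    for g in np.unique(groups):
        Xg = X[groups == g]
        ug = u[groups == g]
        s = Xg.T @ ug
        meat += np.outer(s, s)
    G = len(np.unique(groups))
    c = G / (G - 1) * (n - 1) / (n - k)
    V = c * XtX_inv @ meat @ XtX_inv
    return beta, np.sqrt(np.diag(V))


class TestGeneEnrichment:
    def test_robust_se_matches_explicit_sandwich(self, rng):
        t = synthetic_gene_frame(rng, 300, beta=0.1)
        b, se, _p, res = gene_enrichment_regression(t)
        X = res.model.exog
        y = res.model.endog
        groups = t["chrom"].astype("category").cat.codes.to_numpy()
        _bo, seo = sandwich_oracle(y, X, groups)
        j = res.model.exog_names.index("resilience_score")
        assert se == pytest.approx(seo[j], abs=1e-8)
        assert b == pytest.approx(res.params["resilience_score"], abs=1e-12)

    def test_permuted_resilience_gives_null_beta(self, rng):
        t = synthetic_gene_frame(rng, 500, beta=0.25)
        t["resilience_score"] = rng.permutation(t["resilience_score"].to_numpy())
        b, se, p, _res = gene_enrichment_regression(t)
        assert abs(b) < 3.5 * se

    def test_homoscedastic_robust_close_to_classical(self, rng):
        t = synthetic_gene_frame(rng, 2000, beta=0.1)
        _b, se_robust, _p, res = gene_enrichment_regression(t)
        classical = res.model.fit()
        se_cl = classical.bse["resilience_score"]
        assert abs(se_robust - se_cl) / se_cl < 0.15

    def test_rank_deficiency_names_columns(self, rng):
        t = synthetic_gene_frame(rng, 100)
        t["snps_per_kb"] = t["length_kb"] * 2.0  # exact collinearity
        with pytest.raises(DesignError, match="collinear"):
            gene_enrichment_regression(t)
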