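"""Risk-resilience correlation structure, interaction and decile analyses, LD
diagnostics, allelic power, and gene-level risk/resilience enrichment."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from intervaltree import IntervalTree
from scipy import stats

from .errors import DesignError
from .stratify import LdPanel, max_r2_to_risk


def _fisher_ci(r: float, n: int, level: float = 0.95):
    if n <= 3 or abs(r) >= 1:
        return (np.nan, np.nan)
    zc = stats.norm.isf((1 - level) / 2)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    return (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))


def group_correlations(risk_z, resilience_z, labels, strata=None,
                       exclude: np.ndarray | None = None) -> pd.DataFrame:
    """Pearson risk-resilience correlations in case/control strata.

    Ultra-high-risk cases must be excluded before grouping; pass either a
    :class:`~polyres.stratify.Strata` threshold context via ``exclude`` (a
    boolean mask of subjects to drop) or ``strata`` carrying a per-subject
    group column aligned with the inputs.  Groups: cases, controls, then
    low-risk and high-risk subjects split by status (low/high at the strata
    threshold, or at the control 90th percentile when no strata are given).
    Groups with fewer than 3 subjects are flagged and skipped.
    """
    risk_z = np.asarray(risk_z, dtype=float)
    resilience_z = np.asarray(resilience_z, dtype=float)
    y = np.asarray(labels, dtype=int)
    keep = np.ones(len(y), dtype=bool)
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    if strata is not None:
        threshold = strata.threshold
    else:
        threshold = np.quantile(risk_z[(y == 0) & keep], 0.9)
    risk_z, resilience_z, y = risk_z[keep], resilience_z[keep], y[keep]

    high = risk_z >= threshold
    groups = {
        "cases": y == 1,
        "controls": y == 0,
        "low_risk_cases": (~high) & (y == 1),
        "low_risk_controls": (~high) & (y == 0),
        "high_risk_cases": high & (y == 1),
        "high_risk_controls": high & (y == 0),
    }
    rows = []
    for name, mask in groups.items():
        n = int(mask.sum())
        if n < 3:
            rows.append((name, n, np.nan, np.nan, np.nan, np.nan, "too_few"))
            continue
        r, p = stats.pearsonr(risk_z[mask], resilience_z[mask])
        lo, hi = _fisher_ci(r, n)
        rows.append((name, n, float(r), lo, hi, float(p), "ok"))
    return pd.DataFrame(rows, columns=["group", "n", "r", "ci_low", "ci_high", "p", "status"])


def interaction_model(risk_z, resilience_z, labels, pcs=None) -> pd.DataFrame:
    """Logistic case ~ risk + resilience + risk x resilience (+ top PCs).

    Ultra-high-risk cases should be excluded upstream.  Returns a
    coefficient table (beta, se, z, p) for the three score terms and the
    PCs; a constant resilience score drops the resilience and interaction
    terms with an explicit design warning (their rows carry NaN).
    """
    risk_z = np.asarray(risk_z, dtype=float)
    res_z = np.asarray(resilience_z, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(y)

    degenerate = np.ptp(res_z) == 0
    if degenerate:
        warnings.warn("resilience score is constant: interaction term dropped from the design",
                      stacklevel=2)
    cols = [np.ones(n), risk_z]
    names = ["const", "risk"]
    if not degenerate:
        cols += [res_z, risk_z * res_z]
        names += ["resilience", "interaction"]
    if pcs is not None:
        pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
        if pcs.shape[0] != n:
            pcs = pcs.T
        for j in range(pcs.shape[1]):
            cols.append(pcs[:, j])
            names.append(f"pc{j + 1}")
    X = np.column_stack(cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    out = pd.DataFrame({
        "term": names,
        "beta": fit.params,
        "se": fit.bse,
        "z": fit.params / fit.bse,
        "p": fit.pvalues,
    })
    if degenerate:
        out = pd.concat([
            out,
            pd.DataFrame({"term": ["resilience", "interaction"],
                          "beta": np.nan, "se": np.nan, "z": np.nan, "p": np.nan}),
        ], ignore_index=True)
    sep = (np.abs(out["beta"]) > 15) | (out["se"] > 100)
    out["status"] = np.where(out["beta"].isna(), "dropped",
                             np.where(sep, "separated", "ok"))
    return out.set_index("term")


def decile_analysis(risk_z, labels, resilience_z=None, pcs=None) -> pd.DataFrame:
    """Risk-score decile ORs versus the bottom decile, plus within-decile
    resilience effects.

    Decile boundaries are linear-interpolation quantiles of the risk score
    (ties land in the lower decile).  For each decile d > 1 a logistic model
    of case status on membership (decile d vs decile 1) with PC adjustment
    gives the OR; within each decile, a logistic model of *control* status
    on the resilience score gives the resilience effect.
    """
    risk_z = np.asarray(risk_z, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    bounds = np.quantile(risk_z, np.arange(1, 10) / 10.0)
    decile = np.searchsorted(bounds, risk_z, side="left")  # 0..9; ties -> lower decile
    counts = np.bincount(decile, minlength=10)
    if (counts == 0).any():
        raise DesignError(f"empty risk decile(s): {np.flatnonzero(counts == 0) + 1}")
    if (counts < 10).any():
        raise DesignError("need at least 10 subjects per decile")

    if pcs is not None:
        pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
        if pcs.shape[0] != n:
            pcs = pcs.T

    def logit(Xcols, yy):
        X = np.column_stack(Xcols)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.Logit(yy, X).fit(disp=0, maxiter=200)

    rows = []
    bottom = decile == 0
    for d in range(10):
        mask = decile == d
        row = {"decile": d + 1, "n": int(mask.sum()), "n_cases": int(y[mask].sum())}
        if d == 0:
            row.update(or_vs_bottom=1.0, or_se=0.0, or_p=np.nan)
        else:
            sel = bottom | mask
            cols = [np.ones(sel.sum()), mask[sel].astype(float)]
            if pcs is not None:
                cols += [pcs[sel, j] for j in range(pcs.shape[1])]
            try:
                fit = logit(cols, y[sel])
                row.update(or_vs_bottom=float(np.exp(fit.params[1])),
                           or_se=float(fit.bse[1]), or_p=float(fit.pvalues[1]))
            except (np.linalg.LinAlgError, ValueError):
                row.update(or_vs_bottom=np.nan, or_se=np.nan, or_p=np.nan)
        if resilience_z is not None:
            rz = np.asarray(resilience_z, dtype=float)[mask]
            yy = 1 - y[mask]  # odds of being a control
            if len(np.unique(yy)) < 2 or np.ptp(rz) == 0:
                row.update(res_beta=np.nan, res_se=np.nan, res_p=np.nan)
            else:
                cols = [np.ones(mask.sum()), rz]
                if pcs is not None:
                    cols += [pcs[mask, j] for j in range(pcs.shape[1])]
                try:
                    fit = logit(cols, yy)
                    row.update(res_beta=float(fit.params[1]), res_se=float(fit.bse[1]),
                               res_p=float(fit.pvalues[1]))
                except (np.linalg.LinAlgError, ValueError):
                    row.update(res_beta=np.nan, res_se=np.nan, res_p=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def ld_vs_assoc_correlation(resilience_assoc: pd.DataFrame, risk_variants: pd.DataFrame,
                            ld_panel, window_kb: float = 1000.0,
                            stat: str = "abs_z"):
    """Correlation of resilience-association strength with LD to risk SNPs.

    For each resilience variant, take the maximum r^2 with any risk variant
    within +/- window_kb (0 when none is nearby), then Pearson-correlate
    with |z| (default) or -log10 p of the resilience association.
    """
    ld = ld_panel if isinstance(ld_panel, LdPanel) else LdPanel(ld_panel)
    t = resilience_assoc[np.isfinite(resilience_assoc["beta"])
                         & np.isfinite(resilience_assoc["se"])].reset_index(drop=True)
    if len(risk_variants) == 0:
        raise ValueError("no risk variants supplied; LD-vs-association is undefined")
    r2max = max_r2_to_risk(t, risk_variants[["snp", "chrom", "pos"]], ld, window_kb)
    if stat == "abs_z":
        x = np.abs(t["beta"] / t["se"])
    elif stat == "neglog10p":
        x = -np.log10(t["p"])
    else:
        raise ValueError("stat must be 'abs_z' or 'neglog10p'")
    if np.ptp(r2max.to_numpy()) == 0:
        return (np.nan, np.nan)
    r, p = stats.pearsonr(x, r2max)
    return (float(r), float(p))


def power_allelic(n_group1: int, n_group2: int, allele_freq: float, odds_ratio: float,
                  alpha: float = 0.05, anchor: str = "reference") -> float:
    """Power of the two-sided 1-df allelic two-proportion test (normal approx).

    ``allele_freq`` anchors the frequency in the reference group (group 2,
    default), the case group (``anchor='cases'``) or the pooled sample
    (``anchor='pooled'``); the other group's frequency follows from the odds
    ratio.  Allele counts are 2n per group.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    if not 0 < allele_freq < 1:
        raise ValueError("allele_freq must lie in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")

    def or_freq(p2):
        odds = odds_ratio * p2 / (1 - p2)
        return odds / (1 + odds)

    if anchor == "reference":
        p2 = allele_freq
        p1 = or_freq(p2)
    elif anchor == "cases":
        p1 = allele_freq
        odds = (p1 / (1 - p1)) / odds_ratio
        p2 = odds / (1 + odds)
    elif anchor == "pooled":
        from scipy.optimize import brentq
        w1 = n_group1 / (n_group1 + n_group2)

        def gap(p2):
            return w1 * or_freq(p2) + (1 - w1) * p2 - allele_freq
        p2 = brentq(gap, 1e-9, 1 - 1e-9)
        p1 = or_freq(p2)
    else:
        raise ValueError("anchor must be 'reference', 'cases' or 'pooled'")

    se = np.sqrt(p1 * (1 - p1) / (2 * n_group1) + p2 * (1 - p2) / (2 * n_group2))
    z_nc = abs(p1 - p2) / se
    za = stats.norm.isf(alpha / 2)
    return float(stats.norm.cdf(z_nc - za) + stats.norm.cdf(-z_nc - za))


# ---------------------------------------------------------------------------
# Gene-level aggregation
# ---------------------------------------------------------------------------

def map_snps_to_genes(variants: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Assign each SNP to every gene whose [start, end] contains its position.

    Coordinates are 1-based inclusive with no flanking extension; a SNP in
    two overlapping genes is assigned to both; intergenic SNPs are absent
    from the output.  Returns a (snp, gene_id) table.
    """
    idcol = "id" if "id" in variants.columns else "snp"
    trees = {}
    for c, g in genes.groupby("chrom"):
        tree = IntervalTree()
        for gid, start, end in zip(g["gene_id"], g["start"], g["end"]):
            tree.addi(start, end + 1, gid)  # inclusive end
        trees[c] = tree
    rows = []
    for snp, chrom, pos in zip(variants[idcol], variants["chrom"], variants["pos"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.at(pos):
            rows.append((snp, iv.data))
    return pd.DataFrame(rows, columns=["snp", "gene_id"])


def gene_scores(assignments: pd.DataFrame, risk_assoc: pd.DataFrame,
                resilience_assoc: pd.DataFrame, genes: pd.DataFrame,
                risk_p_max: float = 0.05) -> pd.DataFrame:
    """Per-gene mean association z-scores for risk and resilience.

    The risk score averages z = beta/se over intragenic risk SNPs with
    p < ``risk_p_max`` only; the resilience score averages over all
    intragenic resilience SNPs.  Covariates: gene length (kb), SNPs per kb
    (over all mapped SNPs) and mean MAF.  Genes with no qualifying SNP get
    NaN scores.
    """
    def z_table(assoc):
        t = assoc[np.isfinite(assoc["beta"]) & np.isfinite(assoc["se"])]
        return t.assign(zscore=t["beta"] / t["se"])

    risk = z_table(risk_assoc)
    risk = risk[risk["p"] < risk_p_max]
    resil = z_table(resilience_assoc)

    merged_risk = assignments.merge(risk[["snp", "zscore"]], on="snp")
    merged_res = assignments.merge(resil[["snp", "zscore", "frq"]], on="snp")
    risk_mean = merged_risk.groupby("gene_id")["zscore"].mean()
    res_mean = merged_res.groupby("gene_id")["zscore"].mean()
    n_snps = assignments.groupby("gene_id")["snp"].nunique()

    maf_source = resilience_assoc[["snp", "frq"]].copy()
    maf_source["maf"] = np.minimum(maf_source["frq"], 1 - maf_source["frq"])
    mean_maf = assignments.merge(maf_source, on="snp").groupby("gene_id")["maf"].mean()

    out = genes[["gene_id", "chrom", "start", "end", "biotype"]].copy()
    out["length_kb"] = (out["end"] - out["start"] + 1) / 1000.0
    out["risk_score"] = out["gene_id"].map(risk_mean)
    out["resilience_score"] = out["gene_id"].map(res_mean)
    out["n_snps"] = out["gene_id"].map(n_snps).fillna(0).astype(int)
    out["snps_per_kb"] = out["n_snps"] / out["length_kb"]
    out["mean_maf"] = out["gene_id"].map(mean_maf)
    return out


def gene_enrichment_regression(gene_table: pd.DataFrame, cluster: str = "chrom"):
    """OLS of per-gene risk score on resilience score with confound adjustment.

    Design: risk_score ~ resilience_score + length_kb + snps_per_kb +
    mean_maf + chromosome indicators; cluster-robust (sandwich) SEs with
    clusters = chromosomes and the small-sample factor
    G/(G-1) * (n-1)/(n-k).  Returns (beta, robust_se, p, results).
    """
    t = gene_table.dropna(subset=["risk_score", "resilience_score", "mean_maf"]).copy()
    if t[cluster].nunique() < 2:
        raise DesignError("need at least 2 clusters for cluster-robust errors")
    t["chrom_f"] = t[cluster].astype("category")
    formula = "risk_score ~ resilience_score + length_kb + snps_per_kb + mean_maf + C(chrom_f)"
    model = smf.ols(formula, data=t)
    if model.exog.shape[0] <= model.exog.shape[1] + 1:
        raise DesignError(
            f"too few genes ({model.exog.shape[0]}) for {model.exog.shape[1]} "
            "design columns")
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        from scipy.linalg import qr
        _, _, piv = qr(model.exog, pivoting=True)
        bad = [model.exog_names[j] for j in piv[rank:]]
        raise DesignError(f"rank-deficient design; collinear column(s): {bad}")
    res = model.fit(cov_type="cluster",
                    cov_kwds={"groups": t["chrom_f"].cat.codes, "use_correction": True})
    beta = float(res.params["resilience_score"])
    se = float(res.bse["resilience_score"])
    p = float(res.pvalues["resilience_score"])
    return beta, se, p, res
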