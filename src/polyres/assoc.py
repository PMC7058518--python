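"""Per-study logistic association, inverse-variance fixed-effect meta-analysis and scan diagnostics.

The per-SNP scan uses an in-package Newton (IRLS) maximizer of the logistic
likelihood so that thousands of single-variant fits stay cheap; the model is
the standard additive-dosage logistic regression with covariates, reported as
ln OR, Wald SE and a two-sided normal p-value.  Pooling follows the
inverse-variance fixed-effect rule: w_i = 1/se_i^2, beta = sum(w b)/sum(w),
se = sum(w)^(-1/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, HarmonizationError
from .io import GenotypePanel, complement_allele

log = logging.getLogger(__name__)

CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.4549364...


def _logistic_loglik(X, y, b):
    eta = X @ b
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def logistic_mle(X, y, max_iter=40, tol=1e-10):
    """Newton-Raphson logistic MLE with step-halving.

    Returns (beta, cov, loglik, converged).  ``cov`` is the inverse observed
    information at the optimum.
    """
    n, k = X.shape
    b = np.zeros(k)
    ll = _logistic_loglik(X, y, b)
    converged = False
    H = np.eye(k)
    for _ in range(max_iter):
        eta = X @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return b, None, ll, False
        # backtrack if the full Newton step overshoots
        for _half in range(25):
            b_new = b + step
            ll_new = _logistic_loglik(X, y, b_new)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        delta = np.max(np.abs(b_new - b))
        b, ll = b_new, ll_new
        if delta < tol or np.max(np.abs(grad)) < 1e-9:
            converged = True
            break
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = None
    return b, cov, ll, converged


def logistic_assoc(
    panel: GenotypePanel,
    covariate_ids=(0, 1, 2, 3),
    outcome: np.ndarray | None = None,
    subset: np.ndarray | None = None,
) -> pd.DataFrame:
    """Additive per-variant logistic association scan for one study.

    Parameters
    ----------
    panel : GenotypePanel
    covariate_ids : sequence of int
        Columns of ``panel.pcs`` included as covariates (ignored when the
        panel carries no PCs).
    outcome : optional binary array overriding the panel phenotype (e.g.
        resilient-control = 1 vs matched-case = 0).
    subset : optional boolean mask or integer index restricting subjects.

    Returns a summary-statistics table (one row per variant) with a
    ``status`` column: ok / monomorphic / separated / unconverged.  Missing
    dosages are mean-imputed for the fit.
    """
    y = panel.phenotype() if outcome is None else np.asarray(outcome).astype(int)
    dosage = panel.dosage
    pcs = panel.pcs
    if subset is not None:
        y = y[subset]
        dosage = dosage[subset]
        pcs = pcs[subset] if pcs is not None else None
    if len(np.unique(y)) < 2:
        raise DesignError("phenotype has a single class; association is undefined")

    n = len(y)
    if pcs is not None and len(covariate_ids) > 0:
        ids = [i for i in covariate_ids if i < pcs.shape[1]]
        C = np.column_stack([np.ones(n)] + [pcs[:, i] for i in ids])
    else:
        C = np.ones((n, 1))

    m = dosage.shape[1]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    frq = np.full(m, np.nan)
    status = np.full(m, "ok", dtype=object)

    X = np.empty((n, 1 + C.shape[1]))
    X[:, 1:] = C
    for j in range(m):
        d = dosage[:, j].copy()
        miss = np.isnan(d)
        if miss.all():
            status[j] = "monomorphic"
            continue
        if miss.any():
            d[miss] = np.nanmean(d)
        frq[j] = d.mean() / 2.0
        if np.ptp(d) == 0:
            status[j] = "monomorphic"
            continue
        X[:, 0] = d
        b, cov, _ll, converged = logistic_mle(X, y)
        if cov is None or not converged:
            status[j] = "unconverged"
            continue
        sj = float(np.sqrt(cov[0, 0]))
        if abs(b[0]) > 15 or sj > 100:
            status[j] = "separated"
            continue
        beta[j] = b[0]
        se[j] = sj
        pval[j] = 2.0 * stats.norm.sf(abs(b[0] / sj))

    v = panel.variants
    return pd.DataFrame({
        "snp": v["id"].to_numpy(),
        "chrom": v["chrom"].to_numpy(),
        "pos": v["pos"].to_numpy(),
        "a1": v["a1"].to_numpy(),
        "a2": v["a2"].to_numpy(),
        "frq": frq,
        "info": v["info"].to_numpy(),
        "beta": beta,
        "se": se,
        "p": np.clip(pval, np.finfo(float).tiny, 1.0),
        "n_studies": 1,
        "status": status,
    })


@dataclass
class MetaResult:
    """Pooled fixed-effect meta-analysis of per-study association tables."""

    table: pd.DataFrame            # sumstats columns; n_studies = studies pooled per variant
    n_studies: int                 # studies supplied
    lambda_gc: float
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)  # harmonization drop log


def _orientation(a1, a2, ref_a1, ref_a2):
    """+1 if (a1,a2) matches the reference orientation (allowing strand
    complement), -1 if swapped, 0 if irreconcilable.  Strand-ambiguous pairs
    resolve by direct letter match first."""
    if a1 == ref_a1 and a2 == ref_a2:
        return 1
    if a1 == ref_a2 and a2 == ref_a1:
        return -1
    ca1, ca2 = complement_allele(a1), complement_allele(a2)
    if ca1 == ref_a1 and ca2 == ref_a2:
        return 1
    if ca1 == ref_a2 and ca2 == ref_a1:
        return -1
    return 0


def fixed_effect_meta(tables, study_ids=None, strict: bool = False) -> MetaResult:
    """Inverse-variance fixed-effect pooling of per-study summary statistics.

    Alleles are harmonized to the first study observed at each variant: a
    swapped a1/a2 flips the beta sign (and frequency); unambiguous strand
    flips are complemented; irreconcilable allele sets are dropped with a log
    record (or raise when ``strict``).
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no studies to pool")
    if study_ids is None:
        study_ids = [f"study{i}" for i in range(len(tables))]

    frames = []
    for sid, t in zip(study_ids, tables):
        t = t.copy()
        t["study"] = sid
        ok = np.isfinite(t["beta"]) & np.isfinite(t["se"]) & (t["se"] > 0)
        frames.append(t[ok])
    long = pd.concat(frames, ignore_index=True)
    if long.empty:
        raise ValueError("no usable association records to pool")

    ref = long.drop_duplicates("snp")[["snp", "chrom", "pos", "a1", "a2"]] \
        .rename(columns={"a1": "ref_a1", "a2": "ref_a2"})
    merged = long.merge(ref[["snp", "ref_a1", "ref_a2"]], on="snp")
    sign = np.array([
        _orientation(a1, a2, r1, r2)
        for a1, a2, r1, r2 in zip(merged["a1"], merged["a2"], merged["ref_a1"], merged["ref_a2"])
    ])
    bad = sign == 0
    dropped = merged.loc[bad, ["snp", "study", "a1", "a2", "ref_a1", "ref_a2"]].reset_index(drop=True)
    if bad.any():
        if strict:
            raise HarmonizationError(
                "irreconcilable alleles at variant(s): "
                + ", ".join(sorted(dropped["snp"].unique())[:10])
            )
        log.warning("meta-analysis dropped %d study-records with irreconcilable alleles", bad.sum())
        merged = merged[~bad]
        sign = sign[~bad]

    w = 1.0 / merged["se"].to_numpy() ** 2
    merged = merged.assign(
        w=w,
        wb=w * sign * merged["beta"].to_numpy(),
        wf=w * np.where(sign > 0, merged["frq"], 1.0 - merged["frq"]),
    )
    grp = merged.groupby("snp", sort=False)
    sw = grp["w"].sum()
    pooled = pd.DataFrame({
        "snp": sw.index,
        "beta": grp["wb"].sum() / sw,
        "se": 1.0 / np.sqrt(sw),
        "n_studies": grp.size(),
        "frq": grp["wf"].sum() / sw,
        "info": grp["info"].min(),
    }).reset_index(drop=True)
    pooled["p"] = np.clip(2.0 * stats.norm.sf(np.abs(pooled["beta"] / pooled["se"])),
                          np.finfo(float).tiny, 1.0)
    pooled = pooled.merge(ref, on="snp").rename(columns={"ref_a1": "a1", "ref_a2": "a2"})
    pooled = pooled[["snp", "chrom", "pos", "a1", "a2", "frq", "info", "beta", "se", "p", "n_studies"]]
    lam = genomic_inflation(pooled["p"].to_numpy())
    return MetaResult(pooled, len(tables), lam, dropped)


def genomic_inflation(pvals) -> float:
    """Genomic inflation factor: median association chi-square over the
    chi-square(1) median."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_1_MEDIAN)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def qq_points(pvals):
    """Expected/observed -log10(p) pairs with expected quantiles (i-0.5)/n."""
    p = np.sort(np.asarray(pvals, dtype=float))
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)[::-1]
    observed = -np.log10(p)[::-1]
    return expected, observed
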