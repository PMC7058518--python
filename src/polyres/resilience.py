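"""Resilience-score association: two-model Nagelkerke fit, liability transform, replication meta.

The central object is :class:`ResilienceModel`: a logistic regression of
resilient-control (1) versus matched-case (0) status on a standardized
resilience score plus selected principal components.  ``fit()`` returns a
:class:`FitResult` carrying the score coefficient (ln OR per SD), its Wald
SE and p, and the incremental Nagelkerke pseudo-R^2 of the score over the
covariate-only model, optionally transformed to the liability scale at
population prevalence K (default 0.10, matching the 90th-percentile
definition of resilience).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import AlignmentError

# statsmodels moved PerfectSeparationError across versions; fall back broadly
try:  # pragma: no cover - import shim
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError, PerfectSeparationWarning,
    )
except ImportError:  # pragma: no cover
    class PerfectSeparationError(Exception):
        pass

    class PerfectSeparationWarning(Warning):
        pass


def nagelkerke_r2(loglik_null: float, loglik_model: float, n: int) -> float:
    """Nagelkerke's pseudo-R^2: Cox-Snell rescaled to a unit maximum.

    R^2 = (1 - exp(2*(ll0 - ll1)/n)) / (1 - exp(2*ll0/n)).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if loglik_null == 0:
        raise ValueError("null log-likelihood of 0 leaves Nagelkerke R^2 undefined")
    if loglik_model < loglik_null - 1e-6:
        raise ValueError("model log-likelihood must be >= null log-likelihood")
    cox_snell = 1.0 - math.exp(2.0 * (loglik_null - min(loglik_model, 0.0)) / n)
    max_r2 = 1.0 - math.exp(2.0 * loglik_null / n)
    return max(cox_snell, 0.0) / max_r2


def liability_multiplier(K: float, P: float) -> float:
    """Ascertainment-corrected observed-to-liability R^2 conversion factor.

    K is the population prevalence of the modeled class, P its proportion in
    the analyzed sample, and z the standard-normal density at the liability
    threshold Phi^{-1}(1-K):  C = K^2 (1-K)^2 / (z^2 P (1-P)).
    """
    if not 0.0 < K < 1.0 or not 0.0 < P < 1.0:
        raise ValueError("K and P must lie in (0, 1)")
    t = stats.norm.isf(K)
    z = stats.norm.pdf(t)
    return (K ** 2) * ((1.0 - K) ** 2) / (z ** 2 * P * (1.0 - P))


def liability_transform(r2_obs: float, K: float = 0.10, P: float = 0.5) -> float:
    """Convert observed-scale variance explained to the liability scale."""
    if not 0.0 <= r2_obs <= 1.0:
        raise ValueError("r2_obs must lie in [0, 1]")
    return r2_obs * liability_multiplier(K, P)


@dataclass
class FitResult:
    """One resilience-score fit (one p-value bin, one cohort)."""

    cohort: str
    cutoff: float
    beta: float            # ln OR per SD of resilience score
    se: float
    p: float
    nagelkerke_full: float
    nagelkerke_cov: float
    delta_r2: float
    liability_r2: float
    n_resilient: int
    n_cases: int
    status: str = "ok"

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def n(self) -> int:
        return self.n_resilient + self.n_cases

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort, "cutoff": self.cutoff, "beta": self.beta,
            "se": self.se, "p": self.p, "or": self.odds_ratio,
            "nagelkerke_full": self.nagelkerke_full,
            "nagelkerke_cov": self.nagelkerke_cov,
            "delta_r2": self.delta_r2, "liability_r2": self.liability_r2,
            "n_resilient": self.n_resilient, "n_cases": self.n_cases,
            "status": self.status,
        }

    def summary(self) -> str:
        lines = [
            "Resilience-score logistic fit "
            f"(cohort={self.cohort}, p<{self.cutoff} bin, status={self.status})",
            f"  resilient controls: {self.n_resilient}   matched cases: {self.n_cases}",
            f"  ln OR per SD: {self.beta:+.4f}  (SE {self.se:.4f}, p = {self.p:.3g})",
            f"  OR per SD:    {self.odds_ratio:.4f}",
            f"  Nagelkerke R^2: full {self.nagelkerke_full:.4f}, covariates "
            f"{self.nagelkerke_cov:.4f}, score Delta {self.delta_r2:.4f}",
            f"  liability-scale R^2: {self.liability_r2:.5f}",
        ]
        return "\n".join(lines)


def fits_frame(fits) -> pd.DataFrame:
    return pd.DataFrame([f.to_dict() for f in fits])


class ResilienceModel:
    """Logistic model of resilient-vs-matched-case status on a resilience score.

    Parameters
    ----------
    is_resilient : binary array (1 = resilient control, 0 = matched case)
    score_z : standardized resilience score per subject
    pcs : optional covariate matrix (the selected principal components)
    cutoff : p-value bin label carried into the result
    prevalence : population prevalence K of resilience for the liability
        transform (0.10 for the 90th-percentile definition)
    """

    def __init__(self, is_resilient, score_z, pcs=None, cutoff=float("nan"),
                 cohort="cohort", prevalence=0.10):
        self.y = np.asarray(is_resilient, dtype=float)
        if not np.isin(self.y, [0.0, 1.0]).all():
            raise ValueError("is_resilient must be binary")
        self.score = np.asarray(score_z, dtype=float)
        self.pcs = None if pcs is None else np.atleast_2d(np.asarray(pcs, dtype=float))
        if self.pcs is not None and self.pcs.shape[0] != len(self.y):
            self.pcs = self.pcs.T
        self.cutoff = cutoff
        self.cohort = cohort
        self.prevalence = prevalence

    def _null_loglik(self) -> float:
        p = self.y.mean()
        n1 = self.y.sum()
        n0 = len(self.y) - n1
        return float(n1 * math.log(p) + n0 * math.log(1 - p))

    def fit(self) -> FitResult:
        n = len(self.y)
        n1 = int(self.y.sum())
        if n1 == 0 or n1 == n:
            raise ValueError("both resilient controls and matched cases are required")
        covs = [np.ones(n)]
        if self.pcs is not None and self.pcs.shape[1] > 0:
            covs.append(self.pcs)
        X_cov = np.column_stack(covs)
        X_full = np.column_stack([X_cov, self.score])

        status = "ok"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                full = sm.Logit(self.y, X_full).fit(disp=0, maxiter=200)
                cov_only = sm.Logit(self.y, X_cov).fit(disp=0, maxiter=200)
            except (PerfectSeparationError, np.linalg.LinAlgError):
                return FitResult(self.cohort, self.cutoff, math.nan, math.nan, math.nan,
                                 math.nan, math.nan, math.nan, math.nan,
                                 n1, n - n1, status="separated")
        beta = float(full.params[-1])
        se = float(full.bse[-1])
        if not np.isfinite(se) or se > 100 or abs(beta) > 15:
            status = "separated"
        ll0 = self._null_loglik()
        r2_full = nagelkerke_r2(ll0, float(full.llf), n)
        r2_cov = nagelkerke_r2(ll0, float(cov_only.llf), n)
        delta = r2_full - r2_cov
        if delta < 0:
            delta = 0.0 if delta > -1e-9 else delta
        P = n1 / n
        liab = liability_transform(min(max(delta, 0.0), 1.0), self.prevalence, P)
        pval = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else math.nan
        return FitResult(self.cohort, self.cutoff, beta, se, pval,
                         r2_full, r2_cov, delta, liab, n1, n - n1, status=status)


def fit_resilience_assoc(score_z, is_resilient, pcs=None, cutoff=float("nan"),
                         cohort="cohort", prevalence=0.10) -> FitResult:
    """Convenience wrapper: build a :class:`ResilienceModel` and fit it."""
    return ResilienceModel(is_resilient, score_z, pcs=pcs, cutoff=cutoff,
                           cohort=cohort, prevalence=prevalence).fit()


def replicate_meta(cohort_fits: dict) -> pd.DataFrame:
    """Inverse-variance fixed-effect pooling of per-cohort fits, bin by bin.

    ``cohort_fits`` maps cohort name -> list of :class:`FitResult` (one per
    p-value bin).  All cohorts must carry the same bins.  Pooling follows the
    same contract as the GWAS meta-analysis, applied to the score
    coefficient; Nagelkerke and liability R^2 are averaged arithmetically
    across cohorts.  BH-FDR across bins is applied to the pooled p-values.
    A single cohort passes through with a warning.
    """
    from .assoc import bh_fdr  # local import to avoid a cycle at module load

    if not cohort_fits:
        raise ValueError("no cohorts to pool")
    names = list(cohort_fits)
    bins = [tuple(f.cutoff for f in cohort_fits[nm]) for nm in names]
    if len(set(bins)) != 1:
        raise AlignmentError(f"cohorts carry mismatched p-value bins: {dict(zip(names, bins))}")
    if len(names) == 1:
        warnings.warn("single cohort: replication meta-analysis is a passthrough", stacklevel=2)

    rows = []
    for i, cutoff in enumerate(bins[0]):
        fits = [cohort_fits[nm][i] for nm in names]
        usable = [f for f in fits if np.isfinite(f.beta) and np.isfinite(f.se) and f.se > 0]
        if not usable:
            rows.append({"cutoff": cutoff, "beta": np.nan, "se": np.nan, "p": np.nan,
                         "or": np.nan, "k": 0, "delta_r2_mean": np.nan,
                         "liability_r2_mean": np.nan})
            continue
        w = np.array([1.0 / f.se ** 2 for f in usable])
        beta = float(np.sum(w * [f.beta for f in usable]) / w.sum())
        se = float(1.0 / math.sqrt(w.sum()))
        rows.append({
            "cutoff": cutoff,
            "beta": beta,
            "se": se,
            "p": float(2.0 * stats.norm.sf(abs(beta / se))),
            "or": math.exp(beta),
            "k": len(usable),
            "delta_r2_mean": float(np.mean([f.delta_r2 for f in usable])),
            "liability_r2_mean": float(np.mean([f.liability_r2 for f in usable])),
        })
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    return out
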