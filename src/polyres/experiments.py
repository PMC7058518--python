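"""Canned simulation experiments: the package's own study conditions.

Two designs are frozen here and reused by the test suite and the acceptance
script:

* ``null_experiment`` — no resilience architecture (b_int = 0, gamma = 0),
  two studies (one discovery, one held-out).  Used for type-I-error
  calibration of the held-out resilience-score test and of the
  risk x resilience interaction test.
* ``resilience_experiment`` — the default resilience architecture
  (b_int = -0.5, 20 resilience loci) with two discovery studies and one
  held-out cohort.  Used for direction recovery: held-out score OR > 1,
  negative interaction, control-specific positive risk-resilience
  correlation.

Problem sizes are deliberately desk-scale (hundreds of markers, a few
thousand subjects) so that hundreds of replicates run on a single CPU.
"""

from __future__ import annotations

import numpy as np

from .pipeline import PipelineConfig, run_simulated_study
from .simulate import SimConfig


def null_sim_config(seed: int) -> SimConfig:
    """Two-study design with risk but no resilience architecture."""
    return SimConfig(
        n_studies=2, n_cases=800, n_controls=800,
        m_variants=160, block_size=8,
        n_risk_loci=15, n_resilience_loci=0,
        risk_effect_sd=0.3,
        resilience_effect_sd=0.0, b_int=0.0,
        seed=seed,
    )


def resilience_sim_config(seed: int) -> SimConfig:
    """Default resilience architecture: 2 discovery + 1 held-out study."""
    return SimConfig(seed=seed)


def _experiment_pipeline_config(analysis_bin: float = 0.3) -> PipelineConfig:
    return PipelineConfig(min_studies=1, analysis_bin=analysis_bin)


def null_replicate(seed: int, analysis_bin: float = 0.5) -> dict:
    """One null-pipeline replicate; returns held-out test p-values.

    The discovery study supplies risk weights, strata and (noise-only)
    resilience weights; the held-out study is stratified and scored with
    them.  Under the null the score p-value and the interaction p-value are
    both uniform.
    """
    result = run_simulated_study(
        null_sim_config(seed), _experiment_pipeline_config(analysis_bin),
        n_discovery=1, n_reference=379, analyses=True)
    cohort = next(iter(result.replication_fits))
    fits = {f.cutoff: f for f in result.replication_fits[cohort]}
    fit = fits[analysis_bin]
    inter = result.analyses["interaction"]
    return {
        "score_p": fit.p,
        "score_beta": fit.beta,
        "interaction_p": float(inter.loc["interaction", "p"]),
        "interaction_beta": float(inter.loc["interaction", "beta"]),
        "status": fit.status,
    }


def resilience_replicate(seed: int, analysis_bin: float = 0.3) -> dict:
    """One resilience-architecture replicate; returns held-out recovery stats."""
    result = run_simulated_study(
        resilience_sim_config(seed), _experiment_pipeline_config(analysis_bin),
        n_discovery=2, n_reference=379, analyses=True)
    cohort = next(iter(result.replication_fits))
    fits = {f.cutoff: f for f in result.replication_fits[cohort]}
    fit = fits[analysis_bin]
    inter = result.analyses["interaction"]
    corr = result.analyses["correlations"].set_index("group")
    disc = {f.cutoff: f for f in result.discovery_fits}
    return {
        "heldout_or": fit.odds_ratio,
        "heldout_p": fit.p,
        "heldout_delta_r2": fit.delta_r2,
        "interaction_beta": float(inter.loc["interaction", "beta"]),
        "interaction_p": float(inter.loc["interaction", "p"]),
        "r_controls": float(corr.loc["controls", "r"]),
        "r_cases": float(corr.loc["cases", "r"]),
        "discovery_delta_r2": disc[analysis_bin].delta_r2,
        "lambda_gc": result.resilience_meta.lambda_gc,
        "status": fit.status,
    }


def rejection_rate(pvals, alpha: float = 0.05) -> float:
    p = np.asarray([x for x in pvals if np.isfinite(x)], dtype=float)
    if p.size == 0:
        raise ValueError("no finite p-values")
    return float(np.mean(p < alpha))


def binomial_interval(rate0: float, n: int, level: float = 0.95):
    """Normal-approximation acceptance interval for a rejection rate."""
    from scipy import stats
    z = stats.norm.isf((1 - level) / 2)
    half = z * np.sqrt(rate0 * (1 - rate0) / n)
    return (max(rate0 - half, 0.0), min(rate0 + half, 1.0))
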