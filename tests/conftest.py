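"""Shared fixtures: toy genotype panels, exact-correlation LD fixtures, and a
session-scoped small pipeline run reused across tests."""

import numpy as np
import pandas as pd
import pytest

from polyres.io import GenotypePanel
from polyres.pipeline import PipelineConfig, run_simulated_study
from polyres.simulate import SimConfig


def make_panel(dosage, phenotype, study_id="s1", chrom=None, pos=None, a1=None,
               a2=None, pcs=None, maf=None, info=None, n_studies=None):
    """Build a GenotypePanel from raw arrays with sensible metadata defaults."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosage, axis=0) / 2.0
    variants = pd.DataFrame({
        "id": [f"v{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else 1,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
        "a1": a1 if a1 is not None else "A",
        "a2": a2 if a2 is not None else "G",
        "maf": maf if maf is not None else np.minimum(freq, 1 - freq),
        "info": info if info is not None else 1.0,
        "n_studies": n_studies if n_studies is not None else 1,
    })
    subjects = pd.DataFrame({
        "subject_id": [f"{study_id}_i{i}" for i in range(n)],
        "phenotype": np.asarray(phenotype, dtype=int),
    })
    return GenotypePanel(study_id, subjects, variants, dosage, pcs)


def exact_corr_columns(rng, n, corrs):
    """Columns with exact sample correlation to a base column.

    Returns (n, 1 + len(corrs)) matrix: column 0 is the base; column i+1 has
    sample Pearson correlation exactly corrs[i] with the base (columns are
    centered and orthonormalized before mixing).
    """
    k = len(corrs) + 1
    raw = rng.standard_normal((n, k))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    base = q[:, 0]
    cols = [base]
    for i, r in enumerate(corrs):
        cols.append(r * base + np.sqrt(1.0 - r ** 2) * q[:, i + 1])
    return np.column_stack(cols)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def panel_factory():
    return make_panel


@pytest.fixture(scope="session")
def small_sim():
    """A small two-study simulation with both risk and resilience architecture."""
    cfg = SimConfig(n_studies=2, n_cases=500, n_controls=500, m_variants=160,
                    block_size=8, n_risk_loci=10, n_resilience_loci=5,
                    risk_effect_sd=0.3, resilience_effect_sd=0.5, seed=7)
    from polyres.simulate import simulate_multistudy
    panels, truth = simulate_multistudy(cfg)
    return cfg, panels, truth


@pytest.fixture(scope="session")
def small_run():
    """A complete small pipeline run (2 discovery + 1 replication study)."""
    sim = SimConfig(n_studies=3, n_cases=600, n_controls=600, m_variants=160,
                    block_size=8, n_risk_loci=10, n_resilience_loci=8, seed=11)
    cfg = PipelineConfig(min_studies=1)
    return run_simulated_study(sim, cfg, n_discovery=2, analyses=True)
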