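"""Multi-study case-control simulator with LD blocks, polygenic risk and resilience loci.

Genotypes are drawn haplotype-wise from a Gaussian copula with exchangeable
within-block correlation ``rho`` and thresholded at each marker's allele
frequency, which gives Hardy-Weinberg marginals and block-structured LD.
Phenotypes follow a logit model with a centered risk x resilience
interaction:

    logit P(case) = alpha + R + c_s * S + b_int * (R - mu_R) * (S - mu_S)

where R = sum_j beta_j g_j over risk loci, S = sum_k gamma_k g_k over
resilience loci (gamma_k >= 0, so the a1 allele of a resilience locus is the
protective one), c_s is the resilience main effect (0 by default, so
resilience loci carry no marginal full-sample association and act purely by
moderating penetrance in high-risk subjects when b_int < 0), and alpha is
calibrated by bisection so the realized case rate matches ``base_rate``.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so per-study streams are independent
and runs are fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, CapacityError
from .io import GenotypePanel

_UNAMBIGUOUS_PAIRS = (("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"))


@dataclass
class SimConfig:
    """Generative parameters for a multi-study case-control simulation.

    Defaults describe the desk-scale study conditions used throughout the
    package's own experiments: 3 studies (2 discovery + 1 held-out) of
    5000 cases / 5000 controls, 400 markers in 50 exchangeable LD blocks of
    8, 20 risk and 20 resilience loci in disjoint blocks, and a
    penetrance-moderating interaction b_int = -0.5.
    """

    n_studies: int = 3
    n_cases: int = 5000
    n_controls: int = 5000
    m_variants: int = 400
    block_size: int = 8
    rho: float = 0.85
    n_risk_loci: int = 20
    n_resilience_loci: int = 20
    # Deliberately weak per-allele risk effects: the ascertainment-induced
    # marginal association of resilience loci scales with SD(R)^2 while the
    # high-risk-stratum contrast scales with SD(R), so a modest risk scale
    # keeps resilience loci orthogonal to the full-sample risk scan (the
    # model's core postulate) yet detectable in the resilient-vs-matched
    # contrast.
    risk_effect_sd: float = 0.25
    resilience_effect_sd: float = 0.5
    resilience_main_effect: float = 0.0
    b_int: float = -0.5
    base_rate: float = 0.20
    maf_range: tuple = (0.05, 0.5)
    freq_jitter_sd: float = 0.01
    n_pcs: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.m_variants % self.block_size != 0:
            raise ValueError("m_variants must be a multiple of block_size")
        n_blocks = self.m_variants // self.block_size
        if self.n_risk_loci + self.n_resilience_loci > n_blocks:
            raise ValueError(
                "risk and resilience loci must occupy disjoint LD blocks: need "
                f"{self.n_risk_loci + self.n_resilience_loci} blocks, have {n_blocks}"
            )
        if self.n_risk_loci + self.n_resilience_loci > self.m_variants:
            raise ValueError("more loci than markers")
        if not 0.0 < self.base_rate < 1.0:
            raise ValueError("base_rate must lie in (0, 1)")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth of a simulation run, for parameter-recovery tests."""

    risk_loci: pd.DataFrame          # snp, block, beta_true
    resilience_loci: pd.DataFrame    # snp, block, gamma_true
    b_int: float
    alpha: dict                      # study_id -> calibrated intercept
    study_freqs: pd.DataFrame        # snp x study allele-1 frequency
    block: np.ndarray                # block index per variant
    seed: int


@dataclass
class _Architecture:
    variants: pd.DataFrame
    freqs: np.ndarray
    block: np.ndarray
    risk_idx: np.ndarray
    res_idx: np.ndarray
    beta: np.ndarray     # per-variant risk effect (0 off risk loci)
    gamma: np.ndarray    # per-variant resilience effect (0 off resilience loci)
    mu_r: float
    mu_s: float


def _build_architecture(cfg: SimConfig) -> _Architecture:
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(0,))
    rng = np.random.default_rng(ss)
    m = cfg.m_variants
    n_blocks = m // cfg.block_size
    block = np.repeat(np.arange(n_blocks), cfg.block_size)

    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    pair_idx = rng.integers(0, len(_UNAMBIGUOUS_PAIRS), size=m)
    a1 = np.array([_UNAMBIGUOUS_PAIRS[i][0] for i in pair_idx])
    a2 = np.array([_UNAMBIGUOUS_PAIRS[i][1] for i in pair_idx])

    # lay blocks round-robin across a handful of chromosomes (several blocks
    # per chromosome, so clump/exclusion windows see neighbouring blocks);
    # random 10-90 kb marker gaps make block spans (hence synthetic gene
    # lengths and SNP densities) vary
    n_chroms = min(22, max(2, n_blocks // 6))
    chrom = (block % n_chroms) + 1
    pos = np.zeros(m, dtype=int)
    cursors = {}
    gaps = rng.integers(10_000, 90_000, size=m)
    for j in range(m):
        c = chrom[j]
        cursors[c] = cursors.get(c, 1_000_000) + int(gaps[j])
        pos[j] = cursors[c]

    chosen = rng.choice(n_blocks, size=cfg.n_risk_loci + cfg.n_resilience_loci, replace=False)
    risk_blocks = chosen[:cfg.n_risk_loci]
    res_blocks = chosen[cfg.n_risk_loci:]
    risk_idx = np.array(
        [rng.integers(b * cfg.block_size, (b + 1) * cfg.block_size) for b in risk_blocks],
        dtype=int)
    res_idx = np.array(
        [rng.integers(b * cfg.block_size, (b + 1) * cfg.block_size) for b in res_blocks],
        dtype=int)

    beta = np.zeros(m)
    gamma = np.zeros(m)
    beta[risk_idx] = rng.normal(0.0, cfg.risk_effect_sd, size=cfg.n_risk_loci)
    gamma[res_idx] = np.abs(rng.normal(0.0, cfg.resilience_effect_sd, size=cfg.n_resilience_loci))

    variants = pd.DataFrame({
        "id": [f"rs{j + 1:06d}" for j in range(m)],
        "chrom": chrom,
        "pos": pos,
        "a1": a1,
        "a2": a2,
        "maf": np.minimum(freqs, 1.0 - freqs),
        "info": 1.0,
        "n_studies": cfg.n_studies,
    })
    mu_r = float(np.sum(beta * 2.0 * freqs))
    mu_s = float(np.sum(gamma * 2.0 * freqs))
    return _Architecture(variants, freqs, block, risk_idx, res_idx, beta, gamma, mu_r, mu_s)


def _draw_genotypes(rng, n: int, freqs: np.ndarray, block: np.ndarray, rho: float) -> np.ndarray:
    """Copula-threshold genotypes: two independent haplotypes per subject.

    Each haplotype's latent vector is sqrt(rho) * (shared block factor) +
    sqrt(1-rho) * noise, thresholded at Phi^{-1}(p_j); summing two
    haplotypes gives Hardy-Weinberg marginals with exchangeable block LD.
    """
    m = freqs.size
    thresholds = stats.norm.ppf(freqs).astype(np.float32)
    g = np.zeros((n, m), dtype=np.int8)
    sr, se_ = np.float32(np.sqrt(rho)), np.float32(np.sqrt(1.0 - rho))
    for _hap in range(2):
        z = rng.standard_normal((n, m), dtype=np.float32)
        z *= se_
        shared = rng.standard_normal((n, block.max() + 1), dtype=np.float32)
        z += sr * shared[:, block]
        g += z < thresholds
    return g


def _calibrate_alpha(linpred_no_alpha: np.ndarray, base_rate: float,
                     tol: float = 1e-4, max_iter: int = 200) -> float:
    lo, hi = -40.0, 40.0
    rate = float("nan")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        with np.errstate(over="ignore"):
            rate = float(np.mean(1.0 / (1.0 + np.exp(-(mid + linpred_no_alpha)))))
        if abs(rate - base_rate) < tol:
            return mid
        if rate < base_rate:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"intercept calibration failed: achieved rate {rate:.4f}, target {base_rate:.4f}"
    )


def _compute_pcs(dosage: np.ndarray, n_pcs: int) -> np.ndarray:
    """Leading genotype principal components via the m x m covariance eigenproblem."""
    D = dosage.astype(float)
    mu = D.mean(axis=0)
    sd = D.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (D - mu) / sd
    C = Z.T @ Z
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1][:n_pcs]
    pcs = Z @ vecs[:, order]
    psd = pcs.std(axis=0)
    psd[psd == 0] = 1.0
    return pcs / psd


def _simulate_panel(cfg: SimConfig, arch: _Architecture, study_seed, study_id: str,
                    n_cases: int, n_controls: int):
    rng = np.random.default_rng(study_seed)
    freqs = np.clip(arch.freqs + rng.normal(0.0, cfg.freq_jitter_sd, size=arch.freqs.size),
                    0.01, 0.99)

    target = max(int(n_cases / cfg.base_rate), int(n_controls / (1 - cfg.base_rate)))
    chunk = int(target * 1.3) + 200
    cases, controls = [], []
    alpha = None
    for _attempt in range(12):
        g = _draw_genotypes(rng, chunk, freqs, arch.block, cfg.rho)
        R = g @ arch.beta
        S = g @ arch.gamma
        lin = (R + cfg.resilience_main_effect * S
               + cfg.b_int * (R - arch.mu_r) * (S - arch.mu_s))
        if alpha is None:
            alpha = _calibrate_alpha(lin, cfg.base_rate)
        with np.errstate(over="ignore"):
            prob = 1.0 / (1.0 + np.exp(-(alpha + lin)))
        y = rng.random(chunk) < prob
        cases.append(g[y])
        controls.append(g[~y])
        if sum(len(c) for c in cases) >= n_cases and sum(len(c) for c in controls) >= n_controls:
            break
        chunk = max(chunk // 2, 2000)
    else:  # pragma: no cover - pathological configs only
        raise CalibrationError(f"{study_id}: could not fill case/control quotas")

    g_cases = np.concatenate(cases)[:n_cases]
    g_controls = np.concatenate(controls)[:n_controls]
    dosage = np.concatenate([g_cases, g_controls]).astype(float)
    phenotype = np.concatenate([np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)])
    order = rng.permutation(len(phenotype))
    dosage = dosage[order]
    phenotype = phenotype[order]

    subjects = pd.DataFrame({
        "subject_id": [f"{study_id}_s{i + 1:05d}" for i in range(len(phenotype))],
        "phenotype": phenotype,
        "sex": 0,
    })
    pcs = _compute_pcs(dosage, cfg.n_pcs)
    panel = GenotypePanel(study_id, subjects, arch.variants.copy(), dosage, pcs)
    return panel, alpha, freqs


def simulate_multistudy(cfg: SimConfig):
    """Generate the per-study panels and the ground-truth record.

    Returns (list of :class:`GenotypePanel`, :class:`SimTruth`).  The
    variant map is identical across studies; allele frequencies get
    per-study jitter; each study draws from its own spawned RNG stream.
    """
    arch = _build_architecture(cfg)
    panels, alphas, freq_cols = [], {}, {}
    for s in range(cfg.n_studies):
        sid = f"study{s + 1}"
        seed = np.random.SeedSequence(cfg.seed, spawn_key=(1 + s,))
        panel, alpha, freqs = _simulate_panel(cfg, arch, seed, sid, cfg.n_cases, cfg.n_controls)
        panels.append(panel)
        alphas[sid] = alpha
        freq_cols[sid] = freqs

    ids = arch.variants["id"].to_numpy()
    truth = SimTruth(
        risk_loci=pd.DataFrame({
            "snp": ids[arch.risk_idx],
            "block": arch.block[arch.risk_idx],
            "beta_true": arch.beta[arch.risk_idx],
        }),
        resilience_loci=pd.DataFrame({
            "snp": ids[arch.res_idx],
            "block": arch.block[arch.res_idx],
            "gamma_true": arch.gamma[arch.res_idx],
        }),
        b_int=cfg.b_int,
        alpha=alphas,
        study_freqs=pd.DataFrame(freq_cols, index=ids),
        block=arch.block,
        seed=cfg.seed,
    )
    return panels, truth


def simulate_reference(cfg: SimConfig, n_subjects: int = 379) -> GenotypePanel:
    """An external LD reference panel drawn from the same variant architecture.

    Mirrors the role of the 1000 Genomes European reference (default n=379):
    unascertained subjects, same markers and LD structure, separate stream.
    """
    arch = _build_architecture(cfg)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(10_000,)))
    g = _draw_genotypes(rng, n_subjects, arch.freqs, arch.block, cfg.rho).astype(float)
    subjects = pd.DataFrame({
        "subject_id": [f"ref_s{i + 1:05d}" for i in range(n_subjects)],
        "phenotype": 0,
        "sex": 0,
    })
    return GenotypePanel("reference", subjects, arch.variants.copy(), g, None)


def synthetic_gene_table(variants: pd.DataFrame, block: np.ndarray) -> pd.DataFrame:
    """One synthetic gene per LD block, spanning the block's markers.

    A stand-in annotation for simulated data (there is no real genome here):
    gene_id GENE<block>, coordinates padded 1 kb beyond the outermost
    markers, biotype protein_coding.
    """
    rows = []
    for b in np.unique(block):
        sub = variants[block == b]
        rows.append((
            f"GENE{b:04d}", f"GENE{b:04d}", int(sub["chrom"].iloc[0]),
            max(int(sub["pos"].min()) - 1000, 1), int(sub["pos"].max()) + 1000,
            "protein_coding",
        ))
    return pd.DataFrame(rows, columns=["gene_id", "gene_name", "chrom", "start", "end", "biotype"])


# ---------------------------------------------------------------------------
# QC defect injection
# ---------------------------------------------------------------------------

#: Defect kinds understood by :func:`inject_qc_defects` and the metadata each writes.
DEFECT_KINDS = ("ambiguous", "indel", "low_info", "mhc", "chr8_inversion",
                "low_maf", "few_studies")


def inject_qc_defects(panel: GenotypePanel, spec: dict, seed: int = 0,
                      avoid=()):
    """Plant known QC defects into a panel's variant metadata.

    ``spec`` maps defect kind -> count, e.g. ``{"ambiguous": 7, "mhc": 5}``.
    Each defect lands on a distinct marker not in ``avoid``.  Returns
    (new panel, truth table of injected defects) so downstream filter
    assertions can check exact removal.
    """
    unknown = set(spec) - set(DEFECT_KINDS)
    if unknown:
        raise ValueError(f"unknown defect kind(s): {sorted(unknown)}")
    total = sum(spec.values())
    v = panel.variants.copy().reset_index(drop=True)
    eligible = v.index[~v["id"].isin(set(avoid))].to_numpy()
    if total > eligible.size:
        raise CapacityError(
            f"requested {total} defects but only {eligible.size} markers are available"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(eligible, size=total, replace=False)
    truth_rows = []
    k = 0
    for kind, count in spec.items():
        for _ in range(count):
            j = picked[k]
            k += 1
            if kind == "ambiguous":
                v.loc[j, ["a1", "a2"]] = ["A", "T"]
            elif kind == "indel":
                v.loc[j, ["a1", "a2"]] = ["AG", "A"]
            elif kind == "low_info":
                v.loc[j, "info"] = 0.85
            elif kind == "mhc":
                v.loc[j, "chrom"] = 6
                v.loc[j, "pos"] = int(rng.integers(25_000_000, 34_000_001))
            elif kind == "chr8_inversion":
                v.loc[j, "chrom"] = 8
                v.loc[j, "pos"] = int(rng.integers(7_000_000, 14_000_001))
            elif kind == "low_maf":
                v.loc[j, "maf"] = 0.02
            elif kind == "few_studies":
                v.loc[j, "n_studies"] = 10
            truth_rows.append((v.loc[j, "id"], kind))
    new_panel = GenotypePanel(panel.study_id, panel.subjects, v, panel.dosage, panel.pcs)
    return new_panel, pd.DataFrame(truth_rows, columns=["snp", "defect"])
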