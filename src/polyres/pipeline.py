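"""End-to-end orchestration: simulate -> risk GWAS -> meta -> PRS -> stratify ->
filter -> resilience GWAS -> score -> fit -> replicate -> analyze.

The discovery studies supply the risk meta-analysis, the PRS weights, the
resilient/matched strata, the risk-orthogonal variant set and the resilience
score model; each replication cohort is stratified with its own scores and
fitted with the discovery formulae; per-cohort fits are pooled by
inverse-variance fixed-effect meta-analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assoc import fixed_effect_meta, logistic_assoc
from .downstream import (
    decile_analysis,
    gene_enrichment_regression,
    gene_scores,
    group_correlations,
    interaction_model,
    ld_vs_assoc_correlation,
    map_snps_to_genes,
)
from .errors import DesignError
from .resilience import FitResult, ResilienceModel, fits_frame, replicate_meta
from .scoring import DEFAULT_BINS, build_score_model, compute_scores, standardize_within_study
from .simulate import SimConfig, simulate_multistudy, simulate_reference, synthetic_gene_table
from .stratify import (
    LdPanel,
    exclude_risk_linked,
    ld_clump,
    qc_filter,
    select_covariate_pcs,
    stratify_by_percentile,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline thresholds, at the defaults of the reference analysis.

    ``min_studies`` defaults to 11 (markers present in 10 or fewer studies
    are removed); simulated desk-scale runs must lower it to at most the
    number of simulated studies.
    """

    pct: float = 90.0
    risk_bin: float = 0.05        # p-value bin for the risk PRS
    risk_p: float = 0.05          # risk-association exclusion threshold
    ld_r2: float = 0.2            # r^2 threshold for risk-LD exclusion
    window_kb: float = 1000.0     # window for risk-LD exclusion
    clump_kb: float = 500.0
    clump_r2: float = 0.2
    clump_p1: float = 1.0
    clump_p2: float = 1.0
    info_min: float = 0.9
    maf_min: float = 0.05
    min_studies: int = 11
    bins: tuple = DEFAULT_BINS
    prevalence: float = 0.10      # K for the liability transform
    pc_alpha_discovery: float = 0.1
    pc_alpha_replication: float = 0.05
    n_pcs_assoc: int = 4          # PCs offered to the per-study GWAS
    n_pcs_interaction: int = 10
    analysis_bin: float = 0.3     # bin used for downstream score analyses
    seed: int = 0
    strict: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "bins" in raw:
            raw["bins"] = tuple(raw["bins"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bins"] = list(self.bins)
        return d


@dataclass
class StudyResult:
    """Everything one end-to-end run produces."""

    config: PipelineConfig
    sim: SimConfig | None
    risk_meta: object
    risk_score_model: object
    prs: pd.DataFrame                     # study_id, subject_id, phenotype, raw, z
    strata_discovery: object
    filter_report: object
    resilience_meta: object
    resilience_score_model: object
    discovery_fits: list
    replication_fits: dict                # cohort -> list[FitResult]
    replication_meta: pd.DataFrame | None
    strata_replication: dict              # cohort -> Strata
    analyses: dict = field(default_factory=dict)
    truth: object = None

    @property
    def discovery_table(self) -> pd.DataFrame:
        return fits_frame(self.discovery_fits)


def _prs_frame(panels, model, cutoff) -> pd.DataFrame:
    """Within-study standardized PRS for every subject of every panel."""
    frames = []
    for panel in panels:
        ss = standardize_within_study(compute_scores(panel, model, cutoff))
        frames.append(pd.DataFrame({
            "study_id": panel.study_id,
            "subject_id": ss.scores["subject_id"],
            "phenotype": panel.phenotype(),
            "raw": ss.raw,
            "z": ss.z,
        }))
    return pd.concat(frames, ignore_index=True)


def _strata_masks(panel, strata):
    """Boolean masks over a panel's subjects: (in strata, resilient)."""
    t = strata.table
    mine = t[t["study_id"] == panel.study_id]
    res = set(mine.loc[mine["group"] == "resilient_control", "subject_id"])
    mat = set(mine.loc[mine["group"] == "matched_case", "subject_id"])
    sid = panel.subjects["subject_id"]
    in_strata = sid.isin(res | mat).to_numpy()
    resilient = sid.isin(res).to_numpy()
    return in_strata, resilient


def _resilience_scan(panel, strata, alpha):
    """Resilient-vs-matched GWAS within one study, with screened PC covariates."""
    in_strata, resilient = _strata_masks(panel, strata)
    if in_strata.sum() == 0 or resilient[in_strata].all() or not resilient[in_strata].any():
        return None, []
    pcs_sel = []
    if panel.pcs is not None:
        try:
            pcs_sel = select_covariate_pcs(
                panel.pcs, resilient & in_strata, in_strata & ~resilient, alpha)
        except ValueError:
            pcs_sel = []
    tab = logistic_assoc(panel, covariate_ids=pcs_sel,
                         outcome=resilient.astype(int), subset=in_strata)
    return tab, pcs_sel


def _score_z_for(panel, model, cutoff):
    ss = standardize_within_study(compute_scores(panel, model, cutoff))
    return pd.Series(ss.z, index=panel.subjects["subject_id"].to_numpy())


def _fit_cohort_bins(panels, strata, model, bins, alpha, prevalence, cohort_name):
    """Per-bin resilience fits over the pooled strata of one or more panels."""
    rows = {}
    for panel in panels:
        in_strata, resilient = _strata_masks(panel, strata)
        rows[panel.study_id] = (panel, in_strata, resilient)

    # pooled PC screening: stack per-study PCs (shared column meaning at desk scale)
    pcs_blocks, res_flags = [], []
    for panel, in_strata, resilient in rows.values():
        if panel.pcs is None:
            pcs_blocks = None
            break
        pcs_blocks.append(panel.pcs[in_strata])
        res_flags.append(resilient[in_strata])
    pcs_sel, pcs_stack, flags = [], None, None
    if pcs_blocks:
        pcs_stack = np.vstack(pcs_blocks)
        flags = np.concatenate(res_flags)
        try:
            pcs_sel = select_covariate_pcs(pcs_stack, flags, ~flags, alpha)
        except ValueError:
            pcs_sel = []

    fits = []
    for cutoff in bins:
        zs, ys = [], []
        for panel, in_strata, resilient in rows.values():
            try:
                z = _score_z_for(panel, model, cutoff).to_numpy()
            except Exception:
                z = None
            if z is None:
                continue
            zs.append(z[in_strata])
            ys.append(resilient[in_strata])
        if not zs:
            fits.append(FitResult(cohort_name, cutoff, *([np.nan] * 7), 0, 0,
                                  status="empty_bin"))
            continue
        z = np.concatenate(zs)
        y = np.concatenate(ys)
        if np.ptp(z) == 0:
            fits.append(FitResult(cohort_name, cutoff, *([np.nan] * 7),
                                  int(y.sum()), int((~y.astype(bool)).sum()),
                                  status="empty_bin"))
            continue
        pcs_use = pcs_stack[:, pcs_sel] if (pcs_stack is not None and pcs_sel) else None
        fit = ResilienceModel(y.astype(int), z, pcs=pcs_use, cutoff=cutoff,
                              cohort=cohort_name, prevalence=prevalence).fit()
        fits.append(fit)
    return fits


def run_simulated_study(sim: SimConfig, cfg: PipelineConfig | None = None,
                        n_discovery: int = 2, n_reference: int = 379,
                        analyses: bool = True) -> StudyResult:
    """Run the full pipeline on a simulated multi-study data set.

    ``n_discovery`` panels form the discovery set; the remainder are
    replication cohorts.  The LD reference panel is drawn from the same
    variant architecture.  When the config still carries the real-data
    default ``min_studies`` larger than the simulated study count it is
    capped with a log note (otherwise every simulated marker would fail the
    study-support filter).
    """
    cfg = cfg or PipelineConfig()
    if cfg.min_studies > sim.n_studies:
        log.info("capping min_studies=%d at the simulated study count %d",
                 cfg.min_studies, sim.n_studies)
        cfg = PipelineConfig(**{**cfg.to_dict(), "min_studies": 1,
                                "bins": tuple(cfg.bins)})
    if not 1 <= n_discovery <= sim.n_studies:
        raise ValueError("n_discovery must lie in [1, n_studies]")

    panels, truth = simulate_multistudy(sim)
    reference = simulate_reference(sim, n_reference)
    ld = LdPanel(reference)
    discovery = panels[:n_discovery]
    replication = panels[n_discovery:]

    # 1) risk GWAS and meta over the discovery studies
    risk_tabs = [logistic_assoc(p, covariate_ids=tuple(range(cfg.n_pcs_assoc)))
                 for p in discovery]
    risk_meta = fixed_effect_meta(risk_tabs, study_ids=[p.study_id for p in discovery])

    # 2) risk PRS: clumped discovery meta, weights at the risk bin
    risk_idx = ld_clump(risk_meta.table, ld, kb=cfg.clump_kb, r2=cfg.clump_r2,
                        p1=cfg.clump_p1, p2=cfg.clump_p2)
    risk_model = build_score_model(
        risk_meta.table[risk_meta.table["snp"].isin(risk_idx)],
        bins=(cfg.risk_bin,), provenance="risk")
    prs = _prs_frame(panels, risk_model, cfg.risk_bin)

    # 3) stratify the pooled discovery sample at the control percentile
    disc_ids = {p.study_id for p in discovery}
    strata_d = stratify_by_percentile(
        prs[prs["study_id"].isin(disc_ids)].reset_index(drop=True), cfg.pct)

    # 4) resilient-vs-matched GWAS per discovery study, pooled
    res_tabs = []
    for p in discovery:
        tab, _sel = _resilience_scan(p, strata_d, cfg.pc_alpha_discovery)
        if tab is not None:
            res_tabs.append((p.study_id, tab))
    if not res_tabs:
        raise DesignError("no discovery study produced usable strata")
    res_meta = fixed_effect_meta([t for _s, t in res_tabs],
                                 study_ids=[s for s, _t in res_tabs])

    # 5) risk-orthogonal filtering and clumping of the resilience scan
    surv, rep1 = exclude_risk_linked(res_meta.table, risk_meta, ld,
                                     p_thresh=cfg.risk_p, r2_thresh=cfg.ld_r2,
                                     window_kb=cfg.window_kb, strict=cfg.strict)
    meta_support = res_meta.table[["snp", "n_studies"]].rename(
        columns={"n_studies": "meta_support"})
    vmeta = panels[0].variants.rename(columns={"id": "snp"})[
        ["snp", "chrom", "pos", "a1", "a2", "maf", "info", "n_studies"]]
    cand_meta = surv[["snp"]].merge(vmeta, on="snp").merge(meta_support, on="snp")
    surv2, rep2 = qc_filter(cand_meta, info_min=cfg.info_min, maf_min=cfg.maf_min,
                            min_studies=cfg.min_studies)
    report = rep1.merge(rep2)
    kept = res_meta.table[res_meta.table["snp"].isin(surv2["snp"])]
    clumped = ld_clump(kept, ld, kb=cfg.clump_kb, r2=cfg.clump_r2,
                       p1=cfg.clump_p1, p2=cfg.clump_p2)
    from .stratify import FilterReport
    rep3 = FilterReport(
        n_input=len(kept),
        removed={"clump_pruned": len(kept) - len(clumped)},
        removed_ids={"clump_pruned": sorted(set(kept["snp"]) - set(clumped))},
        survivors=list(clumped),
    )
    report = report.merge(rep3)

    res_model = build_score_model(res_meta.table[res_meta.table["snp"].isin(clumped)],
                                  bins=cfg.bins, provenance="resilience")

    # 6) discovery per-bin fits
    discovery_fits = _fit_cohort_bins(discovery, strata_d, res_model, cfg.bins,
                                      cfg.pc_alpha_discovery, cfg.prevalence, "discovery")

    # 7) replication: per-cohort stratification, fits, pooled meta
    replication_fits, strata_r = {}, {}
    for p in replication:
        sub = prs[prs["study_id"] == p.study_id].reset_index(drop=True)
        try:
            strata_c = stratify_by_percentile(sub, cfg.pct)
        except Exception as exc:
            log.warning("%s: replication stratification failed (%s)", p.study_id, exc)
            continue
        strata_r[p.study_id] = strata_c
        replication_fits[p.study_id] = _fit_cohort_bins(
            [p], strata_c, res_model, cfg.bins,
            cfg.pc_alpha_replication, cfg.prevalence, p.study_id)
    repl_meta = None
    if replication_fits:
        import warnings as _warnings
        with _warnings.catch_warnings():
            # a single replication cohort is a legitimate design here
            _warnings.simplefilter("ignore", UserWarning)
            repl_meta = replicate_meta(replication_fits)

    result = StudyResult(
        config=cfg, sim=sim, risk_meta=risk_meta, risk_score_model=risk_model,
        prs=prs, strata_discovery=strata_d, filter_report=report,
        resilience_meta=res_meta, resilience_score_model=res_model,
        discovery_fits=discovery_fits, replication_fits=replication_fits,
        replication_meta=repl_meta, strata_replication=strata_r, truth=truth,
    )

    if analyses:
        target = replication[0] if replication else discovery[0]
        strata_t = strata_r.get(target.study_id, strata_d)
        result.analyses = run_downstream(target, prs, res_model, strata_t,
                                         risk_meta, res_meta, ld, cfg, truth)
    return result


def run_downstream(panel, prs, res_model, strata, risk_meta, res_meta, ld, cfg,
                   truth=None) -> dict:
    """Correlation / interaction / decile / LD-diagnostic / gene analyses on one cohort."""
    sub = prs[prs["study_id"] == panel.study_id].set_index("subject_id")
    sid = panel.subjects["subject_id"].to_numpy()
    risk_z = sub.loc[sid, "z"].to_numpy()
    y = panel.phenotype()
    res_z = _score_z_for(panel, res_model, cfg.analysis_bin).to_numpy()
    ultra = {s for (_st, s) in strata.ultra_high_cases}
    keep = ~pd.Series(sid).isin(ultra).to_numpy()

    pcs = panel.pcs[:, :cfg.n_pcs_interaction] if panel.pcs is not None else None
    out = {}
    out["correlations"] = group_correlations(risk_z, res_z, y, strata=strata,
                                             exclude=~keep)
    out["interaction"] = interaction_model(
        risk_z[keep], res_z[keep], y[keep],
        pcs=pcs[keep] if pcs is not None else None)
    try:
        out["deciles"] = decile_analysis(risk_z[keep], y[keep], res_z[keep],
                                         pcs=pcs[keep] if pcs is not None else None)
    except DesignError as exc:
        out["deciles"] = None
        log.warning("decile analysis skipped: %s", exc)
    risk_hits = risk_meta.table[risk_meta.table["p"] < cfg.risk_p][["snp", "chrom", "pos"]]
    scored = set().union(*(set(res_model.entries[c]["snp"]) for c in res_model.bins))
    res_tab = res_meta.table[res_meta.table["snp"].isin(scored)]
    if len(risk_hits) and len(res_tab):
        out["ld_vs_assoc"] = ld_vs_assoc_correlation(res_tab, risk_hits, ld,
                                                     window_kb=cfg.window_kb)
    else:
        out["ld_vs_assoc"] = (np.nan, np.nan)

    if truth is not None:
        genes = synthetic_gene_table(panel.variants, truth.block)
        assign = map_snps_to_genes(panel.variants, genes)
        gtab = gene_scores(assign, risk_meta.table, res_meta.table, genes,
                           risk_p_max=cfg.risk_p)
        try:
            beta, se, p, _res = gene_enrichment_regression(gtab)
            out["gene_enrichment"] = {"beta": beta, "robust_se": se, "p": p}
        except DesignError as exc:
            out["gene_enrichment"] = None
            log.warning("gene enrichment skipped: %s", exc)
        out["gene_table"] = gtab
    return out


# ---------------------------------------------------------------------------
# On-disk runs
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(sim: SimConfig, cfg: PipelineConfig, out_dir,
                 n_discovery: int = 2) -> Path:
    """Run the simulated pipeline and write stage TSVs, a manifest and logs.

    Rerunning with the same config and seed is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = run_simulated_study(sim, cfg, n_discovery=n_discovery, analyses=True)

    from .io import write_sumstats
    write_sumstats(result.risk_meta.table, out / "risk_meta.tsv")
    write_sumstats(result.resilience_meta.table, out / "resilience_meta.tsv")
    result.prs.to_csv(out / "prs.tsv", sep="\t", index=False, float_format="%.10g")
    result.strata_discovery.table.to_csv(out / "strata_discovery.tsv", sep="\t",
                                         index=False, float_format="%.10g")
    result.filter_report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
    fits_frame(result.discovery_fits).to_csv(out / "discovery_fits.tsv", sep="\t",
                                             index=False, float_format="%.10g")
    for cohort, fits in result.replication_fits.items():
        fits_frame(fits).to_csv(out / f"replication_{cohort}.tsv", sep="\t",
                                index=False, float_format="%.10g")
    if result.replication_meta is not None:
        result.replication_meta.to_csv(out / "replication_meta.tsv", sep="\t",
                                       index=False, float_format="%.10g")
    if result.analyses:
        result.analyses["correlations"].to_csv(out / "correlations.tsv", sep="\t",
                                               index=False, float_format="%.10g")
        result.analyses["interaction"].to_csv(out / "interaction.tsv", sep="\t",
                                              float_format="%.10g")
        if result.analyses.get("deciles") is not None:
            result.analyses["deciles"].to_csv(out / "deciles.tsv", sep="\t",
                                              index=False, float_format="%.10g")

    counts = result.strata_discovery.counts().to_dict()
    log.info("strata sizes: %s", counts)
    for rule, c in result.filter_report.removed.items():
        log.info("filter %-18s removed %d", rule, c)

    manifest = {
        "seed": sim.seed,
        "sim_config": asdict(sim),
        "pipeline_config": result.config.to_dict(),
        "strata_counts": {str(k): int(v) for k, v in counts.items()},
        "lambda_gc_resilience": result.resilience_meta.lambda_gc,
        "outputs": {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))},
    }
    manifest["sim_config"]["maf_range"] = list(sim.maf_range)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
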