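"""Percentile-based risk stratification and risk-orthogonal variant filtering.

Stratification: the 90th percentile of the (pooled, within-study
standardized) polygenic risk score among controls defines "resilient"
controls; cases between that threshold and the control maximum are the
risk-matched comparison group; cases above the control maximum are
ultra-high-risk and set aside.

Filtering: candidate resilience variants are purged of anything associated
with risk (p < 0.05) or in LD with such a variant (r^2 > 0.2 within 1 Mb),
then of MHC / chr8-inversion / low-INFO / strand-ambiguous / indel /
low-MAF / low-study-support markers, and finally LD-clumped.  Every removal
is attributed to the first rule that fires, in a fixed order, so filter
reports reconcile exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StrataError
from .io import GenotypePanel, is_ambiguous_pair

log = logging.getLogger(__name__)

#: Region masks excluded from scoring: (name, chrom, start, end), 1-based inclusive.
DEFAULT_REGIONS = (
    ("mhc", 6, 25_000_000, 34_000_000),
    ("chr8_inversion", 8, 7_000_000, 14_000_000),
)

#: Fixed rule-attribution order for merged filter reports.
RULE_ORDER = (
    "risk_p", "ld_with_risk", "mhc", "chr8_inversion", "low_info",
    "ambiguous_or_indel", "low_maf", "few_studies", "clump_pruned",
)


@dataclass
class FilterReport:
    """Removal counts per rule plus the surviving variant ids."""

    n_input: int
    removed: dict = field(default_factory=dict)        # rule -> count
    removed_ids: dict = field(default_factory=dict)    # rule -> list of snp ids
    survivors: list = field(default_factory=list)

    def audit(self) -> bool:
        """Removals + survivors must reconcile exactly with the input count."""
        total = sum(self.removed.values()) + len(self.survivors)
        if total != self.n_input:
            raise AssertionError(
                f"filter audit failed: {sum(self.removed.values())} removed + "
                f"{len(self.survivors)} surviving != {self.n_input} input"
            )
        return True

    def merge(self, other: "FilterReport") -> "FilterReport":
        """Chain a report applied to this report's survivors."""
        if other.n_input != len(self.survivors):
            raise ValueError("chained report does not start from these survivors")
        removed = dict(self.removed)
        removed_ids = {k: list(v) for k, v in self.removed_ids.items()}
        for k, c in other.removed.items():
            removed[k] = removed.get(k, 0) + c
            removed_ids.setdefault(k, []).extend(other.removed_ids.get(k, []))
        merged = FilterReport(self.n_input, removed, removed_ids, list(other.survivors))
        merged.audit()
        return merged

    def to_frame(self) -> pd.DataFrame:
        rows = [(r, self.removed.get(r, 0)) for r in RULE_ORDER if r in self.removed]
        rows += [(r, c) for r, c in self.removed.items() if r not in RULE_ORDER]
        rows.append(("surviving", len(self.survivors)))
        return pd.DataFrame(rows, columns=["rule", "count"])


@dataclass
class Strata:
    """Partition of a cohort by standardized PRS.

    ``table`` has one row per subject with columns study_id, subject_id,
    phenotype, z and group in {resilient_control, matched_case,
    ultra_high_case, below_threshold}.
    """

    threshold: float
    max_control: float
    table: pd.DataFrame

    def ids(self, group: str) -> set:
        sub = self.table[self.table["group"] == group]
        return set(zip(sub["study_id"], sub["subject_id"]))

    @property
    def resilient_controls(self) -> set:
        return self.ids("resilient_control")

    @property
    def matched_cases(self) -> set:
        return self.ids("matched_case")

    @property
    def ultra_high_cases(self) -> set:
        return self.ids("ultra_high_case")

    @property
    def below_threshold(self) -> set:
        return self.ids("below_threshold")

    def counts(self) -> pd.Series:
        return self.table["group"].value_counts()

    def check_partition(self) -> bool:
        groups = [self.resilient_controls, self.matched_cases,
                  self.ultra_high_cases, self.below_threshold]
        total = sum(len(g) for g in groups)
        union = set().union(*groups)
        if total != len(self.table) or len(union) != len(self.table):
            raise AssertionError("strata do not partition the cohort")
        return True


def stratify_by_percentile(scores: pd.DataFrame, pct: float = 90.0) -> Strata:
    """Stratify subjects by standardized PRS at the control ``pct`` percentile.

    ``scores`` needs columns study_id, subject_id, phenotype (0/1) and z.
    The threshold is the empirical linear-interpolation quantile of control
    scores; case-window boundaries are inclusive on both ends.
    """
    required = {"study_id", "subject_id", "phenotype", "z"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores must have columns {sorted(required)}")
    ph = scores["phenotype"].to_numpy()
    if not (ph == 0).any() or not (ph == 1).any():
        raise StrataError("both cases and controls are required for stratification")

    control_z = scores.loc[ph == 0, "z"].to_numpy()
    threshold = float(np.quantile(control_z, pct / 100.0))  # linear interpolation
    max_control = float(control_z.max())

    z = scores["z"].to_numpy()
    group = np.empty(len(scores), dtype=object)
    is_case = ph == 1
    group[(~is_case) & (z >= threshold)] = "resilient_control"
    group[(~is_case) & (z < threshold)] = "below_threshold"
    group[is_case & (z >= threshold) & (z <= max_control)] = "matched_case"
    group[is_case & (z > max_control)] = "ultra_high_case"
    group[is_case & (z < threshold)] = "below_threshold"

    table = scores[["study_id", "subject_id", "phenotype", "z"]].copy()
    table["group"] = group
    strata = Strata(threshold, max_control, table)
    if not (group == "resilient_control").any():
        raise StrataError("degenerate strata: no control at or above the threshold")
    strata.check_partition()
    return strata


def select_covariate_pcs(pcs: np.ndarray, group1: np.ndarray, group2: np.ndarray,
                         alpha: float = 0.1) -> list:
    """Indices of PC columns that differ between two groups (Welch t, p < alpha).

    ``group1`` / ``group2`` are row indices or boolean masks (e.g. resilient
    controls vs matched cases).  Order of the original columns is preserved.
    """
    pcs = np.asarray(pcs, dtype=float)
    a = pcs[group1]
    b = pcs[group2]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group for the PC difference test")
    selected = []
    for j in range(pcs.shape[1]):
        if np.ptp(a[:, j]) == 0 and np.ptp(b[:, j]) == 0:
            continue
        p = stats.ttest_ind(a[:, j], b[:, j], equal_var=False).pvalue
        if p < alpha:
            selected.append(j)
    return selected


# ---------------------------------------------------------------------------
# LD helpers
# ---------------------------------------------------------------------------

class LdPanel:
    """Standardized-dosage cache over a reference panel for r^2 queries."""

    def __init__(self, panel: GenotypePanel):
        D = panel.dosage.astype(float, copy=True)
        nan = np.isnan(D)
        if nan.any():
            colmean = np.nanmean(D, axis=0)
            D[nan] = np.broadcast_to(colmean, D.shape)[nan]
        mu = D.mean(axis=0)
        sd = D.std(axis=0)
        sd[sd == 0] = np.nan  # monomorphic: r^2 undefined -> treated as 0
        self._Z = (D - mu) / sd
        self._n = D.shape[0]
        v = panel.variants
        self._col = {snp: j for j, snp in enumerate(v["id"].to_numpy())}
        self.chrom = v["chrom"].to_numpy()
        self.pos = v["pos"].to_numpy()

    def has(self, snp: str) -> bool:
        return snp in self._col

    def r2(self, snp_a: str, snps_b) -> np.ndarray:
        """Squared Pearson dosage correlation of snp_a with each of snps_b."""
        ja = self._col[snp_a]
        jb = np.array([self._col[s] for s in snps_b], dtype=int)
        r = (self._Z[:, jb].T @ self._Z[:, ja]) / self._n
        return np.nan_to_num(r ** 2)

    def r2_matrix(self, snps_a, snps_b) -> np.ndarray:
        """r^2 between two id lists (len(a) x len(b))."""
        ja = np.array([self._col[s] for s in snps_a], dtype=int)
        jb = np.array([self._col[s] for s in snps_b], dtype=int)
        r = (self._Z[:, ja].T @ self._Z[:, jb]) / self._n
        return np.nan_to_num(r ** 2)


def max_r2_to_risk(candidates: pd.DataFrame, risk_hits: pd.DataFrame, ld: LdPanel,
                   window_kb: float = 1000.0) -> pd.Series:
    """Max r^2 of each candidate to any risk hit within +/- window_kb.

    Candidates with no risk hit in the window (or absent from the LD panel)
    get 0; pairing a candidate with itself is ignored.
    """
    window = window_kb * 1000.0
    orig_index = candidates.index
    candidates = candidates.reset_index(drop=True)
    out = np.zeros(len(candidates))
    hits_by_chrom = {c: g for c, g in risk_hits.groupby("chrom")}
    cand_pos = candidates["pos"].to_numpy()
    cand_snp = candidates["snp"].to_numpy()
    for chrom, rows in candidates.groupby("chrom"):
        hits = hits_by_chrom.get(chrom)
        if hits is None:
            continue
        hsnp = np.array([s for s in hits["snp"] if ld.has(s)])
        if hsnp.size == 0:
            continue
        hpos = hits.set_index("snp").loc[hsnp, "pos"].to_numpy()
        ii = np.asarray(rows.index)
        usable = np.array([ld.has(s) for s in cand_snp[ii]])
        ii = ii[usable]
        if ii.size == 0:
            continue
        r2 = ld.r2_matrix(cand_snp[ii], hsnp)
        in_window = np.abs(cand_pos[ii][:, None] - hpos[None, :]) <= window
        not_self = cand_snp[ii][:, None] != hsnp[None, :]
        r2 = np.where(in_window & not_self, r2, 0.0)
        out[ii] = r2.max(axis=1) if r2.shape[1] else 0.0
    return pd.Series(out, index=orig_index)


def exclude_risk_linked(
    candidates: pd.DataFrame,
    risk_meta,
    ld_panel,
    p_thresh: float = 0.05,
    r2_thresh: float = 0.2,
    window_kb: float = 1000.0,
    strict: bool = False,
):
    """Discard candidates associated with risk or in LD with a risk variant.

    A candidate is removed iff its risk meta p < ``p_thresh`` (rule
    ``risk_p``) or some risk variant with p < ``p_thresh`` within
    +/- ``window_kb`` has squared dosage correlation > ``r2_thresh`` with it
    (rule ``ld_with_risk``).  Candidates absent from the LD panel raise in
    strict mode and are retained with a warning otherwise.

    Returns (survivors DataFrame, FilterReport).
    """
    risk_table = risk_meta.table if hasattr(risk_meta, "table") else risk_meta
    ld = ld_panel if isinstance(ld_panel, LdPanel) else LdPanel(ld_panel)

    cand = candidates.reset_index(drop=True)
    risk_p = cand[["snp"]].merge(
        risk_table[["snp", "p"]].rename(columns={"p": "risk_p"}), on="snp", how="left"
    )["risk_p"]
    rule_risk = (risk_p < p_thresh).to_numpy()

    missing_ld = [s for s in cand["snp"] if not ld.has(s)]
    if missing_ld:
        msg = f"{len(missing_ld)} candidate(s) absent from the LD panel (e.g. {missing_ld[:3]})"
        if strict:
            raise KeyError(msg)
        log.warning("%s; retained without an LD check", msg)

    risk_hits = risk_table[risk_table["p"] < p_thresh][["snp", "chrom", "pos"]]
    remaining = cand[~rule_risk]
    r2max = max_r2_to_risk(remaining, risk_hits, ld, window_kb)
    rule_ld = np.zeros(len(cand), dtype=bool)
    rule_ld[remaining.index] = (r2max > r2_thresh).to_numpy()

    report = FilterReport(
        n_input=len(cand),
        removed={"risk_p": int(rule_risk.sum()), "ld_with_risk": int(rule_ld.sum())},
        removed_ids={
            "risk_p": cand.loc[rule_risk, "snp"].tolist(),
            "ld_with_risk": cand.loc[rule_ld, "snp"].tolist(),
        },
        survivors=cand.loc[~rule_risk & ~rule_ld, "snp"].tolist(),
    )
    report.audit()
    return cand[~rule_risk & ~rule_ld].reset_index(drop=True), report


def qc_filter(
    variants: pd.DataFrame,
    regions=DEFAULT_REGIONS,
    info_min: float = 0.9,
    maf_min: float = 0.05,
    min_studies: int = 11,
):
    """Marker QC: region masks, imputation quality, ambiguity/indels, MAF, study support.

    Removal rules in attribution order: each region (bounds inclusive), then
    INFO < ``info_min`` (so INFO = 0.9 is retained), strand-ambiguous A/T-C/G
    or indel alleles, MAF < ``maf_min``, and support below ``min_studies``
    (the default 11 removes markers present in 10 or fewer studies).

    ``variants`` needs columns id (or snp), chrom, pos, a1, a2, maf, info,
    n_studies.  Returns (survivors DataFrame, FilterReport).
    """
    v = variants.reset_index(drop=True)
    idcol = "id" if "id" in v.columns else "snp"
    removed_by = np.full(len(v), "", dtype=object)

    def mark(mask, rule):
        fresh = mask.to_numpy() if hasattr(mask, "to_numpy") else np.asarray(mask)
        fresh = fresh & (removed_by == "")
        removed_by[fresh] = rule

    for name, chrom, start, end in regions:
        mark((v["chrom"] == chrom) & (v["pos"] >= start) & (v["pos"] <= end), name)
    mark(v["info"] < info_min, "low_info")
    amb = np.array([
        is_ambiguous_pair(a1, a2) or len(a1) != 1 or len(a2) != 1
        or a1 not in "ACGT" or a2 not in "ACGT"
        for a1, a2 in zip(v["a1"], v["a2"])
    ])
    mark(amb, "ambiguous_or_indel")
    mark(v["maf"] < maf_min, "low_maf")
    mark(v["n_studies"] < min_studies, "few_studies")

    rules = [r for r in RULE_ORDER if (removed_by == r).any()]
    report = FilterReport(
        n_input=len(v),
        removed={r: int((removed_by == r).sum()) for r in rules},
        removed_ids={r: v.loc[removed_by == r, idcol].tolist() for r in rules},
        survivors=v.loc[removed_by == "", idcol].tolist(),
    )
    report.audit()
    return v[removed_by == ""].reset_index(drop=True), report


def ld_clump(
    assoc: pd.DataFrame,
    ld_panel,
    kb: float = 500.0,
    r2: float = 0.2,
    p1: float = 1.0,
    p2: float = 1.0,
) -> list:
    """Greedy LD clumping: returns the index-variant ids.

    Repeatedly take the smallest-p unclaimed variant with p <= ``p1`` as an
    index and claim every unclaimed variant with p <= ``p2`` within
    +/- ``kb`` whose r^2 with the index exceeds ``r2``.  Ties break
    deterministically by (p, chrom, pos, id).  Variants absent from the LD
    panel cannot be claimed and become their own indices.
    """
    ld = ld_panel if isinstance(ld_panel, LdPanel) else LdPanel(ld_panel)
    t = assoc[np.isfinite(assoc["p"])]
    t = t.sort_values(["p", "chrom", "pos", "snp"], kind="mergesort").reset_index(drop=True)
    window = kb * 1000.0

    claimed = np.zeros(len(t), dtype=bool)
    indices = []
    snp = t["snp"].to_numpy()
    chrom = t["chrom"].to_numpy()
    pos = t["pos"].to_numpy()
    p = t["p"].to_numpy()
    for i in range(len(t)):
        if claimed[i] or p[i] > p1:
            continue
        indices.append(snp[i])
        claimed[i] = True
        if not ld.has(snp[i]):
            continue
        near = np.flatnonzero(
            (~claimed) & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window) & (p <= p2)
        )
        if near.size == 0:
            continue
        usable = np.array([ld.has(s) for s in snp[near]])
        near = near[usable]
        if near.size == 0:
            continue
        r2v = ld.r2(snp[i], snp[near])
        claimed[near[r2v > r2]] = True
    return indices
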