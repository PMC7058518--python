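"""Polygenic scores from p-value-binned weight models, with within-study z-scaling.

A :class:`ScoreModel` maps each p-value cutoff to the set of (variant, effect
allele, weight = ln OR) entries with meta p below the cutoff, so bins are
nested by construction.  A subject's raw score is the weighted sum of
effect-allele dosages after allele harmonization; scores are then z-scaled
within each study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import CoverageError, StandardizationError
from .io import complement_allele

#: The ten p-value cutoffs used for score construction.
DEFAULT_BINS = (0.0001, 0.001, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0)


@dataclass
class ScoreModel:
    """Ordered p-value bins and per-bin scoring entries (snp, a1, weight)."""

    bins: tuple
    entries: dict            # cutoff -> DataFrame[snp, a1, weight]
    provenance: str = ""

    def for_bin(self, cutoff: float) -> pd.DataFrame:
        if cutoff not in self.entries:
            raise KeyError(f"no score bin at cutoff {cutoff}; have {sorted(self.entries)}")
        return self.entries[cutoff]

    def counts(self) -> pd.Series:
        return pd.Series({c: len(self.entries[c]) for c in self.bins})


def build_score_model(meta_table: pd.DataFrame, bins=DEFAULT_BINS, provenance: str = "") -> ScoreModel:
    """Build a score model from a pooled association table.

    Each bin holds every variant with p < cutoff; the weight is the pooled
    beta (ln OR) for its effect allele a1.  Empty bins are permitted.
    """
    bins = tuple(sorted(bins))
    if len(set(bins)) != len(bins):
        raise ValueError("bins must be strictly increasing")
    t = meta_table[np.isfinite(meta_table["beta"])]
    entries = {}
    for cutoff in bins:
        sel = t[t["p"] < cutoff]
        entries[cutoff] = pd.DataFrame({
            "snp": sel["snp"].to_numpy(),
            "a1": sel["a1"].to_numpy(),
            "weight": sel["beta"].to_numpy(),
        })
    return ScoreModel(bins, entries, provenance)


@dataclass
class ScoreSet:
    """Per-subject scores for one study at one p-value cutoff."""

    study_id: str
    cutoff: float
    scores: pd.DataFrame     # subject_id, raw[, z]
    n_variants_used: int
    n_variants_missing: int

    @property
    def raw(self) -> np.ndarray:
        return self.scores["raw"].to_numpy()

    @property
    def z(self) -> np.ndarray:
        if "z" not in self.scores:
            raise KeyError("scores not yet standardized; call standardize_within_study")
        return self.scores["z"].to_numpy()


def compute_scores(
    panel,
    model: ScoreModel,
    cutoff: float,
    missing_policy: str = "impute",
) -> ScoreSet:
    """Raw polygenic score per subject: sum over bin entries of weight x
    effect-allele dosage.

    The effect allele is harmonized to the panel (swapped alleles score
    2 - dosage; unambiguous strand flips are complemented).  Missing dosages
    are mean-imputed from the panel's observed allele frequency (the common
    scoring default) unless ``missing_policy='strict'``, which raises
    instead.  Model variants absent from (or irreconcilable with) the panel
    are skipped and counted in ``n_variants_missing``; losing more than half
    of the model raises under strict mode and warns otherwise.
    """
    if missing_policy not in ("impute", "strict"):
        raise ValueError("missing_policy must be 'impute' or 'strict'")
    entries = model.for_bin(cutoff)
    n = panel.n_subjects
    if len(entries) == 0:
        scores = pd.DataFrame({"subject_id": panel.subjects["subject_id"], "raw": np.zeros(n)})
        return ScoreSet(panel.study_id, cutoff, scores, 0, 0)

    pv = panel.variants.reset_index(drop=True)
    pv_idx = pd.Series(pv.index, index=pv["id"])
    cols, flips, wts = [], [], []
    n_missing = 0
    for snp, a1, wt in zip(entries["snp"], entries["a1"], entries["weight"]):
        j = pv_idx.get(snp)
        if j is None:
            n_missing += 1
            continue
        pa1, pa2 = pv.at[j, "a1"], pv.at[j, "a2"]
        if a1 == pa1 or complement_allele(a1) == pa1:
            cols.append(j); flips.append(False); wts.append(wt)
        elif a1 == pa2 or complement_allele(a1) == pa2:
            cols.append(j); flips.append(True); wts.append(wt)
        else:
            n_missing += 1
    cols = np.array(cols, dtype=int)
    flips = np.array(flips, dtype=bool)
    wts = np.array(wts, dtype=float)

    frac_missing = n_missing / len(entries)
    if frac_missing > 0.5:
        msg = (f"{panel.study_id}: {n_missing}/{len(entries)} score-model variants "
               f"missing from the panel at cutoff {cutoff}")
        if missing_policy == "strict":
            raise CoverageError(msg)
        warnings.warn(msg, stacklevel=2)

    if cols.size == 0:
        scores = pd.DataFrame({"subject_id": panel.subjects["subject_id"], "raw": np.zeros(n)})
        return ScoreSet(panel.study_id, cutoff, scores, 0, n_missing)

    D = panel.dosage[:, cols].astype(float, copy=True)
    nan = np.isnan(D)
    if nan.any():
        if missing_policy == "strict":
            raise CoverageError(f"{panel.study_id}: missing dosages under strict scoring")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            colmean = np.nanmean(D, axis=0)
        colmean = np.where(np.isnan(colmean), 1.0, colmean)  # fully-missing column -> dosage 1
        D[nan] = np.broadcast_to(colmean, D.shape)[nan]
    D[:, flips] = 2.0 - D[:, flips]
    raw = D @ wts
    scores = pd.DataFrame({"subject_id": panel.subjects["subject_id"], "raw": raw})
    return ScoreSet(panel.study_id, cutoff, scores, int(cols.size), int(n_missing))


def standardize_within_study(scoreset: ScoreSet) -> ScoreSet:
    """z-scale raw scores within the study (mean 0, SD 1 with n-1 denominator)."""
    raw = scoreset.raw
    if raw.size < 2:
        raise StandardizationError("need at least 2 subjects to standardize")
    sd = raw.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise StandardizationError(
            f"{scoreset.study_id}: constant scores at cutoff {scoreset.cutoff}; cannot z-scale"
        )
    scores = scoreset.scores.copy()
    scores["z"] = (raw - raw.mean()) / sd
    return replace(scoreset, scores=scores)
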