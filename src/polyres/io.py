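"""Readers/writers for PLINK1 panels, summary statistics, score files and GTF gene annotations.

Conventions
-----------
* Coordinates are 1-based and inclusive everywhere (the native convention of
  PLINK ``.bim`` and GTF); any half-open arithmetic is internal.
* In a ``.bim`` file allele 1 (A1) is the counted allele; in summary
  statistics A1 is the effect allele.  Harmonization between a score model
  and a panel happens at scoring time, never here.
* Missing dosages are carried explicitly as NaN; imputation is a
  scoring-time decision.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GtfParseError, PlinkFormatError, SchemaError

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Gene biotypes retained by default: protein-coding, the small non-coding
#: RNA classes, lincRNA and antisense genes.  Pseudogenes and anything not
#: listed are dropped.
DEFAULT_BIOTYPES = frozenset(
    {"protein_coding", "miRNA", "snoRNA", "snRNA", "lincRNA", "antisense"}
)

SUMSTATS_COLUMNS = [
    "snp", "chrom", "pos", "a1", "a2", "frq", "info", "beta", "se", "p", "n_studies",
]


def complement_allele(allele: str) -> str:
    """Complement every base of an allele string (non-ACGT bases become N)."""
    return "".join(COMPLEMENT.get(b, "N") for b in allele)


def is_ambiguous_pair(a1: str, a2: str) -> bool:
    """True for strand-ambiguous A/T or C/G SNPs."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def normalize_chrom(value) -> int:
    """Normalize a chromosome label ('chr6', '6', 6) to an autosome integer."""
    s = str(value)
    if s.lower().startswith("chr"):
        s = s[3:]
    try:
        c = int(s)
    except ValueError as exc:
        raise ValueError(f"non-autosomal or unrecognized chromosome label: {value!r}") from exc
    if not 1 <= c <= 22:
        raise ValueError(f"chromosome out of autosomal range 1-22: {value!r}")
    return c


@dataclass
class Variant:
    """One biallelic marker.

    ``a1`` is the effect/counted allele, ``maf`` the minor-allele frequency,
    ``info`` the imputation quality and ``n_studies`` the number of studies
    the marker was observed in.
    """

    id: str
    chrom: int
    pos: int
    a1: str
    a2: str
    maf: float = math.nan
    info: float = 1.0
    n_studies: int = 1

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be >= 1, got {self.pos}")
        if self.a1 == self.a2:
            raise ValueError(f"{self.id}: alleles must differ, got {self.a1}/{self.a2}")
        if not math.isnan(self.maf) and not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.id}: maf must lie in [0, 0.5], got {self.maf}")
        if not 0.0 <= self.info <= 1.0:
            raise ValueError(f"{self.id}: info must lie in [0, 1], got {self.info}")

    @property
    def is_snp(self) -> bool:
        return len(self.a1) == 1 and len(self.a2) == 1 and \
            self.a1 in COMPLEMENT and self.a2 in COMPLEMENT

    @property
    def is_indel(self) -> bool:
        return not self.is_snp

    @property
    def is_ambiguous(self) -> bool:
        return self.is_snp and is_ambiguous_pair(self.a1, self.a2)


VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2", "maf", "info", "n_studies"]


def variants_frame(variants) -> pd.DataFrame:
    """Build the canonical variant table from an iterable of :class:`Variant`."""
    return pd.DataFrame(
        [(v.id, v.chrom, v.pos, v.a1, v.a2, v.maf, v.info, v.n_studies) for v in variants],
        columns=VARIANT_COLUMNS,
    )


@dataclass
class GenotypePanel:
    """One study's genotypes: subjects x variants additive dosages with covariates.

    ``dosage[i, j]`` counts copies of variant j's a1 allele carried by subject
    i (0..2, NaN = missing).  ``pcs`` holds principal-component covariates.
    """

    study_id: str
    subjects: pd.DataFrame  # columns: subject_id, phenotype (0=control, 1=case), [sex]
    variants: pd.DataFrame  # canonical VARIANT_COLUMNS
    dosage: np.ndarray
    pcs: np.ndarray | None = None

    def __post_init__(self):
        self.validate()

    def validate(self):
        n, m = self.dosage.shape
        if len(self.subjects) != n:
            raise ValueError(
                f"{self.study_id}: dosage has {n} rows but {len(self.subjects)} subjects"
            )
        if len(self.variants) != m:
            raise ValueError(
                f"{self.study_id}: dosage has {m} columns but {len(self.variants)} variants"
            )
        ph = self.subjects["phenotype"].to_numpy()
        if not np.isin(ph, [0, 1]).all():
            raise ValueError(f"{self.study_id}: phenotype must be binary 0/1")
        if self.pcs is not None:
            if self.pcs.shape[0] != n:
                raise ValueError(f"{self.study_id}: pcs row count mismatch")
            if not np.isfinite(self.pcs).all():
                raise ValueError(f"{self.study_id}: pcs must be finite")

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Observed a1 allele frequency per variant, ignoring missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def phenotype(self) -> np.ndarray:
        return self.subjects["phenotype"].to_numpy().astype(int)


# ---------------------------------------------------------------------------
# PLINK1 bed/bim/fam
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b"
# PLINK1 2-bit genotype codes, SNP-major: 00 = homozygous A1 (2 copies of the
# bim allele-1), 01 = missing, 10 = heterozygous, 11 = homozygous A2.
_CODE_TO_A1_COUNT = np.array([2.0, np.nan, 1.0, 0.0])
_A1_COUNT_TO_CODE = {2: 0, 1: 2, 0: 3}


def decode_bed_byte(byte: int, n_subjects: int = 4, count_allele: str = "a1") -> list:
    """Decode a single SNP-major .bed byte into up to four dosages.

    Subjects are packed low bits first; each 2-bit code follows the PLINK1
    table.  Returns a1 (or a2) allele counts with None for missing.
    """
    out = []
    for i in range(n_subjects):
        code = (byte >> (2 * i)) & 3
        d = _CODE_TO_A1_COUNT[code]
        if np.isnan(d):
            out.append(None)
        else:
            out.append(float(d) if count_allele == "a1" else 2.0 - float(d))
    return out


def read_plink(prefix, count_allele: str = "a1") -> GenotypePanel:
    """Read a PLINK1 bed/bim/fam trio into a :class:`GenotypePanel`.

    Only SNP-major (mode byte 0x01) files are supported.  Phenotypes follow
    the PLINK 1/2 coding (1=control, 2=case).  ``count_allele`` selects which
    bim allele the dosage counts (a1 by default).
    """
    prefix = str(prefix)
    if count_allele not in ("a1", "a2"):
        raise ValueError("count_allele must be 'a1' or 'a2'")
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix + ".fam", sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype={"iid": str},
    )
    raw = Path(prefix + ".bed").read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes {raw[:2]!r}")
    if raw[2:3] != b"\x01":
        raise PlinkFormatError(
            f"{prefix}.bed: mode byte {raw[2]:#04x}; only SNP-major (0x01) is supported"
        )
    n, m = len(fam), len(bim)
    bpf = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != m * bpf:
        raise PlinkFormatError(
            f"{prefix}.bed: expected {m * bpf} data bytes, found {body.size}"
        )
    codes = (body.reshape(m, bpf)[:, :, None] >> (2 * np.arange(4, dtype=np.uint8))) & 3
    codes = codes.reshape(m, bpf * 4)[:, :n]
    dosage = _CODE_TO_A1_COUNT[codes].T.copy()
    if count_allele == "a2":
        dosage = 2.0 - dosage

    pheno = fam["pheno"].to_numpy()
    if not np.isin(pheno, [1, 2]).all():
        raise ValueError(f"{prefix}.fam: phenotype must be coded 1 (control) / 2 (case)")
    subjects = pd.DataFrame({
        "subject_id": fam["iid"],
        "phenotype": (pheno == 2).astype(int),
        "sex": fam["sex"],
    })
    with np.errstate(invalid="ignore"):
        f = np.nanmean(dosage, axis=0) / 2.0
    variants = pd.DataFrame({
        "id": bim["id"],
        "chrom": bim["chrom"].map(normalize_chrom),
        "pos": bim["pos"].astype(int),
        "a1": bim["a1"],
        "a2": bim["a2"],
        "maf": np.minimum(f, 1.0 - f),
        "info": 1.0,
        "n_studies": 1,
    })
    return GenotypePanel(Path(prefix).name, subjects, variants, dosage)


def write_plink(panel: GenotypePanel, prefix, count_allele: str = "a1") -> None:
    """Write a panel as PLINK1 bed/bim/fam (SNP-major).

    Dosages must be integral (hard calls) or missing; fractional dosages
    cannot be represented in the 2-bit codec and raise.
    """
    prefix = str(prefix)
    dos = panel.dosage if count_allele == "a1" else 2.0 - panel.dosage
    finite = ~np.isnan(dos)
    if not np.allclose(dos[finite], np.round(dos[finite]), atol=1e-9):
        raise ValueError("write_plink requires integral (hard-call) dosages")
    n, m = dos.shape
    codes = np.full((m, n), 1, dtype=np.uint8)  # 1 = missing
    rounded = np.round(np.nan_to_num(dos, nan=-1.0)).astype(int)
    for count, code in _A1_COUNT_TO_CODE.items():
        codes[(rounded.T == count) & finite.T] = code
    bpf = (n + 3) // 4
    padded = np.zeros((m, bpf * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4] | (padded[:, 1::4] << 2) | (padded[:, 2::4] << 4) | (padded[:, 3::4] << 6)
    )
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        fh.write(packed.astype(np.uint8).tobytes())

    v = panel.variants
    bim = pd.DataFrame({
        "chrom": v["chrom"], "id": v["id"], "cm": 0, "pos": v["pos"],
        "a1": v["a1"], "a2": v["a2"],
    })
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    s = panel.subjects
    fam = pd.DataFrame({
        "fid": s["subject_id"], "iid": s["subject_id"], "pat": 0, "mat": 0,
        "sex": s["sex"] if "sex" in s else 0,
        "pheno": s["phenotype"].to_numpy() + 1,
    })
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Summary statistics (METAL-like TSV)
# ---------------------------------------------------------------------------

_SUMSTATS_OUT_HEADER = ["SNP", "CHR", "BP", "A1", "A2", "FRQ", "INFO", "BETA", "SE", "P", "NSTUD"]


def read_sumstats(path) -> pd.DataFrame:
    """Read a METAL-like tab-separated association table.

    Required columns (any order, case-insensitive): SNP CHR BP A1 A2 SE P and
    one of BETA / OR.  An OR column is converted to beta = ln(OR); OR <= 0
    raises.  Rows with non-positive SE are rejected (dropped).  Optional
    columns FRQ, INFO, NSTUD are carried through.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "snp": str})
    upper = {c.upper(): c for c in df.columns}
    required = ["SNP", "CHR", "BP", "A1", "A2", "SE", "P"]
    missing = [c for c in required if c not in upper]
    if "BETA" not in upper and "OR" not in upper:
        missing.append("BETA|OR")
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    if "BETA" in upper:
        beta = df[upper["BETA"]].astype(float)
    else:
        orr = df[upper["OR"]].astype(float)
        if (orr <= 0).any():
            bad = df.loc[orr <= 0, upper["SNP"]].tolist()
            raise ValueError(f"{path}: OR must be positive (offending SNPs: {bad[:5]})")
        beta = np.log(orr)

    out = pd.DataFrame({
        "snp": df[upper["SNP"]].astype(str),
        "chrom": df[upper["CHR"]].map(normalize_chrom),
        "pos": df[upper["BP"]].astype(int),
        "a1": df[upper["A1"]].astype(str).str.upper(),
        "a2": df[upper["A2"]].astype(str).str.upper(),
        "frq": df[upper["FRQ"]].astype(float) if "FRQ" in upper else np.nan,
        "info": df[upper["INFO"]].astype(float) if "INFO" in upper else 1.0,
        "beta": beta,
        "se": df[upper["SE"]].astype(float),
        "p": df[upper["P"]].astype(float),
        "n_studies": df[upper["NSTUD"]].astype(int) if "NSTUD" in upper else 1,
    })
    out = out[out["se"] > 0].reset_index(drop=True)
    if ((out["p"] <= 0) | (out["p"] > 1)).any():
        raise ValueError(f"{path}: p-values must lie in (0, 1]")
    return out


def write_sumstats(table: pd.DataFrame, path) -> None:
    """Write an association table in the package's TSV dialect."""
    out = pd.DataFrame({
        "SNP": table["snp"], "CHR": table["chrom"], "BP": table["pos"],
        "A1": table["a1"], "A2": table["a2"], "FRQ": table["frq"],
        "INFO": table["info"], "BETA": table["beta"], "SE": table["se"],
        "P": table["p"], "NSTUD": table["n_studies"],
    })
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Score files
# ---------------------------------------------------------------------------

def write_score_file(entries: pd.DataFrame, path) -> None:
    """Write one score bin as a TSV with columns SNP, A1, WEIGHT."""
    out = pd.DataFrame({"SNP": entries["snp"], "A1": entries["a1"], "WEIGHT": entries["weight"]})
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_score_file(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str})
    upper = {c.upper(): c for c in df.columns}
    missing = [c for c in ("SNP", "A1", "WEIGHT") if c not in upper]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return pd.DataFrame({
        "snp": df[upper["SNP"]].astype(str),
        "a1": df[upper["A1"]].astype(str).str.upper(),
        "weight": df[upper["WEIGHT"]].astype(float),
    })


# ---------------------------------------------------------------------------
# GTF gene annotations
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')


def read_gtf_genes(path, keep_biotypes=None) -> pd.DataFrame:
    """Extract retained gene intervals from a GENCODE-style GTF.

    Keeps ``gene`` features whose biotype (``gene_type`` or ``gene_biotype``
    attribute) is in ``keep_biotypes`` (default :data:`DEFAULT_BIOTYPES`).
    Coordinates are returned 1-based inclusive, verbatim.  Non-autosomal
    genes are skipped.  Malformed records raise :class:`GtfParseError`
    naming the line number.
    """
    keep = DEFAULT_BIOTYPES if keep_biotypes is None else frozenset(keep_biotypes)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            if fields[2] != "gene":
                continue
            attrs = dict(_ATTR_RE.findall(fields[8]))
            if "gene_id" not in attrs:
                raise GtfParseError(f"line {lineno}: malformed attributes (no gene_id): {fields[8]!r}")
            biotype = attrs.get("gene_type", attrs.get("gene_biotype"))
            if biotype is None:
                raise GtfParseError(f"line {lineno}: no gene_type/gene_biotype attribute")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if start > end:
                raise GtfParseError(f"line {lineno}: start > end ({start} > {end})")
            if biotype not in keep:
                continue
            try:
                chrom = normalize_chrom(fields[0])
            except ValueError:
                continue
            rows.append((attrs["gene_id"], attrs.get("gene_name", attrs["gene_id"]),
                         chrom, start, end, biotype))
    return pd.DataFrame(rows, columns=["gene_id", "gene_name", "chrom", "start", "end", "biotype"])
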