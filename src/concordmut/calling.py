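"""Paired tumor/normal somatic SNV classification from allele counts.

Each candidate site carries ref/alt read counts for a tumor and its matched
normal in one modality (exome DNA or mRNA).  Sites are classified as
Reference / Germline / Somatic / LOH / InsufficientCoverage using coverage
thresholds and a one-sided Fisher exact test on the 2x2 table of ref/alt
counts (the VarScan-style somatic statistic): under the null that tumor and
normal share one allele fraction, the alt count in the tumor is
hypergeometric given the table margins, and the somatic p-value is the
upper-tail probability of an alt count at least as large as observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

NUCLEOTIDES = frozenset("ACGT")

#: functional classes counted as protein-altering
FUNCTIONAL_CLASSES = frozenset({"nonsynonymous", "stopgain", "stoploss"})

SITE_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "normal_ref", "normal_alt", "tumor_ref", "tumor_alt",
    "gene", "func_class",
]


class CallStatus(str, Enum):
    REFERENCE = "Reference"
    GERMLINE = "Germline"
    SOMATIC = "Somatic"
    LOH = "LOH"
    INSUFFICIENT_COVERAGE = "InsufficientCoverage"


@dataclass(frozen=True)
class SiteKey:
    """A genomic SNV position with its ref/alt alleles (1-based, inclusive)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(f"ref/alt must be single nucleotides, got {self.ref!r}/{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class AlleleDepth:
    """Ref/alt read counts for one sample at one site."""

    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


@dataclass
class CallingParams:
    """Thresholds for paired somatic classification.

    ``purity`` scales the expected tumor heterozygote allele fraction
    (``het_freq * purity``) used as the genotype boundary between a
    heterozygous and a homozygous-alt tumor call.
    """

    min_cov_normal: int = 8
    min_cov_tumor: int = 6
    purity: float = 0.8
    p_somatic: float = 0.05
    min_var_freq: float = 0.08
    het_freq: float = 0.5

    def __post_init__(self) -> None:
        for name in ("min_cov_normal", "min_cov_tumor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("purity", "p_somatic", "min_var_freq", "het_freq"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


@dataclass
class SomaticCall:
    site: SiteKey
    sample: str
    modality: str
    status: CallStatus
    somatic_p: float
    normal_af: float
    tumor_af: float
    gene: str = ""
    func_class: str = ""


def variant_allele_frequency(depth: AlleleDepth) -> float:
    """Fraction of reads carrying the alternate allele.

    Raises ``ValueError`` at zero total depth, where the frequency is
    undefined.
    """
    total = depth.depth
    if total == 0:
        raise ValueError("variant allele frequency undefined at zero depth")
    return depth.alt_count / total


def fisher_somatic_pvalues(
    normal_alt: np.ndarray,
    normal_depth: np.ndarray,
    tumor_alt: np.ndarray,
    tumor_depth: np.ndarray,
) -> np.ndarray:
    """Vectorized one-sided Fisher exact p for alt enrichment in the tumor.

    Upper-tail hypergeometric probability of at least the observed tumor alt
    count, conditioning on the 2x2 table margins (normal depth, tumor depth |
    total ref, total alt).
    """
    total = np.asarray(normal_depth) + np.asarray(tumor_depth)
    total_alt = np.asarray(normal_alt) + np.asarray(tumor_alt)
    return hypergeom.sf(np.asarray(tumor_alt) - 1, total, total_alt, tumor_depth)


def fisher_somatic_pvalue(normal: AlleleDepth, tumor: AlleleDepth) -> float:
    """One-sided Fisher exact p for alt-allele enrichment in the tumor.

    Scalar wrapper over :func:`fisher_somatic_pvalues`; p is in (0, 1] and
    equals 1 when the tumor carries no alternate reads.
    """
    if normal.depth == 0 or tumor.depth == 0:
        raise ValueError("fisher_somatic_pvalue requires positive depth in both samples")
    return float(
        fisher_somatic_pvalues(normal.alt_count, normal.depth, tumor.alt_count, tumor.depth)
    )


def _fisher_depletion_pvalue(normal: AlleleDepth, tumor: AlleleDepth) -> float:
    """Lower-tail counterpart: alt-allele depletion in the tumor (LOH toward ref)."""
    total = normal.depth + tumor.depth
    total_alt = normal.alt_count + tumor.alt_count
    return float(hypergeom.cdf(tumor.alt_count, total, total_alt, tumor.depth))


def classify_site(
    site: SiteKey,
    normal: AlleleDepth,
    tumor: AlleleDepth,
    params: CallingParams | None = None,
    *,
    sample: str = "",
    modality: str = "",
    gene: str = "",
    func_class: str = "",
) -> SomaticCall:
    """Classify one paired site; scalar reference for the vectorized caller.

    Decision ladder:

    1. insufficient coverage in either sample;
    2. Germline — variant present (af >= min_var_freq) in both samples;
    3. Somatic — normal non-variant, tumor variant, one-sided Fisher
       p < p_somatic (strict);
    4. LOH — normal heterozygous, tumor driven back toward reference with a
       significant lower-tail Fisher p (the drive-toward-homozygous-alt arm
       is subsumed by the Germline branch, which fires first);
    5. Reference otherwise.
    """
    params = params or CallingParams()
    naf = variant_allele_frequency(normal) if normal.depth > 0 else float("nan")
    taf = variant_allele_frequency(tumor) if tumor.depth > 0 else float("nan")

    def _call(status: CallStatus, p: float) -> SomaticCall:
        return SomaticCall(site, sample, modality, status, p, naf, taf, gene, func_class)

    if normal.depth < params.min_cov_normal or tumor.depth < params.min_cov_tumor:
        return _call(CallStatus.INSUFFICIENT_COVERAGE, float("nan"))

    normal_variant = naf >= params.min_var_freq
    tumor_variant = taf >= params.min_var_freq
    if normal_variant and tumor_variant:
        return _call(CallStatus.GERMLINE, float("nan"))
    if tumor_variant and not normal_variant:
        p = fisher_somatic_pvalue(normal, tumor)
        if p < params.p_somatic:
            return _call(CallStatus.SOMATIC, p)
        return _call(CallStatus.REFERENCE, p)
    # normal heterozygous band, tumor lost the variant -> candidate LOH
    het_low = params.min_var_freq
    het_high = 1.0 - params.min_var_freq
    if het_low <= naf <= het_high and not tumor_variant:
        p = _fisher_depletion_pvalue(normal, tumor)
        if p < params.p_somatic:
            return _call(CallStatus.LOH, p)
        return _call(CallStatus.REFERENCE, p)
    return _call(CallStatus.REFERENCE, float("nan"))


def classify_table(site_table: pd.DataFrame, params: CallingParams | None = None) -> pd.DataFrame:
    """Vectorized classification of a site table.

    Expects the tab-separated site-table columns (``chrom, pos, ref, alt,
    normal_ref, normal_alt, tumor_ref, tumor_alt, gene, func_class`` and
    optionally ``sample``/``modality``).  Returns a copy with ``status``,
    ``somatic_p``, ``normal_af`` and ``tumor_af`` columns appended.  Agrees
    row-for-row with :func:`classify_site`.
    """
    params = params or CallingParams()
    df = site_table.copy()
    dn = (df["normal_ref"] + df["normal_alt"]).to_numpy(dtype=np.int64)
    dt = (df["tumor_ref"] + df["tumor_alt"]).to_numpy(dtype=np.int64)
    an = df["normal_alt"].to_numpy(dtype=np.int64)
    at = df["tumor_alt"].to_numpy(dtype=np.int64)

    with np.errstate(invalid="ignore", divide="ignore"):
        naf = np.where(dn > 0, an / np.maximum(dn, 1), np.nan)
        taf = np.where(dt > 0, at / np.maximum(dt, 1), np.nan)

    insufficient = (dn < params.min_cov_normal) | (dt < params.min_cov_tumor)
    normal_variant = naf >= params.min_var_freq
    tumor_variant = taf >= params.min_var_freq

    p_up = fisher_somatic_pvalues(an, np.maximum(dn, 1), at, np.maximum(dt, 1))
    p_down = hypergeom.cdf(at, np.maximum(dn + dt, 1), an + at, dt)

    status = np.full(len(df), CallStatus.REFERENCE.value, dtype=object)
    somatic_p = np.full(len(df), np.nan)

    germline = ~insufficient & normal_variant & tumor_variant
    somatic_cand = ~insufficient & tumor_variant & ~normal_variant
    somatic = somatic_cand & (p_up < params.p_somatic)
    het = (naf >= params.min_var_freq) & (naf <= 1.0 - params.min_var_freq)
    loh_cand = ~insufficient & het & ~tumor_variant
    loh = loh_cand & (p_down < params.p_somatic)

    status[insufficient] = CallStatus.INSUFFICIENT_COVERAGE.value
    status[germline] = CallStatus.GERMLINE.value
    status[somatic_cand] = CallStatus.REFERENCE.value
    status[somatic] = CallStatus.SOMATIC.value
    status[loh] = CallStatus.LOH.value
    somatic_p[somatic_cand] = p_up[somatic_cand]
    somatic_p[loh_cand & ~somatic_cand] = p_down[loh_cand & ~somatic_cand]

    df["status"] = status
    df["somatic_p"] = somatic_p
    df["normal_af"] = naf
    df["tumor_af"] = taf
    return df


def call_somatic(site_table: pd.DataFrame, params: CallingParams | None = None) -> pd.DataFrame:
    """Return the Somatic subset of a classified site table, sorted by position.

    Raises on duplicate (sample, modality, chrom, pos, alt) rows — a site may
    appear at most once per sample and modality.
    """
    key_cols = [c for c in ("sample", "modality") if c in site_table.columns]
    key_cols += ["chrom", "pos", "alt"]
    if site_table.duplicated(subset=key_cols).any():
        dup = site_table[site_table.duplicated(subset=key_cols, keep=False)]
        raise ValueError(
            f"duplicate site rows for keys {key_cols}: "
            f"{dup[key_cols].head().to_dict('records')}"
        )
    classified = classify_table(site_table, params)
    somatic = classified[classified["status"] == CallStatus.SOMATIC.value]
    return somatic.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def snv_agreement(
    calls_a: dict[tuple[str, int], str],
    calls_b: dict[tuple[str, int], str],
) -> tuple[int, float]:
    """Cross-modality SNV agreement at shared positions.

    Inputs map (chrom, pos) -> alt allele for each modality.  Returns the
    number of positions present in both and the fraction of those with an
    identical alternate allele (NaN when no position is shared).
    """
    shared = calls_a.keys() & calls_b.keys()
    n_shared = len(shared)
    if n_shared == 0:
        return 0, float("nan")
    same = sum(1 for k in shared if calls_a[k] == calls_b[k])
    return n_shared, same / n_shared
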