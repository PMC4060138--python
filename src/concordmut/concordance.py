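"""DNA/RNA somatic-call concordance, allele-frequency skew, and backfill.

A mutation is *concordant* (conserved) when it is called somatic in both the
exome and the mRNA modality of the same tumor at the exact same genomic
position with the same alternate allele.  Calls private to one modality are
*backfilled*: the other modality's raw allele counts at that position are
re-examined and the discordance is attributed to missing coverage (gene not
expressed), a germline-looking signal, a plain reference call, or a somatic
signal that misses the significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .calling import (
    AlleleDepth,
    CallingParams,
    FUNCTIONAL_CLASSES,
    SiteKey,
    fisher_somatic_pvalue,
)

SITE_KEY = ["chrom", "pos", "ref", "alt"]


class BackfillCategory(str, Enum):
    NOT_COVERED = "NotCovered"
    GERMLINE = "Germline"
    REFERENCE = "Reference"
    SOMATIC_SUBTHRESHOLD = "SomaticSubthreshold"
    OTHER = "Other"


@dataclass
class BackfillRecord:
    sample: str
    site: SiteKey
    called_in: str  # "DNA_only" | "RNA_only"
    category: BackfillCategory


def intersect_calls(dna_calls: pd.DataFrame, rna_calls: pd.DataFrame) -> pd.DataFrame:
    """Concordant mutations: somatic in both modalities at identical (chrom, pos, alt).

    Both inputs must be somatic call tables for the same sample (columns as
    produced by :func:`concordmut.calling.call_somatic`).  The result carries
    both modalities' allele frequencies and somatic p-values.
    """
    for df, name in ((dna_calls, "dna"), (rna_calls, "rna")):
        if "sample" in df.columns and df["sample"].nunique() > 1:
            raise ValueError(f"{name} calls span multiple samples: {sorted(df['sample'].unique())}")
    if (
        "sample" in dna_calls.columns
        and "sample" in rna_calls.columns
        and len(dna_calls)
        and len(rna_calls)
    ):
        sd, sr = dna_calls["sample"].iloc[0], rna_calls["sample"].iloc[0]
        if sd != sr:
            raise ValueError(f"sample-id mismatch between modalities: {sd!r} vs {sr!r}")

    left_cols = SITE_KEY + [
        c for c in ("sample", "gene", "func_class", "tumor_af", "somatic_p") if c in dna_calls.columns
    ]
    right_cols = SITE_KEY + [c for c in ("tumor_af", "somatic_p") if c in rna_calls.columns]
    merged = dna_calls[left_cols].merge(
        rna_calls[right_cols], on=SITE_KEY, suffixes=("", "_rna")
    )
    merged = merged.rename(
        columns={
            "tumor_af": "dna_af",
            "somatic_p": "dna_somatic_p",
            "tumor_af_rna": "rna_af",
            "somatic_p_rna": "rna_somatic_p",
        }
    )
    return merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def intersect_cohort(dna_calls: pd.DataFrame, rna_calls: pd.DataFrame) -> pd.DataFrame:
    """Concordant mutations for a pooled multi-sample call table.

    Same contract as :func:`intersect_calls` applied within each sample
    (the ``sample`` column joins the two modalities).
    """
    key = ["sample"] + SITE_KEY
    left_cols = key + [c for c in ("gene", "func_class", "tumor_af", "somatic_p") if c in dna_calls.columns]
    right_cols = key + [c for c in ("tumor_af", "somatic_p") if c in rna_calls.columns]
    merged = dna_calls[left_cols].merge(rna_calls[right_cols], on=key, suffixes=("", "_rna"))
    merged = merged.rename(
        columns={
            "tumor_af": "dna_af",
            "somatic_p": "dna_somatic_p",
            "tumor_af_rna": "rna_af",
            "somatic_p_rna": "rna_somatic_p",
        }
    )
    return merged.sort_values(["sample", "chrom", "pos"], kind="mergesort").reset_index(drop=True)


def filter_nonsynonymous(calls: pd.DataFrame) -> pd.DataFrame:
    """Retain protein-altering calls (nonsynonymous, stopgain, stoploss); order preserved."""
    if "func_class" not in calls.columns:
        raise ValueError("calls lack the func_class column")
    if len(calls) and calls["func_class"].isna().any():
        raise ValueError("func_class contains missing values")
    return calls[calls["func_class"].isin(FUNCTIONAL_CLASSES)].copy()


def preferential_expression_summary(concordant: pd.DataFrame) -> tuple[int, int, float]:
    """How many conserved mutations have a strictly higher allele fraction in RNA.

    Returns ``(n_higher_in_rna, n_total, percent)`` with the percentage
    rounded to the nearest integer for display (NaN for empty input).  Ties
    do not count as higher.
    """
    n_total = len(concordant)
    if n_total == 0:
        return 0, 0, float("nan")
    n_higher = int((concordant["rna_af"] > concordant["dna_af"]).sum())
    return n_higher, n_total, round(100.0 * n_higher / n_total)


def backfill_classify(
    other_normal: AlleleDepth | None,
    other_tumor: AlleleDepth | None,
    params: CallingParams | None = None,
) -> BackfillCategory:
    """Explain a single-modality somatic call from the other modality's counts.

    Decision ladder (first match wins):

    1. NotCovered — position absent from the other modality or below the
       coverage thresholds there;
    2. Germline — variant allele present in both tumor and normal;
    3. Reference — tumor non-variant;
    4. SomaticSubthreshold — tumor variant with a clean normal, but the
       Fisher p misses the significance threshold;
    5. Other — remaining configurations (e.g. variant-in-normal only).
    """
    params = params or CallingParams()
    if other_normal is None or other_tumor is None:
        return BackfillCategory.NOT_COVERED
    if other_normal.depth < params.min_cov_normal or other_tumor.depth < params.min_cov_tumor:
        return BackfillCategory.NOT_COVERED
    naf = other_normal.alt_count / other_normal.depth
    taf = other_tumor.alt_count / other_tumor.depth
    normal_variant = naf >= params.min_var_freq
    tumor_variant = taf >= params.min_var_freq
    if normal_variant and tumor_variant:
        return BackfillCategory.GERMLINE
    if not tumor_variant:
        return BackfillCategory.REFERENCE
    if not normal_variant:
        p = fisher_somatic_pvalue(other_normal, other_tumor)
        if p >= params.p_somatic:
            return BackfillCategory.SOMATIC_SUBTHRESHOLD
    return BackfillCategory.OTHER


def backfill_table(
    discordant: pd.DataFrame,
    other_sites: pd.DataFrame,
    called_in: str,
    params: CallingParams | None = None,
) -> pd.DataFrame:
    """Vectorized backfill of a discordant call table.

    ``other_sites`` is the other modality's raw site table for the same
    sample; positions absent from it count as NotCovered.  Returns the
    discordant table with ``called_in`` and ``category`` columns.
    """
    params = params or CallingParams()
    if called_in not in ("DNA_only", "RNA_only"):
        raise ValueError(f"called_in must be DNA_only or RNA_only, got {called_in!r}")
    out = discordant[SITE_KEY + [c for c in ("sample", "gene", "func_class") if c in discordant.columns]].copy()
    key = SITE_KEY
    if "sample" in out.columns and "sample" in other_sites.columns:
        key = ["sample"] + SITE_KEY
    other = other_sites[key + ["normal_ref", "normal_alt", "tumor_ref", "tumor_alt"]]
    merged = out.merge(other, on=key, how="left")

    dn = (merged["normal_ref"] + merged["normal_alt"]).to_numpy()
    dt = (merged["tumor_ref"] + merged["tumor_alt"]).to_numpy()
    an = merged["normal_alt"].to_numpy()
    at = merged["tumor_alt"].to_numpy()
    absent = merged["normal_ref"].isna().to_numpy()

    with np.errstate(invalid="ignore", divide="ignore"):
        naf = an / np.maximum(dn, 1)
        taf = at / np.maximum(dt, 1)
    not_covered = absent | (dn < params.min_cov_normal) | (dt < params.min_cov_tumor)
    normal_variant = ~not_covered & (naf >= params.min_var_freq)
    tumor_variant = ~not_covered & (taf >= params.min_var_freq)

    from scipy.stats import hypergeom

    total = np.nan_to_num(dn + dt, nan=1).astype(np.int64)
    total_alt = np.nan_to_num(an + at, nan=0).astype(np.int64)
    at_i = np.nan_to_num(at, nan=0).astype(np.int64)
    dt_i = np.nan_to_num(dt, nan=1).astype(np.int64)
    p_up = hypergeom.sf(at_i - 1, np.maximum(total, 1), total_alt, dt_i)

    category = np.full(len(merged), BackfillCategory.OTHER.value, dtype=object)
    category[~not_covered & tumor_variant & ~normal_variant & (p_up >= params.p_somatic)] = (
        BackfillCategory.SOMATIC_SUBTHRESHOLD.value
    )
    category[~not_covered & ~tumor_variant] = BackfillCategory.REFERENCE.value
    category[normal_variant & tumor_variant] = BackfillCategory.GERMLINE.value
    category[not_covered] = BackfillCategory.NOT_COVERED.value

    out["called_in"] = called_in
    out["category"] = category
    return out


def backfill_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and within-stratum fractions per (called_in, category).

    Fractions sum to 1 within each ``called_in`` stratum.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["called_in", "category", "n", "fraction"])
    counts = (
        records.groupby(["called_in", "category"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    counts["fraction"] = counts.groupby("called_in")["n"].transform(lambda s: s / s.sum())
    return counts.sort_values(["called_in", "n"], ascending=[True, False]).reset_index(drop=True)
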