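"""Cohort-level summaries of conserved mutations.

Recurrence is counted at two resolutions: a *mutation* recurs when the exact
(chrom, pos, alt) site is seen in two or more tumors; a *gene* recurs when
two or more tumors carry any conserved protein-altering mutation in it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SITE_KEY = ["chrom", "pos", "ref", "alt"]


@dataclass
class MutationLoad:
    sample: str
    n_total: int
    n_coding: int
    n_nonsyn: int
    per_mb: float


def gene_recurrence(concordant: pd.DataFrame, n_samples: int) -> pd.DataFrame:
    """Per-gene recurrence across the cohort.

    A sample contributes at most once per gene.  Returns columns
    ``gene, n_samples_mutated, n_samples_total, frequency`` (percent, full
    precision) sorted by count descending with alphabetical tie-break; genes
    absent from every sample do not appear.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if len(concordant) == 0:
        return pd.DataFrame(columns=["gene", "n_samples_mutated", "n_samples_total", "frequency"])
    counts = (
        concordant[["gene", "sample"]]
        .drop_duplicates()
        .groupby("gene")
        .size()
        .rename("n_samples_mutated")
        .reset_index()
    )
    counts["n_samples_total"] = n_samples
    counts["frequency"] = 100.0 * counts["n_samples_mutated"] / n_samples
    return (
        counts.sort_values(["n_samples_mutated", "gene"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )


def recurrent_fraction(
    concordant: pd.DataFrame, min_samples: int = 2
) -> tuple[int, int, float]:
    """Fraction of unique mutations present in >= min_samples samples.

    Uniqueness keys on the exact site (chrom, pos, ref, alt).  Returns
    ``(n_recurrent, n_unique, percent)`` with the percentage rounded to one
    decimal (NaN for empty input).
    """
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    if len(concordant) == 0:
        return 0, 0, float("nan")
    per_site = concordant.drop_duplicates(subset=SITE_KEY + ["sample"]).groupby(SITE_KEY).size()
    n_unique = len(per_site)
    n_recurrent = int((per_site >= min_samples).sum())
    return n_recurrent, n_unique, round(100.0 * n_recurrent / n_unique, 1)


def mutation_load(calls: pd.DataFrame, sample: str, target_mb: float) -> MutationLoad:
    """Per-sample mutation counts and the per-megabase rate over the capture target."""
    if target_mb <= 0:
        raise ValueError("target_mb must be positive")
    n_total = len(calls)
    if "func_class" in calls.columns and n_total:
        coding = calls["func_class"].isin({"synonymous", "nonsynonymous", "stopgain", "stoploss"})
        nonsyn = calls["func_class"].isin({"nonsynonymous", "stopgain", "stoploss"})
        n_coding, n_nonsyn = int(coding.sum()), int(nonsyn.sum())
    else:
        n_coding = n_nonsyn = 0
    return MutationLoad(sample, n_total, n_coding, n_nonsyn, n_total / target_mb)


def cohort_loads(calls: pd.DataFrame, target_mb: float, samples: list[str] | None = None) -> pd.DataFrame:
    """Mutation loads for every sample of a pooled call table (``sample`` column)."""
    samples = samples if samples is not None else sorted(calls["sample"].unique())
    rows = []
    for s in samples:
        load = mutation_load(calls[calls["sample"] == s], s, target_mb)
        rows.append(vars(load))
    return pd.DataFrame(rows, columns=["sample", "n_total", "n_coding", "n_nonsyn", "per_mb"])


def mutation_status_matrix(
    genes: list[str], samples: list[str], concordant: pd.DataFrame
) -> pd.DataFrame:
    """Binary gene x sample matrix: 1 iff the sample carries a conserved mutation in the gene.

    Row order follows ``genes`` and column order ``samples`` (deterministic).
    """
    mat = pd.DataFrame(0, index=pd.Index(genes, name="gene"), columns=samples, dtype=np.int64)
    if len(concordant):
        hits = concordant[["gene", "sample"]].drop_duplicates()
        hits = hits[hits["gene"].isin(mat.index) & hits["sample"].isin(mat.columns)]
        for g, s in hits.itertuples(index=False):
            mat.at[g, s] = 1
    return mat
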