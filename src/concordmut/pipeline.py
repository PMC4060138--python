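"""End-to-end orchestration: call -> overlap -> recurrence -> pathways -> survival.

`analyze_cohort` runs the whole analysis in memory on a `Cohort` (or on
equivalent tables read from disk); `run_pipeline` wraps it with file IO and
a run manifest so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calling import CallingParams, call_somatic
from .concordance import (
    SITE_KEY,
    backfill_summary,
    backfill_table,
    filter_nonsynonymous,
    intersect_cohort,
)
from .pathways import DeregParams, PathwayDefinition, cluster_samples, filter_pathways_by_sd, rpkm_normalize, score_matrix
from .recurrence import cohort_loads, gene_recurrence, mutation_status_matrix, recurrent_fraction
from .survival import SurvivalResult, cox_ph, km_logrank, kruskal_wallis, pearson_load_vs_score
from .synthetic import Cohort, CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

TARGET_MB_DEFAULT = 51.0  # exome capture target size, Mb


@dataclass
class PipelineConfig:
    """File-level configuration for `run_pipeline`."""

    outdir: str
    simulate: CohortConfig | None = None
    dna_sites: str | None = None
    rna_sites: str | None = None
    expression_prefix: str | None = None
    gmt: str | None = None
    clinical: str | None = None
    calling: CallingParams = field(default_factory=CallingParams)
    dereg: DeregParams = field(default_factory=DeregParams)
    min_samples: int = 2
    target_mb: float = TARGET_MB_DEFAULT
    seed: int = 0


@dataclass
class CohortAnalysis:
    dna_calls: pd.DataFrame
    rna_calls: pd.DataFrame
    concordant: pd.DataFrame  # nonsynonymous conserved mutations
    concordant_all: pd.DataFrame  # all conserved mutations (any class)
    backfill: pd.DataFrame
    backfill_fractions: pd.DataFrame
    loads: pd.DataFrame  # per sample: dna/rna/overlap nonsyn loads + per-Mb rate
    recurrence: pd.DataFrame
    recurrent_mutations: tuple[int, int, float]
    status_matrix: pd.DataFrame
    scores: pd.DataFrame  # retained pathways x samples
    scores_all: pd.DataFrame
    mean_score: pd.Series  # per tumor, over retained pathways
    clusters: pd.Series


def analyze_cohort(
    cohort: Cohort,
    calling: CallingParams | None = None,
    dereg: DeregParams | None = None,
    min_samples: int = 2,
    target_mb: float = TARGET_MB_DEFAULT,
    n_clusters: int | None = None,
) -> CohortAnalysis:
    """Run calling, concordance, recurrence, pathway scoring and clustering."""
    calling = calling or CallingParams()
    dereg = dereg or DeregParams()
    samples = cohort.tumor_ids

    dna = cohort.dna_sites.copy()
    rna = cohort.rna_sites.copy()
    dna["modality"], rna["modality"] = "DNA", "RNA"
    dna_calls = call_somatic(dna, calling)
    rna_calls = call_somatic(rna, calling)

    concordant_all = intersect_cohort(dna_calls, rna_calls)
    concordant = filter_nonsynonymous(concordant_all)

    key = ["sample"] + SITE_KEY
    conc_keys = concordant_all[key]
    dna_only = dna_calls.merge(conc_keys, on=key, how="left", indicator=True)
    dna_only = dna_only[dna_only["_merge"] == "left_only"].drop(columns="_merge")
    rna_only = rna_calls.merge(conc_keys, on=key, how="left", indicator=True)
    rna_only = rna_only[rna_only["_merge"] == "left_only"].drop(columns="_merge")
    bf_dna = backfill_table(dna_only, cohort.rna_sites, "DNA_only", calling)
    bf_rna = backfill_table(rna_only, cohort.dna_sites, "RNA_only", calling)
    backfill = pd.concat([bf_dna, bf_rna], ignore_index=True)
    backfill_fracs = backfill_summary(backfill)

    dna_nonsyn = filter_nonsynonymous(dna_calls)
    rna_nonsyn = filter_nonsynonymous(rna_calls)
    loads = cohort_loads(dna_calls, target_mb, samples).set_index("sample")
    loads["dna_nonsyn"] = dna_nonsyn.groupby("sample").size().reindex(samples).fillna(0).astype(int)
    loads["rna_nonsyn"] = rna_nonsyn.groupby("sample").size().reindex(samples).fillna(0).astype(int)
    loads["overlap_nonsyn"] = concordant.groupby("sample").size().reindex(samples).fillna(0).astype(int)

    recur = gene_recurrence(concordant, n_samples=len(samples))
    recur_mut = recurrent_fraction(concordant, min_samples=min_samples)
    top_genes = recur["gene"].head(10).tolist()
    status = mutation_status_matrix(top_genes, samples, concordant)

    log_rpkm = rpkm_normalize(
        cohort.expression_counts, cohort.gene_lengths, offset=dereg.rpkm_log_offset
    )
    scores_all = score_matrix(log_rpkm, cohort.pathways, cohort.normal_ids, dereg)
    scores = filter_pathways_by_sd(scores_all, samples, dereg.sd_min)
    if len(scores) < 2:  # pragma: no cover - degenerate configuration
        logger.warning("SD filter retained %d pathways; clustering on unfiltered scores", len(scores))
        scores = scores_all
    mean_score = scores[samples].mean(axis=0)
    k = n_clusters if n_clusters is not None else dereg.n_clusters
    clusters = cluster_samples(scores[samples], n_clusters=min(k, len(samples)))

    return CohortAnalysis(
        dna_calls=dna_calls,
        rna_calls=rna_calls,
        concordant=concordant,
        concordant_all=concordant_all,
        backfill=backfill,
        backfill_fractions=backfill_fracs,
        loads=loads,
        recurrence=recur,
        recurrent_mutations=recur_mut,
        status_matrix=status,
        scores=scores,
        scores_all=scores_all,
        mean_score=mean_score,
        clusters=clusters,
    )


def associate(
    analysis: CohortAnalysis, clinical: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Statistical report: loads vs groups, load vs mean score, survival by group.

    ``groups`` maps tumor id to a (cluster or subgroup) label.  Returns a
    tidy table (test, variable, statistic, p, hr).
    """
    rows = []
    samples = analysis.loads.index
    groups = groups.reindex(samples)
    by_group = [
        analysis.loads.loc[groups == g, "overlap_nonsyn"].to_numpy()
        for g in sorted(groups.dropna().unique())
    ]
    if len(by_group) >= 2 and all(len(g) for g in by_group):
        h, p = kruskal_wallis(by_group)
        rows.append(("kruskal_wallis", "overlap_nonsyn_by_group", h, p, np.nan))

    ms = analysis.mean_score.reindex(samples)
    for col in ("dna_nonsyn", "rna_nonsyn", "overlap_nonsyn"):
        x = analysis.loads[col].to_numpy(dtype=float)
        if np.std(x) > 0 and np.std(ms) > 0:
            r, p = pearson_load_vs_score(x, ms.to_numpy())
            rows.append(("pearson", f"{col}_vs_mean_score", r, p, np.nan))

    clin = clinical.reindex(samples)
    _, lr = km_logrank(clin, groups)
    rows.append(("logrank", "survival_by_group", lr.statistic, lr.p_value, np.nan))
    try:
        cox = cox_ph(clin, analysis.loads["overlap_nonsyn"], name="overlap_nonsyn")
        rows.append(("cox", "overlap_nonsyn", cox.statistic, cox.p_value, cox.hazard_ratio))
    except ValueError as e:  # constant covariate / no events
        logger.warning("cox fit skipped: %s", e)
    return pd.DataFrame(rows, columns=["test", "variable", "statistic", "p", "hr"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline, writing every intermediate plus a manifest.

    Returns the manifest dictionary.  A given (config, seed) reruns to
    byte-identical outputs.
    """
    from . import io as cio

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        cohort = generate_cohort(config.simulate)
        stage = "simulate"
    else:
        for name in ("dna_sites", "rna_sites", "expression_prefix", "gmt", "clinical"):
            p = getattr(config, name)
            if p is None:
                raise ValueError(f"pipeline needs either simulate= or an input path for {name}")
            if name != "expression_prefix" and not Path(p).exists():
                raise FileNotFoundError(f"input file for {name} not found: {p}")
        dna_sites = cio.read_site_table(config.dna_sites)
        rna_sites = cio.read_site_table(config.rna_sites)
        counts, lengths = cio.read_expression(config.expression_prefix)
        pathways = cio.read_gmt(config.gmt)
        clinical = cio.read_clinical(config.clinical)
        tumor_ids = list(clinical.index)
        cohort = Cohort(
            config=CohortConfig(n_pairs=len(tumor_ids), seed=config.seed),
            genes=pd.DataFrame(),
            dna_sites=dna_sites,
            rna_sites=rna_sites,
            expression_counts=counts,
            gene_lengths=lengths,
            pathways=pathways,
            clinical=clinical,
            truth=None,
        )
        stage = "load"

    try:
        analysis = analyze_cohort(
            cohort, config.calling, config.dereg,
            min_samples=config.min_samples, target_mb=config.target_mb,
        )
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage 'analyze' after '{stage}': {e}") from e

    clusters = analysis.clusters
    report = associate(analysis, cohort.clinical, clusters)

    cio.write_site_table(cohort.dna_sites, out / "dna_sites.tsv")
    cio.write_site_table(cohort.rna_sites, out / "rna_sites.tsv")
    analysis.dna_calls.to_csv(out / "dna_somatic_calls.tsv", sep="\t", index=False)
    analysis.rna_calls.to_csv(out / "rna_somatic_calls.tsv", sep="\t", index=False)
    analysis.concordant.to_csv(out / "conserved_mutations.tsv", sep="\t", index=False)
    analysis.backfill.to_csv(out / "backfill.tsv", sep="\t", index=False)
    analysis.backfill_fractions.to_csv(out / "backfill_summary.tsv", sep="\t", index=False)
    analysis.loads.to_csv(out / "mutation_loads.tsv", sep="\t")
    analysis.recurrence.to_csv(out / "gene_recurrence.tsv", sep="\t", index=False)
    analysis.status_matrix.to_csv(out / "mutation_status_matrix.tsv", sep="\t")
    analysis.scores.to_csv(out / "pathway_scores.tsv", sep="\t")
    clusters.rename("cluster").to_csv(out / "clusters.tsv", sep="\t")
    report.to_csv(out / "association_report.tsv", sep="\t", index=False)
    cio.write_clinical(cohort.clinical, out / "clinical.csv")
    cio.write_gmt(cohort.pathways, out / "pathways.gmt")
    if cohort.truth is not None:
        cohort.truth.planted_mutations.to_csv(out / "truth_somatic.tsv", sep="\t", index=False)
        cohort.truth.subgroup_labels.rename("subgroup").to_csv(out / "truth_subgroups.tsv", sep="\t")

    n_rec, n_uniq, pct = analysis.recurrent_mutations
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "calling": vars(config.calling),
        "dereg": vars(config.dereg),
        "target_mb": config.target_mb,
        "counts": {
            "samples": len(cohort.tumor_ids),
            "dna_sites": len(cohort.dna_sites),
            "rna_sites": len(cohort.rna_sites),
            "dna_somatic_calls": len(analysis.dna_calls),
            "rna_somatic_calls": len(analysis.rna_calls),
            "conserved_nonsyn": len(analysis.concordant),
            "conserved_all": len(analysis.concordant_all),
            "backfill_records": len(analysis.backfill),
            "pathways_scored": len(analysis.scores_all),
            "pathways_retained": len(analysis.scores),
            "recurrent_mutations": n_rec,
            "unique_mutations": n_uniq,
        },
        "recurrent_pct": None if np.isnan(pct) else pct,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
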