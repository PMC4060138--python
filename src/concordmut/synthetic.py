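"""Synthetic paired tumor/normal cohort with DNA and RNA allele counts.

Emulates the statistical structure the analysis assumes for a small
never-smoker lung adenocarcinoma cohort: ~27 tumor/normal pairs sequenced
in two modalities, hundreds to thousands of somatic SNVs per tumor in DNA
(most of them non-coding or in unexpressed genes), a much smaller conserved
subset visible in RNA with an allele-fraction skew toward the transcript, a
handful of recurrently mutated driver genes concentrated in a planted
high-risk subgroup, deregulated pathways in that same subgroup, and
survival times with a subgroup hazard ratio.

Every random draw flows through one seeded generator, so a given
(config, seed) pair reproduces the cohort byte for byte.  The planted truth
(site-level allele fractions, expression flags, subgroup labels,
deregulated pathways) is returned alongside the data for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .pathways import PathwayDefinition

DRIVER_GENES_DEFAULT = (
    "EGFR", "KRAS", "TP53", "RPS6KB2", "PTPN13", "SP1", "SPTAN1", "MYOF", "ATXN2", "DHX9",
)

_BASES = np.array(list("ACGT"))


@dataclass
class CohortConfig:
    """Generator parameters; the defaults are the simulated study conditions.

    Rates are per tumor.  ``somatic_rate_dna`` counts coding somatic SNVs;
    non-coding somatic events are added at ``noncoding_ratio`` times that
    rate, calibrated so a default tumor carries on the order of a thousand
    somatic SNVs of which ~10% are coding.  ``ase_skew`` is the mean
    additive increase of the RNA alt fraction over the DNA alt fraction for
    mutations that reach the transcript.
    """

    n_pairs: int = 27
    n_genes: int = 2000
    gene_length: int = 1500
    n_pathways: int = 50
    genes_per_pathway: int = 15
    n_dereg_pathways: int = 12
    frac_genes_expressed: float = 0.6
    somatic_rate_dna: float = 102.0
    noncoding_ratio: float = 10.2
    frac_nonsyn: float = 0.675
    frac_stopgain: float = 0.05
    germline_rate: float = 300.0
    rna_only_rate: float = 850.0
    frac_drivers: float = 0.0
    driver_genes: tuple[str, ...] = DRIVER_GENES_DEFAULT
    driver_recurrence: tuple[int, ...] = (4, 3, 3, 3, 2, 2, 2, 2, 2, 2)
    driver_highrisk_weight: float = 4.0
    mut_rate_highrisk_mult: float = 1.3
    rna_transmit_prob: float = 0.25
    rna_transmit_prob_highrisk: float = 0.5
    dna_depth_mean: float = 80.0
    rna_depth_mean: float = 60.0
    depth_dispersion: float = 8.0
    seq_error: float = 0.001
    rna_germline_artifact: float = 0.01
    tumor_purity_true: float = 0.8
    ase_skew: float = 0.15
    ase_sd: float = 0.05
    dereg_effect: float = 1.0
    frac_highrisk: float = 0.4
    hazard_baseline: float = 0.15
    hazard_ratio_true: float = 5.0
    censor_time_max: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            "frac_genes_expressed", "frac_nonsyn", "frac_stopgain", "frac_drivers",
            "rna_transmit_prob", "rna_transmit_prob_highrisk", "seq_error",
            "rna_germline_artifact", "tumor_purity_true", "frac_highrisk",
        )
        for name in fracs:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        positives = (
            "n_pairs", "n_genes", "gene_length", "n_pathways", "genes_per_pathway",
            "dna_depth_mean", "rna_depth_mean", "depth_dispersion",
            "hazard_baseline", "hazard_ratio_true", "censor_time_max",
        )
        for name in positives:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        nonneg = (
            "somatic_rate_dna", "noncoding_ratio", "germline_rate", "rna_only_rate",
            "ase_sd", "dereg_effect",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.n_dereg_pathways > self.n_pathways:
            raise ValueError("n_dereg_pathways cannot exceed n_pathways")
        if len(self.driver_genes) > self.n_genes:
            raise ValueError("more driver genes than genes")
        if len(self.driver_recurrence) != len(self.driver_genes):
            raise ValueError("driver_recurrence must parallel driver_genes")
        if any(k < 0 or k > self.n_pairs for k in self.driver_recurrence):
            raise ValueError("driver recurrence targets must lie in [0, n_pairs]")
        if self.driver_highrisk_weight <= 0:
            raise ValueError("driver_highrisk_weight must be positive")


@dataclass
class HazardParams:
    baseline_hazard: float
    hazard_ratio: float
    censor_time_max: float
    highrisk_label: str = "highrisk"

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0 or self.hazard_ratio <= 0:
            raise ValueError("hazards must be positive")
        if self.censor_time_max <= 0:
            raise ValueError("censor_time_max must be positive")


@dataclass
class CohortTruth:
    """Planted ground truth for recovery testing."""

    planted_mutations: pd.DataFrame  # somatic sites with true allele fractions
    germline_sites: pd.DataFrame
    rna_only_sites: pd.DataFrame
    subgroup_labels: pd.Series  # sample -> {"highrisk", "lowrisk"}
    deregulated_pathways: list[str]
    hazard_params: HazardParams


@dataclass
class Cohort:
    """One synthetic cohort: site tables, expression, pathways, clinic, truth."""

    config: CohortConfig
    genes: pd.DataFrame  # gene, chrom, start, end, length, expressed
    dna_sites: pd.DataFrame  # pooled site table, one row per (sample, site)
    rna_sites: pd.DataFrame
    expression_counts: pd.DataFrame  # genes x samples (tumors + normals)
    gene_lengths: pd.Series
    pathways: list[PathwayDefinition]
    clinical: pd.DataFrame  # indexed by sample id
    truth: CohortTruth

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.clinical.index)

    @property
    def normal_ids(self) -> list[str]:
        return [f"{s}N" for s in self.clinical.index]


def _alleles_for_positions(pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic ref/alt per genomic position, identical across samples/modalities."""
    h = (pos.astype(np.uint64) * np.uint64(2654435761)) >> np.uint64(7)
    ref_idx = (h % np.uint64(4)).astype(np.int64)
    alt_idx = (ref_idx + 1 + (pos % 3)) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


def _negbin(rng: np.random.Generator, mean: float, disp: float, size: int) -> np.ndarray:
    if size == 0:
        return np.zeros(0, dtype=np.int64)
    p = disp / (disp + mean)
    return rng.negative_binomial(disp, p, size=size).astype(np.int64)


def simulate_survival(
    subgroup_labels: pd.Series, hazard_params: HazardParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Event/censoring times under an exponential proportional-hazards model.

    High-risk samples get hazard ``baseline * hazard_ratio``.  Censoring
    times are uniform on (5% of, 100% of) ``censor_time_max``, mimicking
    staggered accrual.  Returns a DataFrame indexed like ``subgroup_labels``
    with ``status`` (1 = event observed) and ``ttlf`` (years).
    """
    n = len(subgroup_labels)
    if n == 0:
        raise ValueError("no samples to simulate survival for")
    high = (subgroup_labels == hazard_params.highrisk_label).to_numpy()
    hazard = hazard_params.baseline_hazard * np.where(high, hazard_params.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.05 * hazard_params.censor_time_max, hazard_params.censor_time_max, n)
    status = (t_event <= t_cens).astype(int)
    ttlf = np.maximum(np.minimum(t_event, t_cens), 1e-3)
    return pd.DataFrame({"status": status, "ttlf": ttlf}, index=subgroup_labels.index)


def _plant_sample_sites(
    rng: np.random.Generator,
    sample: str,
    cfg: CohortConfig,
    genes: pd.DataFrame,
    expressed_mask: np.ndarray,
    driver_idx: np.ndarray,
    driver_events: list[tuple[int, int]],
    highrisk: bool,
) -> pd.DataFrame:
    """All candidate sites planted for one tumor/normal pair (every kind)."""
    starts = genes["start"].to_numpy()
    names = genes["gene"].to_numpy()
    n_genes = len(genes)
    rows: list[pd.DataFrame] = []

    mult = (cfg.mut_rate_highrisk_mult if highrisk else 1.0) * np.exp(rng.normal(0.0, 0.12))

    def _make(kind: str, gidx: np.ndarray, pos: np.ndarray, func: np.ndarray,
              daf: np.ndarray, raf: np.ndarray, transmitted: np.ndarray,
              driver: np.ndarray, dna_state: np.ndarray | None = None) -> pd.DataFrame:
        ref, alt = _alleles_for_positions(pos)
        return pd.DataFrame(
            {
                "sample": sample,
                "chrom": "1",
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene": names[gidx],
                "func_class": func,
                "kind": kind,
                "gene_expressed": expressed_mask[gidx],
                "expressed": transmitted,
                "true_dna_af": daf,
                "true_rna_af": raf,
                "driver": driver,
                "dna_state": dna_state if dna_state is not None else np.full(len(pos), "somatic"),
            }
        )

    def _func_classes(n: int, coding: bool) -> np.ndarray:
        if not coding:
            return np.full(n, "other", dtype=object)
        func = np.where(rng.random(n) < cfg.frac_nonsyn, "nonsynonymous", "synonymous").astype(object)
        stop = (func == "nonsynonymous") & (rng.random(n) < cfg.frac_stopgain)
        func[stop] = "stopgain"
        return func

    transmit_p = cfg.rna_transmit_prob_highrisk if highrisk else cfg.rna_transmit_prob

    def _somatic_block(n: int, coding: bool) -> pd.DataFrame:
        gidx = rng.integers(0, n_genes, n)
        if cfg.frac_drivers > 0 and len(driver_idx):
            to_driver = rng.random(n) < cfg.frac_drivers
            gidx[to_driver] = rng.choice(driver_idx, to_driver.sum())
        pos = starts[gidx] + rng.integers(0, cfg.gene_length, n)
        func = _func_classes(n, coding)
        clon = rng.beta(6.0, 2.0, n)
        daf = 0.5 * cfg.tumor_purity_true * clon
        transmitted = expressed_mask[gidx] & (rng.random(n) < transmit_p)
        raf = np.where(
            transmitted,
            np.clip(daf + rng.normal(cfg.ase_skew, cfg.ase_sd, n), 0.02, 0.95),
            0.0,
        )
        return _make("somatic", gidx, pos, func, daf, raf, transmitted,
                     np.isin(gidx, driver_idx))

    # recurrent driver hits first so site de-duplication keeps them
    if driver_events:
        dg = np.array([g for g, _ in driver_events])
        pos = np.array([p for _, p in driver_events])
        n_drv = len(dg)
        clon = rng.beta(12.0, 2.0, n_drv)
        daf = 0.5 * cfg.tumor_purity_true * clon
        raf = np.clip(daf + rng.normal(cfg.ase_skew, cfg.ase_sd, n_drv), 0.02, 0.95)
        rows.append(
            _make("somatic", dg, pos, np.full(n_drv, "nonsynonymous"), daf, raf,
                  np.ones(n_drv, bool), np.ones(n_drv, bool))
        )

    n_coding = rng.poisson(cfg.somatic_rate_dna * mult)
    if n_coding:
        rows.append(_somatic_block(n_coding, coding=True))
    n_nc = rng.poisson(cfg.somatic_rate_dna * cfg.noncoding_ratio * mult)
    if n_nc:
        rows.append(_somatic_block(n_nc, coding=False))

    n_germ = rng.poisson(cfg.germline_rate)
    if n_germ:
        gidx = rng.integers(0, n_genes, n_germ)
        pos = starts[gidx] + rng.integers(0, cfg.gene_length, n_germ)
        func = _func_classes(n_germ, coding=True)
        half = np.full(n_germ, 0.5)
        raf = np.where(expressed_mask[gidx], 0.5, 0.0)
        rows.append(_make("germline", gidx, pos, func, half, raf,
                          expressed_mask[gidx], np.zeros(n_germ, bool)))

    n_rna = rng.poisson(cfg.rna_only_rate)
    if n_rna:
        expr_idx = np.flatnonzero(expressed_mask)
        gidx = rng.choice(expr_idx, n_rna)
        pos = starts[gidx] + rng.integers(0, cfg.gene_length, n_rna)
        coding = rng.random(n_rna) < 0.14
        func = np.full(n_rna, "other", dtype=object)
        func[coding] = _func_classes(int(coding.sum()), coding=True)
        raf = rng.uniform(0.15, 0.6, n_rna)
        state = rng.choice(
            ["reference", "germline", "lowcov", "subthreshold"],
            n_rna,
            p=[0.82, 0.10, 0.04, 0.04],
        )
        daf = np.where(state == "germline", 0.5, np.where(state == "subthreshold", 0.09, 0.0))
        rows.append(_make("rna_only", gidx, pos, func, daf, raf,
                          np.ones(n_rna, bool), np.zeros(n_rna, bool), dna_state=state))

    if not rows:
        return pd.DataFrame()
    planted = pd.concat(rows, ignore_index=True)
    # one record per (pos, alt) within the sample
    return planted.drop_duplicates(subset=["pos", "alt"], keep="first").reset_index(drop=True)


def _draw_counts(rng: np.random.Generator, planted: pd.DataFrame, cfg: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomial read counts for both modalities at every planted site."""
    n = len(planted)
    kind = planted["kind"].to_numpy()
    state = planted["dna_state"].to_numpy()
    gene_expr = planted["gene_expressed"].to_numpy()
    daf = planted["true_dna_af"].to_numpy()
    raf = planted["true_rna_af"].to_numpy()

    # --- DNA ---
    dn = _negbin(rng, cfg.dna_depth_mean, cfg.depth_dispersion, n)
    dt = _negbin(rng, cfg.dna_depth_mean, cfg.depth_dispersion, n)
    lowcov = (kind == "rna_only") & (state == "lowcov")
    subthr = (kind == "rna_only") & (state == "subthreshold")
    dn[lowcov] = rng.poisson(3.0, int(lowcov.sum()))
    dt[lowcov] = rng.poisson(3.0, int(lowcov.sum()))
    # shallow DNA depth keeps a real variant below Fisher significance
    dn[subthr] = _negbin(rng, 12.0, cfg.depth_dispersion, int(subthr.sum()))
    dt[subthr] = _negbin(rng, 12.0, cfg.depth_dispersion, int(subthr.sum()))

    dna_taf = np.where(kind == "somatic", daf, 0.0)
    dna_taf = np.where(kind == "germline", 0.5, dna_taf)
    dna_taf = np.where((kind == "rna_only") & np.isin(state, ["germline", "subthreshold"]), daf, dna_taf)
    dna_naf = np.where((kind == "germline") | ((kind == "rna_only") & (state == "germline")), 0.5, cfg.seq_error)
    dna_alt_t = rng.binomial(dt, np.clip(dna_taf + cfg.seq_error, 0, 1))
    dna_alt_n = rng.binomial(dn, np.clip(dna_naf, 0, 1))

    # --- RNA ---
    rn = np.where(gene_expr, _negbin(rng, cfg.rna_depth_mean, cfg.depth_dispersion, n), rng.poisson(0.1, n))
    rt = np.where(gene_expr, _negbin(rng, cfg.rna_depth_mean, cfg.depth_dispersion, n), rng.poisson(0.1, n))
    rna_taf = np.where(kind == "somatic", raf, 0.0)
    rna_taf = np.where(kind == "germline", np.where(gene_expr, 0.5, 0.0), rna_taf)
    rna_taf = np.where(kind == "rna_only", raf, rna_taf)
    artifact = (kind == "somatic") & (raf > 0) & (rng.random(n) < cfg.rna_germline_artifact)
    rna_naf = np.where((kind == "germline") & gene_expr, 0.5, cfg.seq_error)
    rna_naf = np.where(artifact, raf, rna_naf)
    rna_alt_t = rng.binomial(rt, np.clip(rna_taf + cfg.seq_error, 0, 1))
    rna_alt_n = rng.binomial(rn, np.clip(rna_naf, 0, 1))

    base = planted[["sample", "chrom", "pos", "ref", "alt", "gene", "func_class"]]
    dna = base.copy()
    dna["normal_ref"], dna["normal_alt"] = dn - dna_alt_n, dna_alt_n
    dna["tumor_ref"], dna["tumor_alt"] = dt - dna_alt_t, dna_alt_t
    rna = base.copy()
    rna["normal_ref"], rna["normal_alt"] = rn - rna_alt_n, rna_alt_n
    rna["tumor_ref"], rna["tumor_alt"] = rt - rna_alt_t, rna_alt_t
    return dna, rna


def _expression(
    rng: np.random.Generator,
    cfg: CohortConfig,
    genes: pd.DataFrame,
    pathways: list[PathwayDefinition],
    dereg_ids: list[str],
    tumor_ids: list[str],
    normal_ids: list[str],
    highrisk: pd.Series,
) -> pd.DataFrame:
    """Raw count matrix (genes x tumors+normals) with planted deregulation."""
    n_genes = len(genes)
    expressed = genes["expressed"].to_numpy()
    mu = np.where(expressed, rng.normal(5.0, 1.5, n_genes), -6.0)

    # mild global tumor/normal differences so tumors sit off the normal reference
    tumor_shift = np.zeros(n_genes)
    shifted = expressed & (rng.random(n_genes) < 0.10)
    tumor_shift[shifted] = rng.normal(0.0, 0.8, int(shifted.sum()))

    gene_pos = {g: i for i, g in enumerate(genes["gene"])}
    dereg_shift = np.zeros(n_genes)
    for pw in pathways:
        if pw.pathway_id in dereg_ids:
            for g in pw.genes:
                i = gene_pos[g]
                if dereg_shift[i] == 0.0:
                    dereg_shift[i] = cfg.dereg_effect * rng.choice([-1.0, 1.0])

    samples = tumor_ids + normal_ids
    libsize = 2e7 * np.exp(rng.normal(0.0, 0.1, len(samples)))
    length_kb = genes["length"].to_numpy() / 1000.0
    X = np.empty((n_genes, len(samples)))
    for j, s in enumerate(samples):
        x = mu + rng.normal(0.0, 0.3, n_genes)
        if s in tumor_ids:
            x = x + tumor_shift
            if bool(highrisk.get(s, False)):
                x = x + dereg_shift
        lam = np.clip(2.0**x, 0, None) * length_kb * (libsize[j] / 1e6)
        X[:, j] = rng.poisson(lam)
    return pd.DataFrame(
        X.astype(np.int64), index=pd.Index(genes["gene"], name="gene"), columns=samples
    )


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a full synthetic cohort (site tables, expression, clinic, truth)."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)

    # gene model: non-overlapping single-exon genes on one chromosome, 1-based
    n_drv = len(cfg.driver_genes)
    names = list(cfg.driver_genes) + [f"G{i:05d}" for i in range(n_drv, cfg.n_genes)]
    starts = 1 + np.arange(cfg.n_genes, dtype=np.int64) * (cfg.gene_length + 500)
    expressed = rng.random(cfg.n_genes) < cfg.frac_genes_expressed
    expressed[:n_drv] = True  # drivers are always expressed
    genes = pd.DataFrame(
        {
            "gene": names,
            "chrom": "1",
            "start": starts,
            "end": starts + cfg.gene_length - 1,
            "length": cfg.gene_length,
            "expressed": expressed,
        }
    )
    driver_idx = np.arange(n_drv)
    hotspots = {
        names[i]: starts[i] + np.array([cfg.gene_length // 3, (2 * cfg.gene_length) // 3])
        for i in driver_idx
    }

    # samples and planted subgroup
    tumor_ids = [f"T{i + 1:02d}" for i in range(cfg.n_pairs)]
    n_high = int(round(cfg.frac_highrisk * cfg.n_pairs))
    high_set = set(rng.permutation(tumor_ids)[:n_high])
    labels = pd.Series(
        ["highrisk" if s in high_set else "lowrisk" for s in tumor_ids],
        index=tumor_ids,
        name="subgroup",
    )
    highrisk = labels == "highrisk"

    # assign each driver gene's target recurrence to samples, biased toward
    # the high-risk subgroup, one hotspot hit per chosen sample
    driver_events: dict[str, list[tuple[int, int]]] = {s: [] for s in tumor_ids}
    weights = np.where(highrisk.to_numpy(), cfg.driver_highrisk_weight, 1.0)
    weights = weights / weights.sum()
    for gi, target in zip(driver_idx, cfg.driver_recurrence):
        if target == 0:
            continue
        chosen = rng.choice(tumor_ids, size=min(target, cfg.n_pairs), replace=False, p=weights)
        for s in chosen:
            driver_events[s].append((int(gi), int(rng.choice(hotspots[names[gi]]))))

    planted_all: list[pd.DataFrame] = []
    dna_all: list[pd.DataFrame] = []
    rna_all: list[pd.DataFrame] = []
    for s in tumor_ids:
        planted = _plant_sample_sites(
            rng, s, cfg, genes, expressed, driver_idx, driver_events[s], bool(highrisk[s])
        )
        if len(planted) == 0:
            continue
        dna, rna = _draw_counts(rng, planted, cfg)
        planted_all.append(planted)
        dna_all.append(dna)
        rna_all.append(rna)

    empty_sites = pd.DataFrame(
        columns=["sample", "chrom", "pos", "ref", "alt", "gene", "func_class",
                 "normal_ref", "normal_alt", "tumor_ref", "tumor_alt"]
    )
    planted = (
        pd.concat(planted_all, ignore_index=True) if planted_all else pd.DataFrame()
    )
    dna_sites = pd.concat(dna_all, ignore_index=True) if dna_all else empty_sites.copy()
    rna_sites = pd.concat(rna_all, ignore_index=True) if rna_all else empty_sites.copy()

    # pathways drawn from expressed genes; the first n_dereg are deregulated
    expr_genes = genes.loc[genes["expressed"], "gene"].to_numpy()
    pathways = []
    for i in range(cfg.n_pathways):
        members = rng.choice(expr_genes, size=min(cfg.genes_per_pathway, len(expr_genes)), replace=False)
        pid = f"PW{i + 1:03d}"
        pathways.append(PathwayDefinition(pid, f"synthetic pathway {i + 1}", list(members)))
    dereg_ids = [pw.pathway_id for pw in pathways[: cfg.n_dereg_pathways]]

    normal_ids = [f"{s}N" for s in tumor_ids]
    counts = _expression(rng, cfg, genes, pathways, dereg_ids, tumor_ids, normal_ids, highrisk)

    # clinical covariates loosely matching a stage-I adenocarcinoma series
    hz = HazardParams(cfg.hazard_baseline, cfg.hazard_ratio_true, cfg.censor_time_max)
    surv = simulate_survival(labels, hz, rng)
    age = np.clip(rng.normal(66.0, 12.0, cfg.n_pairs), 30, 95).round(0)
    sex = np.where(rng.random(cfg.n_pairs) < 23 / 27, "Female", "Male")
    stage = np.where(rng.random(cfg.n_pairs) < 10 / 27, "IA", "IB")
    cell = np.where(
        (~highrisk.to_numpy()) & (rng.random(cfg.n_pairs) < 0.25), "BAC", "AD"
    )
    diff = np.where(
        rng.random(cfg.n_pairs) < np.where(highrisk.to_numpy(), 0.5, 0.1), "Mod", "Well"
    )
    clinical = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "stage": stage,
            "cell_type": cell,
            "differentiation": diff,
            "status": surv["status"],
            "ttlf": surv["ttlf"].round(4),
        },
        index=pd.Index(tumor_ids, name="sample"),
    )

    if len(planted):
        somatic = planted[planted["kind"] == "somatic"].drop(columns=["kind", "dna_state"]).reset_index(drop=True)
        germ = planted[planted["kind"] == "germline"].drop(columns=["kind", "dna_state"]).reset_index(drop=True)
        rna_only = planted[planted["kind"] == "rna_only"].drop(columns=["kind"]).reset_index(drop=True)
    else:
        somatic = germ = rna_only = planted
    truth = CohortTruth(somatic, germ, rna_only, labels, dereg_ids, hz)

    return Cohort(
        config=cfg,
        genes=genes,
        dna_sites=dna_sites,
        rna_sites=rna_sites,
        expression_counts=counts,
        gene_lengths=pd.Series(cfg.gene_length, index=counts.index, name="length"),
        pathways=pathways,
        clinical=clinical,
        truth=truth,
    )
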