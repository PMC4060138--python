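# concordmut

Analysis pipeline for somatic mutations conserved between tumor DNA
(exome-seq) and tumor RNA (mRNA-seq) in paired tumor/normal cohorts — with
per-gene recurrence, pathway deregulation scoring against normal
references, and survival association — plus a synthetic-cohort simulator
that plants a recoverable ground truth for every stage.

## The problem

In a small tumor cohort, DNA sequencing reports hundreds to thousands of
somatic point mutations per tumor, most of them passengers, many in genes
the tissue never expresses. Mutations observed in **both** DNA and RNA at
the same genomic position with the same alternate allele ("conserved"
mutations) are a far smaller set, enriched for variants that actually reach
the transcript — and hence for drivers. This package implements that
filter-and-associate analysis end to end for anyone with per-site allele
counts in two modalities, a gene expression matrix, pathway definitions
(GMT) and a clinical table.

## The model

**Somatic calling.** For a site with normal counts (r_N, a_N) and tumor
counts (r_T, a_T), the somatic statistic is the one-sided Fisher exact
p-value — the upper-tail hypergeometric probability
P(X ≥ a_T) with X ~ Hypergeom(N = d_N + d_T, K = a_N + a_T, n = d_T) —
and a site is Somatic when the normal is non-variant (VAF < 0.08), the
tumor is variant (VAF ≥ 0.08), p < 0.05, and coverage is at least 8 (normal)
and 6 (tumor). Sites are otherwise Germline, LOH, Reference, or
InsufficientCoverage.

**Concordance and backfill.** Per sample, DNA and RNA somatic calls are
intersected on (chrom, pos, alt) and restricted to protein-altering
classes. Single-modality calls are explained by re-reading the other
modality's counts: NotCovered / Germline / Reference / SomaticSubthreshold
/ Other.

**Pathway deregulation.** For each pathway, log2 RPKM expression of the
member genes is z-scored and reduced by PCA; a principal curve
(Hastie–Stuetzle) is threaded through all samples; a sample's score is its
arc-length offset from the normal-sample reference position, normalized so
scores lie in [0, 1] with normal median exactly 0. Pathways with score
SD ≤ 0.2 across tumors are dropped; samples are clustered on
1 − Pearson correlation with centroid linkage.

**Clinical association.** Kruskal-Wallis (loads by cluster), exact 2×k
contingency tests (cluster composition), Pearson correlation (load vs mean
deregulation score), Kaplan-Meier + log-rank, and univariate Cox
proportional hazards (HR per additional conserved mutation).

See `docs/methods.md` for assumptions, parameter defaults, and what the
synthetic generator does and does not emulate.

## Worked example

```python
import concordmut as cm

cohort = cm.generate_cohort(cm.CohortConfig(seed=1))   # 27 tumor/normal pairs
analysis = cm.analyze_cohort(cohort)

loads = analysis.loads
print("mean somatic SNVs per tumor (DNA):", round(loads["n_total"].mean(), 1))
print("conserved nonsynonymous mutations:", len(analysis.concordant))

n_hi, n_tot, pct = cm.preferential_expression_summary(analysis.concordant)
print(f"higher VAF in RNA: {n_hi}/{n_tot} ({pct}%)")

print(analysis.recurrence.head(3).to_string(index=False))

r, p = cm.pearson_load_vs_score(loads["overlap_nonsyn"], analysis.mean_score)
print(f"r(conserved load, mean deregulation score) = {r:.2f} (p = {p:.1e})")
curves, lr = cm.km_logrank(cohort.clinical, analysis.clusters)
print(f"log-rank across clusters: chi2 = {lr.statistic:.2f}, p = {lr.p_value:.4f}")
```

prints

```
mean somatic SNVs per tumor (DNA): 1271.7
conserved nonsynonymous mutations: 442
higher VAF in RNA: 412/442 (93%)
  gene  n_samples_mutated  n_samples_total  frequency
  EGFR                  4               27  14.814815
SPTAN1                  4               27  14.814815
G00148                  3               27  11.111111
r(conserved load, mean deregulation score) = 0.81 (p = 3.5e-07)
log-rank across clusters: chi2 = 14.80, p = 0.0006
```

Each tumor carries ~1,300 somatic SNVs in DNA (~25 per Mb over a 51 Mb
target), but only a handful of conserved nonsynonymous mutations
(~16/tumor here). Most conserved mutations have a higher allele fraction
in RNA than in DNA — the mutated allele is preferentially expressed. The
most recurrently mutated gene is hit in 4 of 27 tumors (14.8%), and the
conserved-mutation load tracks mean pathway deregulation (r = 0.81) while
the deregulation-based clusters separate survival — the generator plants
exactly this structure (a high-risk subgroup with more transmitted
mutations, stronger pathway shifts and a higher hazard), and the pipeline
recovers it.

The same stages are available from the shell:

```bash
concordmut simulate --seed 1 --n-pairs 27 --outdir sim/
concordmut call --sites sim/dna_sites.tsv --modality dna --out dna_calls.tsv
concordmut call --sites sim/rna_sites.tsv --modality rna --out rna_calls.tsv
concordmut overlap --dna dna_calls.tsv --rna rna_calls.tsv --out conserved.tsv
concordmut run --seed 1 --outdir results_run/   # everything, plus a manifest
```

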