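# Methods

`concordmut` implements a count-level reanalysis pipeline for paired
tumor/normal cohorts sequenced in two modalities (exome DNA and mRNA), built
around the idea that somatic point mutations observed in *both* DNA and RNA
("conserved" mutations) are enriched for functional drivers, while
DNA-only calls are dominated by passengers in unexpressed genes and
technical noise.

## Somatic classification

The atomic observation is a site with ref/alt read counts for a tumor and
its matched normal. A site is classified by a fixed ladder:

1. **InsufficientCoverage** if normal depth < 8 or tumor depth < 6;
2. **Germline** if the variant allele fraction (VAF) is ≥ `min_var_freq`
   (default 0.08) in both samples;
3. **Somatic** if the normal is non-variant, the tumor VAF ≥
   `min_var_freq`, and the one-sided Fisher exact p-value for alt
   enrichment in the tumor is strictly below 0.05;
4. **LOH** if the normal is heterozygous and the tumor has lost the variant
   with a significant lower-tail p (the drive-toward-homozygous-alt arm is
   subsumed by the Germline branch, which fires first);
5. **Reference** otherwise.

The somatic statistic is the exact upper-tail hypergeometric probability of
the observed tumor alt count given the 2×2 table margins — the same
conditional test a VarScan-style caller applies. The `purity` parameter
(default 0.8) scales the expected tumor heterozygote VAF
(`het_freq × purity`) used as the het/hom genotype boundary. `min_var_freq`
defaults to 0.08, matching the smallest VAF at which conserved mutations
are observed in practice; it is exposed in `CallingParams`.

The implementation is vectorized (`fisher_somatic_pvalues`,
`classify_table`); the scalar API (`classify_site`) shares the same code
path and the test suite checks row-for-row agreement plus exhaustive
agreement with a brute-force log-factorial tail enumeration over every
table with per-sample depths ≤ 60 (≈3.6M tables, tolerance 1e-10).

## Concordance and backfill

Two calls are concordant when they share sample, chromosome, position and
alternate allele; only protein-altering classes (nonsynonymous, stopgain,
stoploss) are kept for downstream summaries. "Preferential expression"
counts conserved mutations whose RNA VAF strictly exceeds their DNA VAF
(ties excluded).

Calls private to one modality are *backfilled*: the other modality's raw
counts at the position are re-examined and the call is attributed to the
first matching rung of NotCovered (absent or below the coverage
thresholds), Germline (variant in both tumor and normal), Reference (tumor
non-variant), SomaticSubthreshold (tumor variant, clean normal, Fisher
p ≥ 0.05), or Other. The coverage thresholds are the calling thresholds,
unchanged. Categories partition the discordant calls by construction.

## Pathway deregulation scores

For each pathway (GMT input), expression is taken as
log2 RPKM = log2(count × 1e9 / (length_bp × library_size) + offset),
restricted to the pathway's genes with nonzero variance (≥ 3 required),
z-scored per gene, and reduced by PCA to `n_pca_components` (default 3,
automatically reduced for small pathways). A principal curve is fitted
through all samples (tumors and normals) by the Hastie–Stuetzle
alternation: initialize the parameter as the first principal component
score, then repeat (a) smooth each coordinate against the parameter,
(b) project the samples onto the resulting polyline, (c) reparameterize by
arc length, until the mean squared projection distance changes by less
than `curve_tol` (relative, default 1e-4) or 50 iterations.

The scatterplot smoother is a Gaussian-kernel local-linear regression with
bandwidth `curve_span` × the parameter range (default 0.2). A local
*linear* smoother reproduces collinear point clouds exactly (so lines are
fixed points of the iteration), has no knot-placement or penalty-selection
machinery, and is fast enough to refit thousands of curves in the
replicate-based test suite; the measured approximation error on a noiseless
quadratic arc at span 0.1 is ≈0.03 rms against an arc of height 0.8.

A sample's raw score is the absolute arc-length offset of its projection
from the median projection of the normal samples. Raw scores are recentred
by the *upper median* of the normal offsets, clipped at zero, and divided
by their maximum, which enforces three contract properties exactly: scores
lie in [0, 1], the per-pathway maximum is 1, and the median normal score is
0 (the upper median guarantees this for even as well as odd reference
counts). Gene-wise z-scoring makes scores invariant to positive rescaling
of the expression submatrix. Degenerate pathways (all samples identical)
score 0 everywhere; pathways with fewer than 3 resolvable variable genes
are skipped with a logged warning.

Pathways whose score standard deviation across tumors is ≤ `sd_min`
(default 0.2, strict inequality to retain) are dropped before clustering.
Samples are clustered hierarchically on d(i,j) = 1 − Pearson(score_i,
score_j) with centroid linkage applied to that distance matrix as given —
centroid linkage is formally Euclidean, so occasional dendrogram inversions
are possible and accepted. The tree is cut at `n_clusters` (default 3,
mirroring a 2-main/3-sub cluster read of a deregulation heat map).

Gene-set over-representation for the conserved-mutation gene list is an
upper-tail hypergeometric test against a stated universe size.

## Clinical association

Mutation loads across clusters are compared by tie-corrected
Kruskal-Wallis; cluster composition by an exact conditional homogeneity
test (two-sided by the point-probability rule for 2×2 — the convention of
standard statistical software — and full enumeration of tables with fixed
margins for 2×k); load vs mean deregulation score by Pearson correlation;
survival by Kaplan-Meier with the log-rank test (χ², groups−1 df) and by a
univariate Cox proportional-hazards model (Efron tie handling; for a count
covariate the hazard ratio is per additional conserved mutation). The
survival wrappers sit on lifelines; the exact 2×k test is implemented here
because no installed package provides Fisher's exact test beyond 2×2, and
it is cross-checked against scipy's 2×2 implementation.

## Synthetic cohort generator

The generator (`CohortConfig`, `generate_cohort`) emulates the statistical
structure of a small stage-I adenocarcinoma cohort of never-smokers; its
defaults are the study conditions the tests and the acceptance script run
under. What it emulates, per tumor/normal pair (27 pairs by default):

- **Genome**: 2,000 non-overlapping single-exon genes of 1,500 bp on one
  chromosome, 1-based inclusive coordinates; ~60% of genes expressed; the
  ref/alt alleles at a position are a deterministic function of the
  position so recurrent and cross-modality hits always carry the same
  alternate allele. One alternate allele per site; indels, copy number and
  subclonal structure are out of scope.
- **Somatic SNVs**: coding events at Poisson rate `somatic_rate_dna`
  (default 102/tumor) plus non-coding events at `noncoding_ratio` (10.2)
  times that rate, giving ≈1,270 somatic SNVs per tumor (≈25/Mb over a
  51 Mb target), ~77 of them nonsynonymous — inside the hundreds-to-
  thousands range such cohorts report. True DNA VAF = 0.5 × purity ×
  clonality with clonality ~ Beta(6,2). Read depths are negative binomial
  (means 80 DNA / 60 RNA, dispersion 8) so under-covered sites exist; alt
  counts are binomial at the true VAF plus a 1e-3 error rate.
- **Expression coupling**: a somatic allele reaches the transcript with
  probability 0.25 (low-risk tumors) or 0.5 (high-risk); transmitted
  alleles gain `ase_skew` = 0.15 mean RNA-over-DNA VAF (sd 0.05), so most
  conserved mutations look preferentially expressed. Unexpressed genes get
  ~zero RNA coverage. RNA-only artifact calls (850/tumor) are planted with
  DNA ground states in paper-like proportions (reference 82%, germline
  10%, low coverage 4%, subthreshold 4%); germline heterozygous sites
  (300/tumor, VAF 0.5 in both tissues) populate the Germline backfill rung
  and the caller's specificity check.
- **Drivers**: ten named driver genes carry hotspot mutations planted at
  explicit recurrence targets (4,3,3,3,2,2,2,2,2,2 samples), assigned with
  4× sampling weight toward the planted high-risk subgroup, always
  expressed and transmitted.
- **Subgroup structure**: ~40% of tumors are "high-risk": 1.3× somatic
  rate, the higher transmission probability, a +1 log2 expression shift
  (random sign per gene) on 12 of 50 pathways, and a 5× hazard. Survival
  times are exponential with baseline 0.15/yr, censored uniformly within
  12 years; status is 0/1 with time-to-last-follow-up in years. The large
  default hazard ratio is a detectability choice: with 27 patients a
  log-rank test has adequate power only for a large group effect, and the
  generator's job is to give the pipeline a recoverable signal. Parameter-
  recovery tests use HR 1 and 3 at n = 200–2,000, where the Cox estimate
  must land within 3 standard errors of the truth.

All draws flow through a single `numpy` Generator seeded from
`CohortConfig.seed`; identical configurations reproduce byte-identical
outputs. The planted truth (per-site VAFs, expression flags, subgroup
labels, deregulated pathway ids, hazard parameters) is returned for
recovery testing.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: alignment and mapping artifacts, strand bias,
RNA editing, tumor subclonality, gene-length and GC biases in coverage,
correlated expression structure beyond the planted pathway shifts, and
recurrence arising from mutational processes rather than planted hotspots.
Recovery rates on this generator are upper bounds on real-data
performance.

## Numerical and design choices

- Fisher/hypergeometric p-values come from scipy's exact hypergeometric
  tail; ties at the significance threshold are non-calls (strictly less
  than 0.05 required).
- The somatic test is one-sided (tumor alt enrichment), matching the
  directionality of a somatic caller; the contingency test for cluster
  composition is two-sided.
- Curve fitting stops on relative MSE change < 1e-4 or at an absolute MSE
  below 1e-12 (exact-fit short-circuit for collinear data).
- Multi-allelic VCF rows are split into one observation per alternate
  allele at read time; chromosome naming is taken as-is (no silent "chr"
  normalization).
- Rounding is display-only (one decimal for recurrence tables, nearest
  integer for the preferential-expression percentage); full precision is
  retained internally.
- No multiple-testing correction is applied across the association report
  by default.

## Problem sizes in the test suite

The acceptance suite runs the full pipeline on 50 seeded default cohorts
for the cohort-level reproduction checks, exhaustively sweeps all 2×2
tables with per-sample depths ≤ 60 for oracle equivalence, uses n = 2,000
for Cox recovery and 100 replicates of n = 200 for log-rank power, and one
default cohort for the caller-recovery and score-contract checks. The
acceptance script reports the same quantities from freshly generated
cohorts (20 replicates for the stability fractions).

## Known limitations

- The retained-pathway count depends on the synthetic deregulation
  strength; the SD > 0.2 filter is calibrated to [0,1]-normalized scores,
  not to any particular real cohort.
- Centroid linkage on a correlation distance is a faithful reproduction of
  the configured method, not a recommendation; Ward or average linkage on
  Euclidean distances is statistically cleaner.
- The exact 2×k homogeneity test enumerates all tables with the observed
  margins and is practical only for small cohorts (k ≤ ~5, n ≤ ~100).
- `snv_agreement` compares position/allele maps and leaves the choice of
  which variant sets to compare (somatic-only vs all variant sites) to the
  caller.
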