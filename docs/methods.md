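# Methods

This note records the models, parameter choices, numerical conventions
and known limitations behind `cnvmeth`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and containers

All intervals are 0-based half-open internally; BED and genePred keep
their native conventions at I/O. The TSS of a − strand gene is its
`txEnd` (the half-open end), so the strand-aware promoter window
[TSS−1500, TSS+500) maps to [TSS−500, TSS+1500) in genome coordinates on
the − strand. Normalized read depth is dimensionless with diploid ≙ 2.
Methylation counts are held as paired coverage/methylated matrices with
NaN for *missing* cells — a site a sample did not cover — which is
deliberately distinct from an observed coverage of zero.

## CNV consensus and genotyping

**Caller filters.** Callers are typed by evidence
(`read_depth`, `paired`, `split`, `paired_split`). Paired-read calls are
kept at per-sample coverage ≤ 50× and ≥ 4 supporting pairs; paired+split
calls at mapping quality strictly > 20, ≥ 2 supporting reads, length
≤ 500 kb. Read-depth-only and split-read-only calls pass unchanged at
this stage (the depth cascade below is their filter).

**Consensus.** The overlap fraction is one-way, measured against the
read-depth caller's call length, boundary inclusive (≥ 0.5). Output
regions always carry the read-depth caller's breakpoints.

**Depth summary.** Per-region per-sample depth is the overlap-weighted
mean of window values (median available via
`PipelineConfig.region_depth_summary`); windows are 500 bp.

**Genotyping.** Depth cutoffs define half-open copy-number bins of width
1 centered on integers ([1.5, 2.5) → 2, ties at x.5 to the higher bin).
On top of the cutoffs, candidate partitions of the per-sample region
means are formed: the cutoff-bin partition itself plus k-means solutions
for k ∈ 2..min(10, n−1) (10 restarts, seeded). A candidate is
*genotype-consistent* when every cluster center lies within 0.35 of a
distinct non-negative integer; among consistent candidates the highest
Calinski–Harabasz index wins (a zero-within-dispersion partition scores
+∞), and samples receive their cluster's integer. A region with no
consistent candidate is excluded with reason `cluster-genotype mismatch`.

Two remarks on why the rule is shaped this way. First, the CH index in
one dimension often prefers splitting a tight Gaussian cluster in two;
selecting the best-CH candidate *before* checking genotype consistency
would reject nearly every region because the split halves both round to
the same integer. Screening for consistency first, then ranking, keeps
model selection meaningful. Second, the cutoff-bin partition must be a
candidate in its own right: with few samples at clean integer depths,
no k-means solution in the allowed k range matches all integers, yet the
cutoffs alone genotype the region perfectly. The 0.35 tolerance is the
package's deterministic replacement for per-region manual cutoff review;
it is configurable (`cluster_match_tolerance`).

**Sex-specific CNVs** are flagged when all carriers (copy number ≠ 2)
are of one sex with ≥ 2 carriers, and excluded downstream; singleton
carriers are uninformative about sex linkage and never flagged.

**Gene CNVs.** Overlap ≥ 90% of the gene length is *full*, less is
*partial*; gene intervals are then re-filtered with the same three depth
conditions computed on the gene's own coordinates, and each surviving
gene inherits copy numbers from its best-overlapping region.

## V_st

Unbiased (n−1) variance estimators; V_pop is the unweighted mean of the
two within-population variances (a sample-size-weighted version is
available, `vst_weighted`). V_st is reported as computed — negative
values are not clamped — and is missing when V_tot = 0. The outlier rule
pools all pairwise values across regions (reading "top 2% of all
pairwise values" literally; a per-pair pool is a config change away),
takes the top 2% by rank with ties included, and intersects with
V_st > 0.1.

## Methylation processing and DMS

Coverage filtering blanks cells under 10 reads or above the sample's
99.9th coverage percentile. Coverage normalization scales every sample
toward the cohort's median of per-sample median coverages, rounding
half-up and restoring `methylated ≤ coverage`; per-cell proportions move
by less than 1/coverage. Uniting requires ≥ 11 covered samples in every
population and ≤ 30% missing cells overall. SNP exclusion removes listed
C>T / G>A positions; sex-chromosome sites are dropped wholesale. CpG
dyads are not destranded; counts stay as provided.

The per-site test is a binomial logistic-regression likelihood-ratio
test of methylated/unmethylated counts on population membership. With a
single two-level factor the group MLE is the pooled per-group
proportion, so the deviance has a closed form and is computed vectorized
from group totals; no iterative fitting is involved and no
overdispersion correction is applied by default. Multiple testing uses
Benjamini–Hochberg within each population pair. The reported difference
is the pooled (coverage-weighted) difference in percentage points. DMS
require |difference| ≥ 15 and q ≤ 0.0125; population-specific DMS are
flagged in all five pairwise comparisons involving that population.

## Integration

Correlations are Pearson across individuals per gene, requiring ≥ 3
informative samples and non-zero variance on both vectors; anything less
is reported *untestable* rather than r = 0. BH correction is applied
within scope (global, or one population when the analysis is restricted).

The permutation overlap test counts DMS positions inside the union of
the tested intervals, then re-places every interval (keeping its length)
uniformly at random — chromosome drawn proportional to length among
chromosomes the interval fits (chromosome-matched placement is
available), start uniform over feasible positions — and recomputes the
count; empirical p = (#{null ≥ observed} + 1)/(N + 1), which floors at
1/(N+1) and never returns zero. Intervals longer than every chromosome
are an error.

The "low-frequency CNV" chi-square uses a carrier-frequency cutoff of
0.05 (5%) by default; the test applies no continuity correction so the
statistic equals the textbook Σ(O−E)²/E. Mann-Whitney comparisons are
two-sided.

## The synthetic cohort

`SimulationConfig` defaults define the study design; all randomness
flows from one seeded generator, so a fixed seed reproduces the bundle
byte-for-byte.

* **Cohort**: 6 populations × 16 diploid individuals with per-population
  salinity annotations (4.3–28.9 PSU) and balanced sexes.
* **Genome**: four 3-Mb autosomes plus a 2-Mb sex chromosome; 300 genes
  placed without overlap, typed lineage-specific (19%), paralog (63%),
  singleton (18%).
* **CNV truth**: 200 loci (47% deletions), lengths log-normal around
  4–7 kb, breakpoints aligned to the 500-bp depth-window grid; half the
  loci are placed on genes. Genotypes are Hardy–Weinberg draws from
  per-population allele frequencies, giving bi-allelic states {0,1,2} or
  {2,3,4}. Frequencies mix an explicit singleton component (55% of
  ordinary loci have exactly one heterozygous carrier — no single Beta
  prior yields realistic singleton proportions without most loci having
  zero carriers) with a Beta(0.5, 8) common tail. Five loci are
  *differentiated*: allele frequency 0.8 in one population, 0.05
  elsewhere. Five loci at 25 records stay within the ~30-record capacity
  of a top-2% outlier rule on this cohort's ≈1400 finite pairwise V_st
  values; planting more would cap recall below 1 by construction and
  test the rank cutoff rather than the scan. Three sex-specific loci sit
  on the sex chromosome with all-male carriers (hemizygous-like states);
  hemizygosity is emulated only at these loci, not as a whole-chromosome
  male depth shift.
* **Depth**: simulated directly on the normalized scale — window depth =
  true copy number + N(0, 0.2) truncated at 0 — then multiplied by a
  per-sample library factor that `normalize_depth` removes. The noise sd
  0.2 is a free parameter chosen so genotyping is challenging but
  solvable; real data's depth dispersion is cohort-specific.
* **Callers**: each truth locus is emitted per caller with sensitivity
  0.9–0.97 and Gaussian breakpoint jitter (read-depth caller snapped
  back to its window grid); evidence fields are drawn so caller filters
  reject a realistic minority; false positives (5% of true calls per
  caller, diploid everywhere) are added and die in the depth cascade.
* **Methylation**: CpGs are placed in promoter clusters (40% of genes,
  mirroring the fact that fewer than half of genes have promoter CpGs
  captured by RRBS), gene-body clusters (60%), and intergenic clusters.
  Counts are beta-binomial (precision 30) around class means — promoter
  0.30, lineage-specific promoters 0.55, gene body 0.70, intergenic
  0.58 — with Poisson(30) coverage, per-sample library scaling and 10%
  dropout. 3% of sites carry a ±0.30 one-population shift (DMS truth).
  An optional coupling coefficient shifts coupled genes' promoter levels
  linearly with the sample's true copy number; coupled loci are full
  duplications of promoter-covered genes at frequency 0.25 so carriers
  exist to correlate against. 3% of CpG sites are marked SNP-affected.

**What the generator does not emulate** — and therefore what passing
tests do not establish about real data: read-level artifacts (mapping
bias, bisulfite conversion error, PCR duplicates), depth GC-waviness and
segmental-duplication pileups, overlapping or nested CNVs,
linkage between loci, shared ancestry/relatedness within populations,
and methylation spatial autocorrelation beyond cluster-level class
means. The generator's CNVs are bi-allelic by construction, so the
bi-allelic frequency table covers every retained locus, which is
optimistic relative to real multi-allelic loci.

One interaction is worth naming: because CNV loci are preferentially
genic and CpG clusters concentrate at genes, DMS-CNV permutation tests
on the default cohort show mild *enrichment* against a
genome-uniform null even with no planted coupling — a geometry effect,
not a methylation-CNV interaction. The calibration of the permutation
test itself is checked separately with intervals drawn from the same
placement law as the null.

## Operating characteristics the suite computes

The acceptance tests and `scripts/acceptance.py` recompute, from fresh
simulations: per-sample copy-number concordance on the default design
(threshold ≥ 95%); exact agreement of all seven filtering operations
with brute-force oracles on random fixtures; V_st equality with the
direct variance formula to 1e-12 and label-permutation null centering;
the DMS caller's null flagged fraction (≤ 0.0125) and its power at a
30-point pooled difference (≥ 95%) on a 2 × 12 design at Poisson(30)
coverage over 10,000 sites; uniformity of permutation-test p-values over
100 replicate null datasets (KS) and the p floor 1/1001 with planted
overlap; recovery of 20 coupled genes at BH q < 0.05 (≥ 80%) with a
false-positive check at coupling 0; and the full run's output tables
plus ≥ 80% V_st outlier recall of truth-differentiated loci. Problem
sizes (200 loci, ~4800 CpGs, 10,000 calibration sites, 199–1000
permutations) were chosen so the whole suite runs in well under a minute
per stage on one CPU.

## Known limitations

* The genotyper assumes integer copy numbers up to ~4 with unimodal
  depth per state; mosaic or multi-allelic loci would be excluded as
  cluster-genotype mismatches rather than genotyped.
* The DMS test inherits the binomial assumption; true per-sample
  overdispersion inflates its type-I error (the calibration simulation
  draws per-site, not per-sample, proportions — matching the test's
  model, not the generator's beta-binomial cohort counts).
* q-values use BH; the upstream tool this emulates defaults to a
  different FDR method (SLIM), so q-values are comparable but not
  identical to that tool's output.
* The permutation null places intervals genome-uniformly by default;
  chromosome-matched placement is available but no GC- or
  accessibility-matched null is implemented.
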