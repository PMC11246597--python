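"""Synthetic cohort generator with known CNV and methylation truth.

Emulates the statistical structure of a multi-population resequencing +
RRBS study design: 6 populations x 16 diploid individuals along a salinity
gradient, CNV loci segregating with population-specific allele
frequencies, per-window normalized read depth centered on the true copy
number with Gaussian noise, multiple structural-variant callers with
caller-specific sensitivity, breakpoint jitter and false positives,
clustered RRBS-like CpG coverage, and beta-binomial methylation counts
with low promoter / high gene-body means and hypermethylated
lineage-specific genes. Every downstream stage of the pipeline can be
tested against the truth tables produced here.

All randomness flows from one ``numpy.random.default_rng(seed)`` stream,
so a fixed seed reproduces the bundle exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cnv_consensus import DepthMatrix
from .errors import ConfigError
from .io_formats import write_bed, write_cpg_counts, write_genepred, write_sample_metadata
from .methylation import MethylationCountMatrix, annotate_positions

GENE_TYPES = ("LSG", "paralog", "singleton")


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults are the study design.

    Lengths in bp, depth dimensionless (diploid = 2), rates in [0, 1].
    """

    seed: int = 0

    # cohort design
    n_populations: int = 6
    n_per_population: int = 16
    salinities: tuple = (4.3, 4.6, 6.0, 9.8, 18.0, 28.9)  # PSU per population
    male_fraction: float = 0.5

    # genome
    chromosome_lengths: dict = field(default_factory=lambda: {
        "chrI": 3_000_000, "chrII": 3_000_000, "chrIII": 3_000_000,
        "chrIV": 3_000_000, "chrXIX": 2_000_000})
    sex_chromosomes: tuple = ("chrXIX",)
    window_size: int = 500
    n_genes: int = 300
    gene_length_range: tuple = (2_000, 12_000)
    gene_type_proportions: dict = field(default_factory=lambda: {
        "singleton": 0.18, "paralog": 0.63, "LSG": 0.19})

    # CNV truth
    n_cnv_loci: int = 200
    deletion_fraction: float = 0.47
    deletion_length_lognorm: tuple = (8.3, 0.5)    # (mu, sigma) of log length
    duplication_length_lognorm: tuple = (8.8, 0.5)
    min_cnv_length: int = 1_500
    genic_fraction: float = 0.5                     # loci forced onto a gene
    full_gene_fraction: float = 0.6                 # of genic loci, cover >=90%
    allele_freq_beta: tuple = (0.5, 8.0)            # undifferentiated loci
    singleton_fraction: float = 0.55                # loci with exactly 1 carrier
    # Planted differentiated loci each produce ~5 informative population
    # pairs; the default count keeps those records within the capacity of a
    # top-2% outlier rule on this cohort's finite pairwise-V_st pool.
    n_differentiated: int = 5
    differentiated_freq_high: float = 0.8
    differentiated_freq_low: float = 0.05
    n_sex_specific_del: int = 2
    n_sex_specific_dup: int = 1

    # depth
    depth_noise_sd: float = 0.2
    sample_scale_range: tuple = (0.8, 1.25)         # raw-depth scale per sample
    coverage_per_copy: float = 7.0                  # x per copy, evidence fields

    # callers
    caller_sensitivity: dict = field(default_factory=lambda: {
        "cnvnator": 0.97, "breakdancer": 0.90, "pindel": 0.90,
        "delly": 0.90, "duppy": 0.90})
    caller_jitter_sd: dict = field(default_factory=lambda: {
        "cnvnator": 100.0, "breakdancer": 150.0, "pindel": 30.0,
        "delly": 50.0, "duppy": 50.0})
    false_positive_rate: float = 0.05               # per caller, vs true calls

    # CpG placement (RRBS-like clusters)
    promoter_coverage_fraction: float = 0.40        # genes with promoter CpGs
    promoter_sites_mean: float = 12.0
    gene_body_coverage_fraction: float = 0.60
    gene_body_sites_mean: float = 8.0
    n_intergenic_clusters: int = 300
    intergenic_sites_mean: float = 6.0

    # methylation counts
    cpg_coverage_mean: float = 30.0
    sample_coverage_scale_range: tuple = (0.7, 1.4)
    site_missing_rate: float = 0.10
    bb_precision: float = 30.0                      # beta-binomial precision
    promoter_mean: float = 0.30
    lsg_promoter_mean: float = 0.55
    gene_body_mean: float = 0.70
    intergenic_mean: float = 0.58
    level_precision: float = 8.0                    # spread of per-site means
    dms_site_fraction: float = 0.03                 # sites with a pop shift
    dms_shift: float = 0.30

    # methylation-copy-number coupling
    coupling: float = 0.0                           # level shift per extra copy
    n_coupled_genes: int = 0
    coupled_allele_freq: float = 0.25

    # SNP emulation
    snp_fraction: float = 0.03

    def __post_init__(self) -> None:
        rates = {"male_fraction": self.male_fraction,
                 "deletion_fraction": self.deletion_fraction,
                 "genic_fraction": self.genic_fraction,
                 "full_gene_fraction": self.full_gene_fraction,
                 "differentiated_freq_high": self.differentiated_freq_high,
                 "differentiated_freq_low": self.differentiated_freq_low,
                 "false_positive_rate": self.false_positive_rate,
                 "promoter_coverage_fraction": self.promoter_coverage_fraction,
                 "gene_body_coverage_fraction": self.gene_body_coverage_fraction,
                 "site_missing_rate": self.site_missing_rate,
                 "dms_site_fraction": self.dms_site_fraction,
                 "singleton_fraction": self.singleton_fraction,
                 "snp_fraction": self.snp_fraction,
                 "coupled_allele_freq": self.coupled_allele_freq}
        for name, v in rates.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v!r}")
        if self.depth_noise_sd < 0:
            raise ConfigError("depth_noise_sd must be >= 0")
        for caller, s in self.caller_sensitivity.items():
            if not (0.0 <= s <= 1.0):
                raise ConfigError(f"caller_sensitivity[{caller!r}] must be in [0, 1]")
        for caller, sd in self.caller_jitter_sd.items():
            if sd < 0:
                raise ConfigError(f"caller_jitter_sd[{caller!r}] must be >= 0")
        if len(self.salinities) < self.n_populations:
            raise ConfigError("need one salinity per population")
        if self.n_cnv_loci < 0 or self.n_genes < 1:
            raise ConfigError("n_cnv_loci must be >= 0 and n_genes >= 1")
        if self.window_size < 1:
            raise ConfigError("window_size must be positive")
        props = self.gene_type_proportions
        if set(props) != set(GENE_TYPES) or abs(sum(props.values()) - 1.0) > 1e-6:
            raise ConfigError("gene_type_proportions must cover LSG/paralog/"
                              "singleton and sum to 1")

    @property
    def populations(self) -> list[str]:
        return [f"pop{i+1}" for i in range(self.n_populations)]

    @property
    def n_samples(self) -> int:
        return self.n_populations * self.n_per_population


# --------------------------------------------------------------------------
# Bundle types
# --------------------------------------------------------------------------

@dataclass
class GenomeModel:
    chromosomes: dict                 # name -> length (bp)
    genes: pd.DataFrame               # genePred-like + gene_type + tss
    cpg_sites: pd.DataFrame           # chrom, pos, strand (sorted)

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chromosomes]


@dataclass
class CnvTruth:
    loci: pd.DataFrame                # locus_id, chrom, start, end, cnv_class,
                                      # differentiated, sex_specific
    frequencies: pd.DataFrame         # locus_id x population allele frequency
    copy_numbers: pd.DataFrame        # locus_id x sample integer copy number


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeModel
    metadata: pd.DataFrame
    truth: CnvTruth
    depth_raw: DepthMatrix            # per-sample scaled; normalize before use
    caller_calls: pd.DataFrame
    cpg_counts: MethylationCountMatrix
    snp_positions: pd.DataFrame
    coupled_genes: list


# --------------------------------------------------------------------------
# Genome and cohort
# --------------------------------------------------------------------------

def simulate_metadata(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for pi, pop in enumerate(config.populations):
        n_male = int(round(config.male_fraction * config.n_per_population))
        sexes = np.array(["M"] * n_male + ["F"] * (config.n_per_population - n_male))
        rng.shuffle(sexes)
        for si in range(config.n_per_population):
            rows.append((f"{pop}_s{si+1:02d}", pop, sexes[si],
                         config.salinities[pi]))
    return pd.DataFrame(rows, columns=["sample", "population", "sex", "salinity"])


def simulate_genome(config: SimulationConfig, rng: np.random.Generator) -> GenomeModel:
    """Genes placed without overlap in per-chromosome blocks; CpG sites in
    promoter / gene-body / intergenic clusters (RRBS-fragment-like)."""
    chrom_names = list(config.chromosome_lengths)
    lengths = np.array([config.chromosome_lengths[c] for c in chrom_names], float)
    n_per_chrom = np.maximum(1, np.round(config.n_genes * lengths / lengths.sum())).astype(int)
    lo, hi = config.gene_length_range
    gene_rows = []
    gid = 0
    for c, n_c in zip(chrom_names, n_per_chrom):
        L = config.chromosome_lengths[c]
        block = L // n_c
        for b in range(n_c):
            if gid >= config.n_genes + len(chrom_names):  # slight overshoot ok
                break
            glen = int(rng.integers(lo, hi + 1))
            margin = block - glen - 4000  # room for promoters at block edges
            if margin <= 0:
                continue
            start = b * block + 2000 + int(rng.integers(0, margin))
            end = start + glen
            strand = "+" if rng.random() < 0.5 else "-"
            mid = (start + end) // 2
            gene_rows.append((f"gene{gid:04d}", c, strand, start, end, start, end,
                              2, (start, mid + 50), (mid, end),
                              start if strand == "+" else end))
            gid += 1
    genes = pd.DataFrame(gene_rows, columns=[
        "name", "chrom", "strand", "txStart", "txEnd", "cdsStart", "cdsEnd",
        "exonCount", "exonStarts", "exonEnds", "tss"])
    types = rng.choice(GENE_TYPES,
                       p=[config.gene_type_proportions[t] for t in GENE_TYPES],
                       size=len(genes))
    genes["gene_type"] = types

    # CpG clusters
    site_rows = []

    def add_cluster(chrom, lo_pos, hi_pos, n_sites):
        n_sites = max(2, n_sites)
        span = hi_pos - lo_pos
        if span < n_sites * 2:
            return
        pos = np.sort(rng.choice(np.arange(lo_pos, hi_pos), size=n_sites, replace=False))
        for p in pos:
            site_rows.append((chrom, int(p), "+" if rng.random() < 0.5 else "-"))

    has_promoter = rng.random(len(genes)) < config.promoter_coverage_fraction
    has_body = rng.random(len(genes)) < config.gene_body_coverage_fraction
    for i, g in genes.iterrows():
        if g["strand"] == "+":
            plo, phi = g["tss"] - 1500, g["tss"] + 500
        else:
            plo, phi = g["tss"] - 500, g["tss"] + 1500
        plo = max(plo, 0)
        if has_promoter[i]:
            add_cluster(g["chrom"], plo, phi, int(rng.poisson(config.promoter_sites_mean)))
        if has_body[i]:
            blo = max(g["txStart"], phi) if g["strand"] == "+" else g["txStart"]
            bhi = g["txEnd"] if g["strand"] == "+" else min(g["txEnd"], plo)
            if bhi - blo > 200:
                add_cluster(g["chrom"], blo, bhi, int(rng.poisson(config.gene_body_sites_mean)))
    for _ in range(config.n_intergenic_clusters):
        ci = rng.choice(len(chrom_names), p=lengths / lengths.sum())
        c = chrom_names[ci]
        start = int(rng.integers(0, config.chromosome_lengths[c] - 300))
        add_cluster(c, start, start + 300, int(rng.poisson(config.intergenic_sites_mean)))

    sites = pd.DataFrame(site_rows, columns=["chrom", "pos", "strand"])
    sites = sites.drop_duplicates(subset=["chrom", "pos"])
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    return GenomeModel(chromosomes=dict(config.chromosome_lengths),
                       genes=genes, cpg_sites=sites)


# --------------------------------------------------------------------------
# CNV truth
# --------------------------------------------------------------------------

def _draw_length(config: SimulationConfig, cnv_class: str, rng) -> int:
    mu, sigma = (config.deletion_length_lognorm if cnv_class == "deletion"
                 else config.duplication_length_lognorm)
    return max(config.min_cnv_length, int(rng.lognormal(mu, sigma)))


def _snap(lo: int, hi: int, w: int, chrom_len: int) -> tuple[int, int]:
    """Align an interval to the depth-window grid (>= one window)."""
    lo = max(0, (lo // w) * w)
    hi = min(chrom_len, ((hi + w - 1) // w) * w)
    if hi <= lo:
        hi = min(chrom_len, lo + w)
    return lo, hi


def simulate_cnv_truth(genome: GenomeModel, metadata: pd.DataFrame,
                       config: SimulationConfig, rng: np.random.Generator
                       ) -> tuple[CnvTruth, list]:
    """CNV loci with per-population frequencies and per-sample genotypes.

    Genotypes are Hardy-Weinberg draws: alleles ~ Binomial(2, f_pop), copy
    number 2 -/+ alleles for deletions/duplications, so loci are bi-allelic
    with states {0,1,2} or {2,3,4}. ``n_differentiated`` loci get a high
    frequency in one random population and a low one elsewhere; coupled
    genes (when requested) are full duplications of genes that received
    promoter CpG coverage, at intermediate frequency in every population so
    carriers exist to correlate against. Sex-specific loci sit on the sex
    chromosome with all-male carriers (hemizygous depth states).
    """
    w = config.window_size
    autosomes = [c for c in genome.chromosomes if c not in config.sex_chromosomes]
    auto_len = np.array([genome.chromosomes[c] for c in autosomes], float)
    occupied: dict[str, list] = {c: [] for c in genome.chromosomes}

    def free(chrom, lo, hi):
        return all(hi <= a or lo >= b for a, b in occupied[chrom])

    prom_sites = annotate_positions(genome.cpg_sites, genome.genes)
    genes_with_prom = sorted(set(
        prom_sites.loc[prom_sites["region_class"] == "promoter", "gene_id"]) - {""})
    auto_genes = genome.genes[genome.genes["chrom"].isin(autosomes)]

    loci = []
    coupled_genes: list[str] = []

    def place_genic(cnv_class, gene_row, full=True):
        chrom = gene_row["chrom"]
        gs, ge = int(gene_row["txStart"]), int(gene_row["txEnd"])
        if full:
            lo, hi = gs - int(rng.integers(0, 500)), ge + int(rng.integers(0, 500))
        else:
            lo, hi = gs + (ge - gs) // 2, ge + int(rng.integers(0, 1000))
        lo, hi = _snap(lo, hi, w, genome.chromosomes[chrom])
        if free(chrom, lo, hi):
            occupied[chrom].append((lo, hi))
            return chrom, lo, hi
        return None

    def place_anywhere(cnv_class):
        for _ in range(200):
            ci = rng.choice(len(autosomes), p=auto_len / auto_len.sum())
            chrom = autosomes[ci]
            length = _draw_length(config, cnv_class, rng)
            if length >= genome.chromosomes[chrom]:
                continue
            lo = int(rng.integers(0, genome.chromosomes[chrom] - length))
            lo, hi = _snap(lo, lo + length, w, genome.chromosomes[chrom])
            if free(chrom, lo, hi):
                occupied[chrom].append((lo, hi))
                return chrom, lo, hi
        raise ConfigError("could not place CNV loci; genome too small/crowded")

    # coupled loci first: full duplications of promoter-covered autosomal genes
    candidates = auto_genes[auto_genes["name"].isin(genes_with_prom)]
    candidates = candidates.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    for _, g in candidates.iterrows():
        if len(coupled_genes) >= config.n_coupled_genes:
            break
        placed = place_genic("duplication", g, full=True)
        if placed:
            loci.append((*placed, "duplication", False, "", "coupled"))
            coupled_genes.append(g["name"])

    n_rest = max(0, config.n_cnv_loci - len(loci))
    n_genic = int(round(config.genic_fraction * n_rest))
    pool = auto_genes.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    placed_genic = 0
    for _, g in pool.iterrows():
        if placed_genic >= n_genic:
            break
        cnv_class = ("deletion" if rng.random() < config.deletion_fraction
                     else "duplication")
        placed = place_genic(cnv_class, g,
                             full=rng.random() < config.full_gene_fraction)
        if placed:
            loci.append((*placed, cnv_class, False, "", ""))
            placed_genic += 1
    while len(loci) < config.n_cnv_loci:
        cnv_class = ("deletion" if rng.random() < config.deletion_fraction
                     else "duplication")
        loci.append((*place_anywhere(cnv_class), cnv_class, False, "", ""))

    # sex-specific loci on the sex chromosome
    for k in range(config.n_sex_specific_del + config.n_sex_specific_dup):
        cnv_class = "deletion" if k < config.n_sex_specific_del else "duplication"
        chrom = config.sex_chromosomes[0]
        for _ in range(200):
            length = _draw_length(config, cnv_class, rng)
            lo = int(rng.integers(0, genome.chromosomes[chrom] - length))
            lo, hi = _snap(lo, lo + length, w, genome.chromosomes[chrom])
            if free(chrom, lo, hi):
                occupied[chrom].append((lo, hi))
                loci.append((chrom, lo, hi, cnv_class, False, "M", ""))
                break

    df = pd.DataFrame(loci, columns=["chrom", "start", "end", "cnv_class",
                                     "differentiated", "sex_specific", "tag"])
    df.insert(0, "locus_id", [f"locus{i:04d}" for i in range(len(df))])

    # mark differentiated loci among ordinary autosomal ones
    ordinary = df.index[(df["sex_specific"] == "") & (df["tag"] == "")]
    n_diff = min(config.n_differentiated, len(ordinary))
    diff_idx = rng.choice(ordinary, size=n_diff, replace=False)
    df.loc[diff_idx, "differentiated"] = True

    # frequencies; an excess of singleton loci (exactly one heterozygous
    # carrier) sits on top of the Beta-distributed common tail, as CNV
    # cohorts typically show
    pops = config.populations
    a, b = config.allele_freq_beta
    freq = np.zeros((len(df), len(pops)))
    high_pop = rng.integers(0, len(pops), size=len(df))
    is_singleton = np.zeros(len(df), dtype=bool)
    for i in range(len(df)):
        if df.at[i, "sex_specific"]:
            freq[i] = 0.0       # handled by sex below, not by allele draws
        elif df.at[i, "tag"] == "coupled":
            freq[i] = config.coupled_allele_freq
        elif df.at[i, "differentiated"]:
            freq[i] = config.differentiated_freq_low
            freq[i, high_pop[i]] = config.differentiated_freq_high
        elif rng.random() < config.singleton_fraction:
            is_singleton[i] = True  # carrier drawn directly below
        else:
            freq[i] = rng.beta(a, b)
    freq_df = pd.DataFrame(freq, index=df["locus_id"], columns=pops)

    # genotypes
    samples = metadata["sample"].to_list()
    pop_of = metadata.set_index("sample")["population"]
    sex_of = metadata.set_index("sample")["sex"]
    cn = np.full((len(df), len(samples)), 2, dtype=int)
    for i in range(len(df)):
        sign = -1 if df.at[i, "cnv_class"] == "deletion" else 1
        if df.at[i, "sex_specific"]:
            for j, s in enumerate(samples):
                if sex_of[s] == "M":
                    cn[i, j] = 2 + sign  # hemizygous-like male state
            continue
        if is_singleton[i]:
            j = int(rng.integers(0, len(samples)))
            cn[i, j] = 2 + sign
            freq_df.iloc[i, pops.index(pop_of[samples[j]])] = \
                1.0 / (2 * config.n_per_population)
            continue
        for j, s in enumerate(samples):
            alleles = rng.binomial(2, freq[i, pops.index(pop_of[s])])
            cn[i, j] = 2 + sign * alleles
    cn_df = pd.DataFrame(cn, index=df["locus_id"], columns=samples)
    truth = CnvTruth(loci=df.drop(columns=["tag"]), frequencies=freq_df,
                     copy_numbers=cn_df)
    return truth, coupled_genes


# --------------------------------------------------------------------------
# Depth
# --------------------------------------------------------------------------

def simulate_depth(genome: GenomeModel, truth: CnvTruth, metadata: pd.DataFrame,
                   config: SimulationConfig, rng: np.random.Generator) -> DepthMatrix:
    """Raw window depth: true copy number + Gaussian noise, scaled per sample.

    Depth is simulated directly on the normalized scale (copy number, with
    diploid = 2) and then multiplied by a per-sample library-size factor;
    ``normalize_depth`` recovers the centered scale.
    """
    w = config.window_size
    win_rows = []
    for c, L in genome.chromosomes.items():
        starts = np.arange(0, L, w)
        ends = np.minimum(starts + w, L)
        win_rows.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends}))
    windows = pd.concat(win_rows, ignore_index=True)

    samples = metadata["sample"].to_list()
    n_w, n_s = len(windows), len(samples)
    cn = np.full((n_w, n_s), 2.0)
    start_arr = windows["start"].to_numpy()
    chrom_arr = windows["chrom"].to_numpy()
    col = {s: j for j, s in enumerate(samples)}
    for i, locus in truth.loci.iterrows():
        sel = ((chrom_arr == locus["chrom"]) & (start_arr >= locus["start"])
               & (start_arr < locus["end"]))
        states = truth.copy_numbers.loc[locus["locus_id"]]
        carriers = states[states != 2]
        for s, v in carriers.items():
            cn[sel, col[s]] = float(v)
    noise = rng.normal(0.0, config.depth_noise_sd, size=(n_w, n_s))
    depth = np.maximum(cn + noise, 0.0)
    lo, hi = config.sample_scale_range
    scale = rng.uniform(lo, hi, size=n_s)
    raw = depth * scale[None, :]
    return DepthMatrix(windows=windows, values=pd.DataFrame(raw, columns=samples))


# --------------------------------------------------------------------------
# Caller calls
# --------------------------------------------------------------------------

def emit_caller_calls(truth: CnvTruth, genome: GenomeModel,
                      config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-caller call tables with jittered breakpoints and false positives.

    Each truth locus is emitted by each caller independently with the
    caller's sensitivity; breakpoints get Gaussian jitter (the read-depth
    caller is then snapped back to its window grid). Evidence fields
    (supporting pairs/split reads, mapping quality, per-sample coverage)
    are drawn so the caller-level filters have realistic work to do.
    False-positive calls are added per caller at ``false_positive_rate``
    times its true-call count, placed uniformly on the autosomes.
    """
    w = config.window_size
    autosomes = [c for c in genome.chromosomes if c not in config.sex_chromosomes]
    auto_len = np.array([genome.chromosomes[c] for c in autosomes], float)
    rows = []

    def evidence(caller, cnv_class, max_cn):
        cov = max_cn * config.coverage_per_copy * rng.uniform(0.9, 1.1)
        if caller == "breakdancer":
            pairs, splits = int(rng.poisson(8)), 0
        elif caller == "pindel":
            pairs, splits = 0, int(rng.poisson(8))
        elif caller in ("delly", "duppy"):
            pairs, splits = int(rng.poisson(6)), int(rng.poisson(4))
        else:
            pairs, splits = 0, 0
        mapq = float(np.clip(rng.normal(45.0, 12.0), 0.0, 60.0))
        return pairs, splits, mapq, float(cov)

    for caller, sens in config.caller_sensitivity.items():
        jsd = config.caller_jitter_sd.get(caller, 0.0)
        n_true = 0
        for _, locus in truth.loci.iterrows():
            if rng.random() >= sens:
                continue
            n_true += 1
            L = genome.chromosomes[locus["chrom"]]
            start = locus["start"] + (rng.normal(0, jsd) if jsd > 0 else 0.0)
            end = locus["end"] + (rng.normal(0, jsd) if jsd > 0 else 0.0)
            if caller == "cnvnator":
                start, end = _snap(int(start), int(end), w, L)
            start = int(np.clip(start, 0, L - 1))
            end = int(np.clip(end, start + 1, L))
            states = truth.copy_numbers.loc[locus["locus_id"]]
            max_cn = int(states.max()) if locus["cnv_class"] == "duplication" else 2
            pairs, splits, mapq, cov = evidence(caller, locus["cnv_class"], max_cn)
            rows.append((caller, locus["cnv_class"], locus["chrom"], start, end,
                         pairs, splits, mapq, cov, locus["locus_id"]))
        n_fp = int(round(config.false_positive_rate * n_true))
        for _ in range(n_fp):
            cnv_class = ("deletion" if rng.random() < config.deletion_fraction
                         else "duplication")
            ci = rng.choice(len(autosomes), p=auto_len / auto_len.sum())
            chrom = autosomes[ci]
            length = _draw_length(config, cnv_class, rng)
            if length >= genome.chromosomes[chrom]:
                continue
            start = int(rng.integers(0, genome.chromosomes[chrom] - length))
            end = start + length
            if caller == "cnvnator":
                start, end = _snap(start, end, w, genome.chromosomes[chrom])
            pairs, splits, mapq, _ = evidence(caller, cnv_class, 2)
            cov = float(rng.uniform(10.0, 60.0))
            rows.append((caller, cnv_class, chrom, start, end,
                         pairs, splits, mapq, cov, ""))
    calls = pd.DataFrame(rows, columns=[
        "caller", "cnv_class", "chrom", "start", "end",
        "read_pairs", "split_reads", "mapq", "max_coverage", "truth_locus"])
    return (calls.sort_values(["caller", "chrom", "start"], kind="mergesort")
                 .reset_index(drop=True))


# --------------------------------------------------------------------------
# SNP positions
# --------------------------------------------------------------------------

def emit_snp_positions(genome: GenomeModel, config: SimulationConfig,
                       rng: np.random.Generator,
                       fraction: float | None = None) -> pd.DataFrame:
    """Mark a fraction of CpG sites as hit by C>T or G>A substitutions."""
    f = config.snp_fraction if fraction is None else fraction
    if not (0.0 <= f <= 1.0):
        raise ConfigError(f"snp fraction must be in [0, 1], got {f!r}")
    hit = rng.random(len(genome.cpg_sites)) < f
    sub = rng.choice(["C>T", "G>A"], size=int(hit.sum()))
    out = genome.cpg_sites.loc[hit, ["chrom", "pos"]].reset_index(drop=True)
    out["substitution"] = sub
    return out


# --------------------------------------------------------------------------
# Methylation counts
# --------------------------------------------------------------------------

def simulate_methylation(genome: GenomeModel, truth: CnvTruth, metadata: pd.DataFrame,
                         config: SimulationConfig, rng: np.random.Generator,
                         coupled_genes: list | None = None) -> MethylationCountMatrix:
    """Beta-binomial methylation counts over the genome's CpG sites.

    Per-site mean levels follow the region class (low promoters, high gene
    bodies, intermediate intergenic; LSG promoters elevated). A fraction of
    sites carries a one-population shift (differential-methylation truth).
    When a coupling coefficient is set, promoter sites of coupled genes
    shift linearly with the sample's true copy number, linking methylation
    to CNV genotype. Coverage is Poisson with per-sample library scaling;
    cells with zero coverage (or dropped out) are missing.
    """
    coupled_genes = coupled_genes or []
    sites = genome.cpg_sites
    n_sites = len(sites)
    samples = metadata["sample"].to_list()
    n_s = len(samples)
    pops = config.populations
    pop_idx = np.array([pops.index(p) for p in
                        metadata.set_index("sample")["population"].reindex(samples)])

    ann = annotate_positions(sites, genome.genes)
    gene_type = genome.genes.set_index("name")["gene_type"]

    # per-gene promoter base level; per-site mean around it
    gene_level: dict[str, float] = {}
    mu = np.empty(n_sites)
    s_lvl = config.level_precision
    for i in range(n_sites):
        cls = ann.at[i, "region_class"]
        gid = ann.at[i, "gene_id"]
        if cls == "promoter":
            if gid not in gene_level:
                base = (config.lsg_promoter_mean if gene_type.get(gid) == "LSG"
                        else config.promoter_mean)
                gene_level[gid] = float(np.clip(
                    rng.beta(base * s_lvl, (1 - base) * s_lvl), 0.02, 0.98))
            m0 = gene_level[gid]
        elif cls == "gene_body":
            m0 = config.gene_body_mean
        else:
            m0 = config.intergenic_mean
        mu[i] = float(np.clip(rng.beta(m0 * s_lvl, (1 - m0) * s_lvl), 0.02, 0.98))

    # population shifts (differential-methylation truth)
    shifted = rng.random(n_sites) < config.dms_site_fraction
    shift_pop = rng.integers(0, len(pops), size=n_sites)
    shift_sign = np.where(rng.random(n_sites) < 0.5, -1.0, 1.0)

    # per-site per-sample mean
    mu_mat = np.tile(mu[:, None], (1, n_s))
    rows_shift = np.where(shifted)[0]
    for i in rows_shift:
        cols = pop_idx == shift_pop[i]
        mu_mat[i, cols] = np.clip(mu[i] + shift_sign[i] * config.dms_shift, 0.02, 0.98)

    # methylation-copy-number coupling on coupled genes' promoter sites
    if config.coupling != 0.0 and coupled_genes:
        gene_cn: dict[str, np.ndarray] = {}
        g_int = genome.genes.set_index("name")
        for gid in coupled_genes:
            g = g_int.loc[gid]
            hits = truth.loci[(truth.loci["chrom"] == g["chrom"])
                              & (truth.loci["start"] < g["txEnd"])
                              & (truth.loci["end"] > g["txStart"])]
            if len(hits):
                gene_cn[gid] = truth.copy_numbers.loc[hits.iloc[0]["locus_id"]].to_numpy()
        is_prom = (ann["region_class"] == "promoter").to_numpy()
        gene_ids = ann["gene_id"].to_numpy()
        for gid, cn_vec in gene_cn.items():
            rows_g = np.where(is_prom & (gene_ids == gid))[0]
            delta = config.coupling * (cn_vec.astype(float) - 2.0)
            mu_mat[rows_g, :] = np.clip(mu_mat[rows_g, :] + delta[None, :], 0.02, 0.98)

    # counts
    lo, hi = config.sample_coverage_scale_range
    lib = rng.uniform(lo, hi, size=n_s)
    lam = config.cpg_coverage_mean * lib[None, :]
    cov = rng.poisson(np.broadcast_to(lam, (n_sites, n_s))).astype(float)
    dropout = rng.random((n_sites, n_s)) < config.site_missing_rate
    cov[dropout] = 0.0
    s_bb = config.bb_precision
    p = rng.beta(mu_mat * s_bb, (1.0 - mu_mat) * s_bb)
    meth = rng.binomial(cov.astype(int), p).astype(float)
    missing = cov == 0
    cov[missing] = np.nan
    meth[missing] = np.nan
    return MethylationCountMatrix(
        sites=sites.copy(),
        cov=pd.DataFrame(cov, columns=samples),
        meth=pd.DataFrame(meth, columns=samples))


# --------------------------------------------------------------------------
# Bundle
# --------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full bundle; deterministic for a fixed config.seed."""
    rng = np.random.default_rng(config.seed)
    metadata = simulate_metadata(config, rng)
    genome = simulate_genome(config, rng)
    truth, coupled = simulate_cnv_truth(genome, metadata, config, rng)
    depth = simulate_depth(genome, truth, metadata, config, rng)
    calls = emit_caller_calls(truth, genome, config, rng)
    snps = emit_snp_positions(genome, config, rng)
    cpg = simulate_methylation(genome, truth, metadata, config, rng, coupled)
    return SimulatedDataset(config=config, genome=genome, metadata=metadata,
                            truth=truth, depth_raw=depth, caller_calls=calls,
                            cpg_counts=cpg, snp_positions=snps,
                            coupled_genes=coupled)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write the observable tables and the truth alongside, plus a config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_sample_metadata(ds.metadata, outdir / "samples.tsv")
    write_genepred(ds.genome.genes, outdir / "genes.genePred")
    ds.genome.genes[["name", "gene_type"]].to_csv(
        outdir / "gene_types.tsv", sep="\t", index=False)
    ds.caller_calls.to_csv(outdir / "caller_calls.tsv", sep="\t", index=False)
    truth_bed = ds.truth.loci.rename(columns={"locus_id": "name"})
    write_bed(truth_bed[["chrom", "start", "end", "name", "cnv_class"]],
              outdir / "truth_cnvs.bed")
    ds.truth.copy_numbers.to_csv(outdir / "truth_copy_numbers.tsv", sep="\t")
    ds.truth.frequencies.to_csv(outdir / "truth_frequencies.tsv", sep="\t")
    ds.depth_raw.windows.assign(**{
        s: ds.depth_raw.values[s] for s in ds.depth_raw.samples}).to_csv(
        outdir / "depth_windows.tsv", sep="\t", index=False)
    write_cpg_counts(ds.cpg_counts, outdir / "cpg_counts.tsv")
    ds.snp_positions.to_csv(outdir / "snp_positions.tsv", sep="\t", index=False)
    with open(outdir / "simulation_config.yaml", "w") as fh:
        cfg = {k: (dict(v) if isinstance(v, dict) else
                   list(v) if isinstance(v, tuple) else v)
               for k, v in vars(ds.config).items()}
        yaml.safe_dump(cfg, fh, sort_keys=True)


# --------------------------------------------------------------------------
# Small two-group count simulator (test-bench for the DMS caller)
# --------------------------------------------------------------------------

def simulate_two_group_counts(n_sites: int, n_per_group: int, coverage_mean: float,
                              diff: float = 0.0, seed: int = 0,
                              config: SimulationConfig | None = None
                              ) -> tuple[MethylationCountMatrix, pd.DataFrame]:
    """Binomial counts for two populations at independent sites.

    Under the null (``diff=0``) each site's true proportion is drawn from
    the generator's fitted region-class mixture and shared by both groups;
    with ``diff`` > 0 group B's proportion is group A's plus ``diff``
    (clipped), giving a true pooled difference of ``diff``. Coverage is
    Poisson(``coverage_mean``); zero-coverage cells are missing.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    s = cfg.level_precision
    cls = rng.choice(3, p=[0.3, 0.4, 0.3], size=n_sites)
    means = np.array([cfg.promoter_mean, cfg.gene_body_mean, cfg.intergenic_mean])
    p_a = rng.beta(means[cls] * s, (1 - means[cls]) * s)
    if diff > 0:
        p_a = np.clip(p_a, 0.02, 0.98 - diff)
        p_b = p_a + diff
    else:
        p_a = np.clip(p_a, 0.02, 0.98)
        p_b = p_a
    n_s = 2 * n_per_group
    cov = rng.poisson(coverage_mean, size=(n_sites, n_s)).astype(float)
    p_mat = np.column_stack([np.tile(p_a[:, None], (1, n_per_group)),
                             np.tile(p_b[:, None], (1, n_per_group))])
    meth = rng.binomial(cov.astype(int), p_mat).astype(float)
    missing = cov == 0
    cov[missing] = np.nan
    meth[missing] = np.nan
    samples = ([f"A_s{i:02d}" for i in range(n_per_group)]
               + [f"B_s{i:02d}" for i in range(n_per_group)])
    sites = pd.DataFrame({"chrom": "chrSim",
                          "pos": np.arange(n_sites) * 50,
                          "strand": "+"})
    meta = pd.DataFrame({"sample": samples,
                         "population": ["A"] * n_per_group + ["B"] * n_per_group,
                         "sex": "unknown"})
    m = MethylationCountMatrix(sites=sites,
                               cov=pd.DataFrame(cov, columns=samples),
                               meth=pd.DataFrame(meth, columns=samples))
    return m, meta
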