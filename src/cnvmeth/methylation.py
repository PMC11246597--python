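"""RRBS-style CpG processing and differential methylation.

The processing chain mirrors standard bisulfite-count workflows: per-sample
coverage filtering (drop low-coverage cells and PCR-bias outliers above a
high coverage percentile), cross-sample coverage normalization, uniting
sites covered in enough samples of every population, exclusion of
SNP-confounded positions (C>T and G>A substitutions destroy or fake the
bisulfite signal) and sex-chromosome sites, annotation relative to genes,
and per-site differential-methylation tests between population pairs.

A site is a differentially methylated site (DMS) between two populations
when the coverage-weighted (pooled) methylation difference reaches
``dms_min_diff`` percentage points and the Benjamini-Hochberg q-value of a
binomial logistic-regression likelihood-ratio test is at most ``dms_max_q``.
For a single two-level factor the logistic-regression MLE is the pooled
per-group proportion, so the deviance test has a closed form and is
computed vectorized over sites.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .errors import ConfigError, DataError


# --------------------------------------------------------------------------
# Container
# --------------------------------------------------------------------------

@dataclass
class MethylationCountMatrix:
    """Per-CpG, per-sample (coverage, methylated) read counts.

    sites : DataFrame with chrom/pos/strand (plus annotation columns once
        annotated), sorted by (chrom, pos).
    cov, meth : DataFrames (n_sites x n_samples); NaN marks a cell the
        sample did not cover, which is distinct from coverage 0.
    """

    sites: pd.DataFrame
    cov: pd.DataFrame
    meth: pd.DataFrame

    def __post_init__(self) -> None:
        if not (len(self.sites) == len(self.cov) == len(self.meth)):
            raise DataError("MethylationCountMatrix: length mismatch")
        if list(self.cov.columns) != list(self.meth.columns):
            raise DataError("MethylationCountMatrix: sample columns differ")
        order = np.lexsort((self.sites["pos"].to_numpy(),
                            self.sites["chrom"].astype(str).to_numpy()))
        self.sites = self.sites.iloc[order].reset_index(drop=True)
        self.cov = self.cov.iloc[order].reset_index(drop=True)
        self.meth = self.meth.iloc[order].reset_index(drop=True)
        c, m = self.cov.to_numpy(), self.meth.to_numpy()
        if np.nansum(m > c) or (np.nan_to_num(c) < 0).any() or (np.nan_to_num(m) < 0).any():
            raise DataError("MethylationCountMatrix: counts violate 0 <= meth <= cov")
        if (np.isnan(c) != np.isnan(m)).any():
            raise DataError("MethylationCountMatrix: cov/meth missingness disagree")

    @property
    def samples(self) -> list[str]:
        return list(self.cov.columns)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def proportions(self) -> pd.DataFrame:
        return self.meth / self.cov

    def covered(self) -> pd.DataFrame:
        return self.cov.notna()

    def subset_sites(self, mask: np.ndarray) -> "MethylationCountMatrix":
        mask = np.asarray(mask)
        return MethylationCountMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            cov=self.cov.loc[mask].reset_index(drop=True),
            meth=self.meth.loc[mask].reset_index(drop=True))


# --------------------------------------------------------------------------
# Filters
# --------------------------------------------------------------------------

def filter_coverage(m: MethylationCountMatrix, min_cov: int = 10,
                    upper_percentile: float = 99.9) -> MethylationCountMatrix:
    """Blank cells with coverage < ``min_cov`` or above the sample's
    ``upper_percentile``-th coverage percentile (PCR-bias guard)."""
    cov = m.cov.to_numpy(dtype=float).copy()
    meth = m.meth.to_numpy(dtype=float).copy()
    for j in range(cov.shape[1]):
        col = cov[:, j]
        observed = col[~np.isnan(col)]
        if len(observed) == 0:
            continue
        hi = np.percentile(observed, upper_percentile)
        bad = (col < min_cov) | (col > hi)
        cov[bad, j] = np.nan
        meth[bad, j] = np.nan
    return MethylationCountMatrix(
        sites=m.sites.copy(),
        cov=pd.DataFrame(cov, columns=m.samples),
        meth=pd.DataFrame(meth, columns=m.samples))


def normalize_coverage(m: MethylationCountMatrix) -> MethylationCountMatrix:
    """Scale each sample's coverage toward the cohort's median coverage.

    Each sample's counts are multiplied by (median of per-sample median
    coverages) / (its median coverage) and rounded half-up; coverage is then
    raised to the methylated count where rounding would invert the order, so
    methylated <= coverage always holds and per-cell proportions move by
    less than 1/coverage.
    """
    cov = m.cov.to_numpy(dtype=float)
    meth = m.meth.to_numpy(dtype=float)
    medians = np.array([np.nanmedian(cov[:, j]) if (~np.isnan(cov[:, j])).any() else np.nan
                        for j in range(cov.shape[1])])
    if np.isnan(medians).any():
        empty = [m.samples[j] for j in np.where(np.isnan(medians))[0]]
        raise DataError(f"sample(s) with no covered sites: {empty[:5]}")
    target = np.median(medians)
    factors = target / medians
    new_cov = np.floor(cov * factors[None, :] + 0.5)
    new_meth = np.floor(meth * factors[None, :] + 0.5)
    new_cov = np.maximum(new_cov, 1.0)          # a covered cell stays covered
    new_cov = np.maximum(new_cov, new_meth)     # preserve meth <= cov
    new_cov[np.isnan(cov)] = np.nan
    new_meth[np.isnan(meth)] = np.nan
    return MethylationCountMatrix(
        sites=m.sites.copy(),
        cov=pd.DataFrame(new_cov, columns=m.samples),
        meth=pd.DataFrame(new_meth, columns=m.samples))


def unite_sites(m: MethylationCountMatrix, metadata: pd.DataFrame,
                min_per_group: int = 11, max_missing: float = 0.30) -> MethylationCountMatrix:
    """Keep sites covered in >= ``min_per_group`` samples of *every*
    population and with overall missingness <= ``max_missing``."""
    pop = metadata.set_index("sample")["population"].reindex(m.samples)
    sizes = pop.value_counts()
    if (sizes < min_per_group).any():
        small = sizes[sizes < min_per_group]
        raise ConfigError(
            f"min_per_group={min_per_group} exceeds population size(s): "
            f"{dict(small)}")
    covered = m.covered().to_numpy()
    keep = np.ones(m.n_sites, dtype=bool)
    for p in sizes.index:
        cols = (pop == p).to_numpy()
        keep &= covered[:, cols].sum(axis=1) >= min_per_group
    missing_frac = 1.0 - covered.mean(axis=1)
    keep &= missing_frac <= max_missing
    return m.subset_sites(keep)


def exclude_sites(m: MethylationCountMatrix, snp_positions: pd.DataFrame | None,
                  sex_chromosomes: tuple[str, ...] = ()) -> MethylationCountMatrix:
    """Drop sites at SNP-affected positions and on sex chromosomes."""
    keep = ~m.sites["chrom"].isin(sex_chromosomes).to_numpy()
    if snp_positions is not None and len(snp_positions):
        snp_keys = set(zip(snp_positions["chrom"], snp_positions["pos"].astype(int)))
        at_snp = np.fromiter(
            ((c, int(p)) in snp_keys
             for c, p in zip(m.sites["chrom"], m.sites["pos"])),
            dtype=bool, count=m.n_sites)
        keep &= ~at_snp
    return m.subset_sites(keep)


# --------------------------------------------------------------------------
# Annotation and gene-level methylation
# --------------------------------------------------------------------------

def promoter_interval(tss: int, strand: str, upstream: int = 1500,
                      downstream: int = 500) -> tuple[int, int]:
    """Strand-aware promoter window around a TSS, half-open genome coords."""
    if strand == "+":
        return tss - upstream, tss + downstream
    return tss - downstream, tss + upstream


def annotate_positions(sites: pd.DataFrame, genes: pd.DataFrame,
                       promoter_upstream: int = 1500,
                       promoter_downstream: int = 500) -> pd.DataFrame:
    """Classify genomic positions as promoter / gene_body / intergenic.

    Promoter takes precedence over gene body; when a site falls in several
    promoters (or several gene bodies) the gene earliest in coordinate
    order wins, deterministically.
    """
    n_sites = len(sites)
    cls = np.array(["intergenic"] * n_sites, dtype=object)
    gene_id = np.array([""] * n_sites, dtype=object)
    pos = sites["pos"].to_numpy()
    for chrom, site_idx in sites.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(site_idx)
        p = pos[idx]
        g = genes[genes["chrom"] == chrom]
        # gene bodies first; promoters afterwards overwrite them
        for _, row in g.iterrows():
            inside = idx[(p >= row["txStart"]) & (p < row["txEnd"])]
            sel = inside[cls[inside] == "intergenic"]
            cls[sel] = "gene_body"
            gene_id[sel] = row["name"]
        assigned_prom = np.zeros(len(idx), dtype=bool)
        for _, row in g.iterrows():
            lo, hi = promoter_interval(int(row["tss"]), row["strand"],
                                       promoter_upstream, promoter_downstream)
            in_prom = (p >= lo) & (p < hi) & ~assigned_prom
            cls[idx[in_prom]] = "promoter"
            gene_id[idx[in_prom]] = row["name"]
            assigned_prom |= in_prom
    return pd.DataFrame({"region_class": cls, "gene_id": gene_id},
                        index=sites.index)


def annotate_cpgs(m: MethylationCountMatrix, genes: pd.DataFrame,
                  promoter_upstream: int = 1500,
                  promoter_downstream: int = 500) -> pd.DataFrame:
    """Annotate a count matrix's sites relative to genes (see
    :func:`annotate_positions`)."""
    return annotate_positions(m.sites, genes, promoter_upstream, promoter_downstream)


def gene_methylation(m: MethylationCountMatrix, annotation: pd.DataFrame,
                     region_class: str = "promoter") -> pd.DataFrame:
    """Per-gene per-sample mean methylation level in [0, 1].

    Unweighted mean of per-site proportions over the gene's sites of the
    requested class; NaN when a sample covers none of them.
    """
    props = m.proportions()
    mask = (annotation["region_class"] == region_class) & (annotation["gene_id"] != "")
    sub = props.loc[mask.to_numpy()]
    if sub.empty:
        return pd.DataFrame(columns=m.samples)
    out = sub.groupby(annotation.loc[mask.to_numpy(), "gene_id"].to_numpy()).mean()
    out.index.name = "gene_id"
    return out


# --------------------------------------------------------------------------
# Differential methylation
# --------------------------------------------------------------------------

@dataclass
class DmsResult:
    """Differential-methylation table for one population pair."""
    pop_a: str
    pop_b: str
    table: pd.DataFrame = field(repr=False)  # site rows: diff, p, q, dms


def _binomial_lrt(meth_a, cov_a, meth_b, cov_b):
    """Closed-form deviance test of group on methylation counts.

    Equivalent to a binomial logistic regression with a single two-level
    factor: the per-group MLE is the pooled proportion, so the LRT is
    2*(saturated-group log-likelihood minus pooled log-likelihood).
    """
    ma, ca = np.asarray(meth_a, float), np.asarray(cov_a, float)
    mb, cb = np.asarray(meth_b, float), np.asarray(cov_b, float)
    pa = np.divide(ma, ca, out=np.zeros_like(ma), where=ca > 0)
    pb = np.divide(mb, cb, out=np.zeros_like(mb), where=cb > 0)
    m0, c0 = ma + mb, ca + cb
    p0 = np.divide(m0, c0, out=np.zeros_like(m0), where=c0 > 0)

    def ll(mth, cv, p):
        return xlogy(mth, p) + xlogy(cv - mth, 1.0 - p)

    lrt = 2.0 * (ll(ma, ca, pa) + ll(mb, cb, pb) - ll(m0, c0, p0))
    lrt = np.maximum(lrt, 0.0)
    return lrt, chi2.sf(lrt, df=1)


def call_dms(m: MethylationCountMatrix, metadata: pd.DataFrame, pair: tuple[str, str],
             min_diff: float = 15.0, q_max: float = 0.0125) -> DmsResult:
    """Per-site differential methylation between two populations.

    The reported difference is the pooled (coverage-weighted) percentage
    difference 100*(sum meth_A/sum cov_A - sum meth_B/sum cov_B); p-values
    come from the binomial logistic-regression LRT and q-values from BH over
    all tested sites of this pair. Sites with zero total coverage in either
    population are reported untested.
    """
    a, b = pair
    pop = metadata.set_index("sample")["population"].reindex(m.samples)
    cols_a = [s for s in m.samples if pop[s] == a]
    cols_b = [s for s in m.samples if pop[s] == b]
    if not cols_a or not cols_b:
        raise DataError(f"population pair {pair} has no samples in the matrix")
    cov_a = np.nansum(m.cov[cols_a].to_numpy(), axis=1)
    meth_a = np.nansum(m.meth[cols_a].to_numpy(), axis=1)
    cov_b = np.nansum(m.cov[cols_b].to_numpy(), axis=1)
    meth_b = np.nansum(m.meth[cols_b].to_numpy(), axis=1)
    tested = (cov_a > 0) & (cov_b > 0)

    diff = np.full(m.n_sites, np.nan)
    diff[tested] = 100.0 * (meth_a[tested] / cov_a[tested]
                            - meth_b[tested] / cov_b[tested])
    p = np.full(m.n_sites, np.nan)
    _, p[tested] = _binomial_lrt(meth_a[tested], cov_a[tested],
                                 meth_b[tested], cov_b[tested])
    q = np.full(m.n_sites, np.nan)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    table = m.sites[["chrom", "pos", "strand"]].copy()
    table["tested"] = tested
    table["diff"] = diff
    table["p"] = p
    table["q"] = q
    table["dms"] = tested & (np.abs(diff) >= min_diff) & (q <= q_max)
    table["direction"] = np.sign(np.nan_to_num(diff)).astype(int)
    return DmsResult(pop_a=a, pop_b=b, table=table)


def call_all_pairwise_dms(m: MethylationCountMatrix, metadata: pd.DataFrame,
                          config: PipelineConfig) -> dict[tuple[str, str], DmsResult]:
    pops = sorted(metadata.loc[metadata["sample"].isin(m.samples), "population"].unique())
    return {(a, b): call_dms(m, metadata, (a, b),
                             min_diff=config.dms_min_diff, q_max=config.dms_max_q)
            for a, b in itertools.combinations(pops, 2)}


def population_specific_dms(results: dict[tuple[str, str], DmsResult],
                            population: str) -> pd.DataFrame:
    """Sites flagged DMS in *all* pairwise comparisons involving one
    population (its private methylation signature)."""
    involved = [r for pair, r in results.items() if population in pair]
    if not involved:
        raise DataError(f"no pairwise results involve population {population!r}")
    key = None
    for r in involved:
        flagged = r.table.loc[r.table["dms"], ["chrom", "pos"]]
        s = set(zip(flagged["chrom"], flagged["pos"].astype(int)))
        key = s if key is None else (key & s)
    t0 = involved[0].table
    mask = [(c, int(p)) in key for c, p in zip(t0["chrom"], t0["pos"])]
    return t0.loc[mask, ["chrom", "pos", "strand"]].reset_index(drop=True)


def unique_dms_sites(results: dict[tuple[str, str], DmsResult]) -> pd.DataFrame:
    """Union of DMS positions over all pairwise comparisons."""
    seen = set()
    rows = []
    for r in results.values():
        for _, row in r.table.loc[r.table["dms"]].iterrows():
            k = (row["chrom"], int(row["pos"]))
            if k not in seen:
                seen.add(k)
                rows.append((row["chrom"], int(row["pos"]), row["strand"]))
    return (pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
            .sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True))
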