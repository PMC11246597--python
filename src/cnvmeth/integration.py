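"""Joint analysis of copy number and DNA methylation.

Four questions, four tools:

* Does a gene's promoter (or gene-body) methylation track its copy number
  across individuals? Per-gene Pearson correlation with Benjamini-Hochberg
  FDR, globally or within one population.
* Do differentially methylated sites fall inside CNVs more often than
  chance? A length-matched permutation test: random regions with the same
  lengths as the tested intervals are placed uniformly on the genome and
  the DMS-overlap count recomputed.
* Do gene classes (lineage-specific vs older genes, CNV vs non-CNV,
  deletions vs duplications) differ in methylation? Mann-Whitney U.
* Are low-frequency CNVs over- or under-represented among genes with
  promoter methylation data? Chi-square on the 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError


# --------------------------------------------------------------------------
# Methylation x copy-number correlation
# --------------------------------------------------------------------------

def methylation_cn_correlation(gene_meth: pd.DataFrame, gene_cn: pd.DataFrame,
                               metadata: pd.DataFrame | None = None,
                               scope: str = "global",
                               region_class: str = "promoter",
                               min_samples: int = 3) -> pd.DataFrame:
    """Pearson correlation between per-gene methylation and copy number.

    ``gene_meth`` and ``gene_cn`` are gene x sample tables; the correlation
    runs across the samples common to both. ``scope`` is "global" or a
    population label (restricting the samples). Genes with fewer than
    ``min_samples`` informative samples or zero variance on either vector
    are reported untestable (NaN r) rather than forced to r = 0. BH
    correction is applied over the tested genes within this scope.
    """
    samples = [s for s in gene_meth.columns if s in gene_cn.columns]
    if scope != "global":
        if metadata is None:
            raise DataError("per-population scope requires metadata")
        pop = metadata.set_index("sample")["population"]
        samples = [s for s in samples if pop.get(s) == scope]
    rows = []
    for gene in gene_meth.index:
        if gene not in gene_cn.index:
            continue
        x = gene_cn.loc[gene, samples].to_numpy(dtype=float)
        y = gene_meth.loc[gene, samples].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        if n < min_samples or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            rows.append((gene, scope, region_class, np.nan, np.nan, n, "untestable"))
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        rows.append((gene, scope, region_class, float(r), float(p), n, ""))
    out = pd.DataFrame(rows, columns=["gene_id", "scope", "region_class",
                                      "r", "p", "n", "note"])
    out["q"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return out


# --------------------------------------------------------------------------
# Length-matched permutation overlap test
# --------------------------------------------------------------------------

@dataclass
class OverlapPermutationResult:
    observed: int
    null_counts: np.ndarray = field(repr=False)
    p: float

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_counts))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_counts))


def _count_overlaps(positions_by_chrom: dict[str, np.ndarray],
                    intervals: np.ndarray, chroms: np.ndarray) -> int:
    """Number of positions falling in any interval (union-aware)."""
    total = 0
    for chrom in np.unique(chroms):
        pos = positions_by_chrom.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        sel = chroms == chrom
        iv = intervals[sel]
        order = np.argsort(iv[:, 0], kind="mergesort")
        iv = iv[order]
        # merge to a union so a site in two intervals counts once
        merged_hits = np.zeros(len(pos), dtype=bool)
        cur_s, cur_e = None, None
        for s, e in iv:
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                lo, hi = np.searchsorted(pos, [cur_s, cur_e])
                merged_hits[lo:hi] = True
                cur_s, cur_e = s, e
        if cur_s is not None:
            lo, hi = np.searchsorted(pos, [cur_s, cur_e])
            merged_hits[lo:hi] = True
        total += int(merged_hits.sum())
    return total


def permutation_overlap(dms_sites: pd.DataFrame, intervals: pd.DataFrame,
                        chromosome_lengths: dict[str, int], n_perm: int = 1000,
                        seed: int = 0,
                        chromosome_matched: bool = False) -> OverlapPermutationResult:
    """Permutation test of DMS falling inside a set of genomic intervals.

    Observed = number of DMS positions inside any tested interval. Each
    permutation re-places every interval (keeping its length) uniformly at
    random: the chromosome is drawn proportional to length (or held fixed
    when ``chromosome_matched``) and the start uniform among positions where
    the interval fits; chromosomes shorter than the interval are never
    drawn, and an interval longer than every chromosome is an error.
    Empirical p = (#{null >= observed} + 1) / (n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    chrom_names = list(chromosome_lengths)
    lengths = np.array([chromosome_lengths[c] for c in chrom_names], dtype=float)
    iv_len = (intervals["end"] - intervals["start"]).to_numpy()
    if (iv_len > lengths.max()).any():
        raise DataError("an interval is longer than every chromosome")
    pos_by_chrom = {c: np.sort(g["pos"].to_numpy())
                    for c, g in dms_sites.groupby("chrom", sort=False)}
    obs_iv = intervals[["start", "end"]].to_numpy()
    observed = _count_overlaps(pos_by_chrom, obs_iv, intervals["chrom"].to_numpy())

    n_iv = len(iv_len)
    fits = iv_len[None, :] <= lengths[:, None]  # chrom x interval
    if chromosome_matched:
        name_to_idx = {c: i for i, c in enumerate(chrom_names)}
        chosen_idx = np.tile(
            intervals["chrom"].map(name_to_idx).to_numpy()[None, :], (n_perm, 1))
    else:
        chosen_idx = np.empty((n_perm, n_iv), dtype=np.int64)
        for j in range(n_iv):  # each interval has its own feasible chromosomes
            ok = np.where(fits[:, j])[0]
            w = lengths[ok] / lengths[ok].sum()
            chosen_idx[:, j] = rng.choice(ok, size=n_perm, p=w)
    chosen_len = lengths[chosen_idx]
    starts = np.floor(rng.random((n_perm, n_iv))
                      * (chosen_len - iv_len[None, :] + 1)).astype(np.int64)
    chrom_arr = np.array(chrom_names, dtype=object)
    null = np.empty(n_perm, dtype=int)
    for it in range(n_perm):
        iv = np.column_stack([starts[it], starts[it] + iv_len])
        null[it] = _count_overlaps(pos_by_chrom, iv, chrom_arr[chosen_idx[it]])
    p = (int((null >= observed).sum()) + 1) / (n_perm + 1)
    return OverlapPermutationResult(observed=observed, null_counts=null, p=p)


# --------------------------------------------------------------------------
# Gene-type comparisons
# --------------------------------------------------------------------------

def gene_type_comparison(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Two-sided Mann-Whitney U tests between every pair of named groups.

    Returns one row per pair with U, p, and each group's n/mean/SD. A group
    with n = 0 is an error.
    """
    for name, vals in values_by_group.items():
        if len(vals) == 0:
            raise DataError(f"group {name!r} is empty")
    names = list(values_by_group)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.asarray(values_by_group[names[i]], dtype=float)
            b = np.asarray(values_by_group[names[j]], dtype=float)
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            if len(a) == 0 or len(b) == 0:
                raise DataError("group has no non-missing values")
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append((names[i], names[j], float(u), float(p),
                         len(a), float(a.mean()), float(a.std(ddof=1)) if len(a) > 1 else 0.0,
                         len(b), float(b.mean()), float(b.std(ddof=1)) if len(b) > 1 else 0.0))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "U", "p",
                                       "n_a", "mean_a", "sd_a",
                                       "n_b", "mean_b", "sd_b"])


# --------------------------------------------------------------------------
# Low-frequency CNV chi-square
# --------------------------------------------------------------------------

def low_frequency_chisq(low_frequency: np.ndarray, has_promoter_data: np.ndarray):
    """Chi-square on the 2x2 table (low-frequency CNV?) x (promoter data?).

    Inputs are aligned boolean arrays over gene CNVs. No continuity
    correction, so the statistic matches the textbook sum of
    (observed-expected)^2/expected. Zero margins are an error.
    """
    lf = np.asarray(low_frequency, dtype=bool)
    pm = np.asarray(has_promoter_data, dtype=bool)
    if lf.shape != pm.shape:
        raise DataError("input flag arrays differ in length")
    table = np.array([[np.sum(lf & pm), np.sum(lf & ~pm)],
                      [np.sum(~lf & pm), np.sum(~lf & ~pm)]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DataError(
            "degenerate 2x2 table (a zero margin): every gene falls in one "
            "stratum, the chi-square test is undefined")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"table": table, "statistic": float(stat), "p": float(p)}
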