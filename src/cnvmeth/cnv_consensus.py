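"""Multi-caller CNV consensus, depth-based region filtering and genotyping.

The pipeline takes structural-variant calls from several callers that rely
on different evidence (read depth, discordant read pairs, split reads),
keeps read-depth calls corroborated by an independent caller, filters the
resulting regions on cross-sample normalized depth, and assigns each sample
an integer copy number (0 = homozygous deletion, 1 = heterozygous deletion,
2 = diploid, >2 = duplication) from its mean normalized depth, guided by
k-means clustering of the per-sample means.

All interval arithmetic is 0-based half-open. Normalized depth is
dimensionless with diploid = 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .config import PipelineConfig
from .errors import ConfigError, DataError

GENOTYPE_CLASSES = {0: "hom-del", 1: "het-del", 2: "diploid"}


def genotype_class(cn: int) -> str:
    """Map an integer copy number to its genotype class label."""
    return GENOTYPE_CLASSES.get(int(cn), "dup")


# --------------------------------------------------------------------------
# Depth matrix
# --------------------------------------------------------------------------

@dataclass
class DepthMatrix:
    """Normalized read depth per genomic window per sample.

    windows : DataFrame with chrom/start/end, sorted within chromosome.
    values  : DataFrame (n_windows x n_samples), index-aligned to windows.
    """

    windows: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.windows) != len(self.values):
            raise DataError("DepthMatrix: windows and values length mismatch")
        if (self.values.to_numpy() < 0).any():
            raise DataError("DepthMatrix: negative depth")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def region_summary(self, regions: pd.DataFrame, summary: str = "mean") -> pd.DataFrame:
        """Per-region per-sample depth summary over overlapping windows.

        ``mean`` is overlap-length weighted; ``median`` is the plain median
        of overlapping window values. Raises DataError for a region with no
        overlapping windows.
        """
        vals = self.values.to_numpy()
        out = np.empty((len(regions), vals.shape[1]))
        w_by_chrom = {c: g for c, g in self.windows.groupby("chrom", sort=False)}
        for i, (_, r) in enumerate(regions.iterrows()):
            g = w_by_chrom.get(r["chrom"])
            if g is None:
                raise DataError(f"region on {r['chrom']!r} has no depth windows")
            starts = g["start"].to_numpy()
            ends = g["end"].to_numpy()
            lo = np.searchsorted(ends, r["start"], side="right")
            hi = np.searchsorted(starts, r["end"], side="left")
            if hi <= lo:
                raise DataError(
                    f"region {r['chrom']}:{r['start']}-{r['end']} overlaps no depth windows")
            idx = g.index[lo:hi]
            overlap = (np.minimum(ends[lo:hi], r["end"])
                       - np.maximum(starts[lo:hi], r["start"])).astype(float)
            block = vals[idx]
            if summary == "mean":
                out[i] = overlap @ block / overlap.sum()
            elif summary == "median":
                out[i] = np.median(block, axis=0)
            else:
                raise ConfigError(f"unknown depth summary {summary!r}")
        return pd.DataFrame(out, index=regions.index, columns=self.values.columns)


def normalize_depth(raw: DepthMatrix, sex_chromosomes: tuple[str, ...] = ()) -> DepthMatrix:
    """Scale each sample so its autosomal median depth is exactly 2."""
    autosomal = ~raw.windows["chrom"].isin(sex_chromosomes)
    if not autosomal.any():
        raise DataError("no autosomal windows to normalize against")
    med = raw.values.loc[autosomal.to_numpy()].median(axis=0)
    zero = med[med <= 0]
    if len(zero):
        raise DataError(f"sample(s) with zero autosomal median depth: {list(zero.index)[:5]}")
    scaled = raw.values / med * 2.0
    return DepthMatrix(windows=raw.windows.copy(), values=scaled)


# --------------------------------------------------------------------------
# Caller-level filters
# --------------------------------------------------------------------------

def filter_caller_calls(calls: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Apply per-caller evidence filters; returns calls with kept/reason columns.

    Paired-read callers: kept iff per-sample coverage at the call is at most
    ``paired_max_coverage`` and supporting read pairs reach
    ``paired_min_read_pairs``. Callers using both paired and split reads:
    kept iff mapping quality strictly exceeds ``paired_split_min_mapq``,
    total supporting reads reach ``paired_split_min_support``, and the call
    is no longer than ``paired_split_max_length``. Read-depth-only and
    split-read-only callers pass unchanged at this stage.
    """
    unknown = set(calls["caller"]) - set(config.caller_types)
    if unknown:
        raise ConfigError(f"unknown caller name(s): {sorted(unknown)}")
    df = calls.copy()
    kept = np.ones(len(df), dtype=bool)
    reason = np.array([""] * len(df), dtype=object)
    ctype = df["caller"].map(config.caller_types).to_numpy()
    length = (df["end"] - df["start"]).to_numpy()

    is_paired = ctype == "paired"
    bad_cov = is_paired & (df["max_coverage"].to_numpy() > config.paired_max_coverage)
    bad_pairs = is_paired & (df["read_pairs"].to_numpy() < config.paired_min_read_pairs)
    is_ps = ctype == "paired_split"
    support = (df["read_pairs"].fillna(0) + df["split_reads"].fillna(0)).to_numpy()
    bad_mapq = is_ps & ~(df["mapq"].to_numpy() > config.paired_split_min_mapq)
    bad_support = is_ps & (support < config.paired_split_min_support)
    bad_len = is_ps & (length > config.paired_split_max_length)

    for mask, why in [(bad_cov, "coverage above maximum"),
                      (bad_pairs, "too few supporting read pairs"),
                      (bad_mapq, "mapping quality not above minimum"),
                      (bad_support, "too few supporting reads"),
                      (bad_len, "call longer than maximum")]:
        newly = mask & kept
        reason[newly] = why
        kept &= ~mask
    df["kept"] = kept
    df["reason"] = reason
    return df


# --------------------------------------------------------------------------
# Consensus
# --------------------------------------------------------------------------

def consensus_overlap(primary_calls: pd.DataFrame, other_calls: pd.DataFrame,
                      min_fraction: float = 0.5) -> pd.DataFrame:
    """Retain primary (read-depth) calls corroborated by another caller.

    A primary call is retained iff a call of the same CNV class from a
    different caller overlaps at least ``min_fraction`` of the *primary*
    call's length (boundary inclusive). Output regions keep the primary
    caller's breakpoints.
    """
    regions = []
    others = other_calls
    for (chrom, klass), grp in primary_calls.groupby(["chrom", "cnv_class"], sort=False):
        cand = others[(others["chrom"] == chrom) & (others["cnv_class"] == klass)]
        o_start = cand["start"].to_numpy()
        o_end = cand["end"].to_numpy()
        o_caller = cand["caller"].to_numpy()
        for _, p in grp.iterrows():
            ov = np.minimum(o_end, p["end"]) - np.maximum(o_start, p["start"])
            frac = ov / (p["end"] - p["start"])
            hit = (frac >= min_fraction) & (o_caller != p["caller"])
            if hit.any():
                supporters = sorted(set(o_caller[hit]))
                regions.append((chrom, int(p["start"]), int(p["end"]), klass,
                                ",".join(supporters)))
    df = pd.DataFrame(regions, columns=["chrom", "start", "end", "cnv_class", "supporting_callers"])
    df = df.drop_duplicates(subset=["chrom", "start", "end", "cnv_class"])
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "region_id", [f"cnvr{i:05d}" for i in range(len(df))])
    return df


# --------------------------------------------------------------------------
# Region depth filter
# --------------------------------------------------------------------------

def _depth_conditions(means: np.ndarray, config: PipelineConfig) -> str:
    """Return "" if all three cross-sample depth conditions hold, else the
    first failing condition's reason."""
    if not ((means > config.depth_cond1_above).any()
            and (means < config.depth_cond1_below).any()):
        return "cond1: no individual above/below depth bounds"
    rng = means.max() - means.min()
    if rng < config.depth_cond2_min_range:
        return "cond2: depth range below minimum"
    if not (rng > config.depth_cond3_min_diff):
        return "cond3: no pair with depth difference above threshold"
    return ""


def region_depth_filter(regions: pd.DataFrame, depth: DepthMatrix,
                        config: PipelineConfig) -> pd.DataFrame:
    """Apply the three cross-sample depth conditions to each region.

    (1) some individual above ``depth_cond1_above`` and some below
    ``depth_cond1_below``; (2) the depth range across individuals reaches
    ``depth_cond2_min_range``; (3) some pair of individuals differs by more
    than ``depth_cond3_min_diff``. Returns the regions with ``retained``
    and ``reason`` columns; the reason is the first failing condition.
    """
    out = regions.copy()
    summary = depth.region_summary(regions, config.region_depth_summary)
    reasons = [_depth_conditions(row, config) for row in summary.to_numpy()]
    out["retained"] = [r == "" for r in reasons]
    out["reason"] = reasons
    return out


# --------------------------------------------------------------------------
# Genotyping
# --------------------------------------------------------------------------

def depth_to_bin(depth: np.ndarray) -> np.ndarray:
    """Integer copy-number bin for a normalized depth: half-open bins of
    width 1 centered on integers, ties at x.5 assigned to the higher bin."""
    return np.maximum(np.floor(np.asarray(depth) + 0.5), 0).astype(int)


def _calinski_harabasz(x: np.ndarray, labels: np.ndarray) -> float:
    """CH index for a 1-D clustering; +inf for a perfect (zero within-
    dispersion) partition so it outranks any noisy alternative."""
    n = len(x)
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2 or k >= n:
        return -np.inf
    overall = x.mean()
    w = 0.0
    b = 0.0
    for u in uniq:
        xs = x[labels == u]
        c = xs.mean()
        w += ((xs - c) ** 2).sum()
        b += len(xs) * (c - overall) ** 2
    if w <= 1e-12:
        return np.inf
    return (b / (k - 1)) / (w / (n - k))


def _genotype_one(means: np.ndarray, config: PipelineConfig, seed: int):
    """Genotype one region from per-sample mean depths.

    Candidate partitions are the depth-cutoff bin assignment plus k-means
    solutions for k in 2..min(k_max, n-1). A candidate is
    genotype-consistent when every cluster center sits within
    ``cluster_match_tolerance`` of a distinct non-negative integer copy
    number; among consistent candidates the highest Calinski-Harabasz index
    wins (a zero-within-dispersion partition scores +inf) and samples get
    their cluster's integer. A region with no consistent candidate is
    excluded: its depth distribution does not match any copy-number
    genotype configuration.

    Returns (copy_numbers or None, reason).
    """
    n = len(means)
    if n < 2:
        raise DataError("genotyping requires at least 2 samples")
    x = np.asarray(means, dtype=float)
    if np.ptp(x) < 1e-12:
        return None, "constant depth"
    candidates: list[tuple[float, np.ndarray, np.ndarray]] = []  # (score, labels, centers)

    bins = depth_to_bin(x)
    if len(np.unique(bins)) >= 2:
        centers = np.array([x[bins == b].mean() for b in np.unique(bins)])
        relab = np.searchsorted(np.unique(bins), bins)
        candidates.append((_calinski_harabasz(x, relab), relab, centers))

    n_distinct = len(np.unique(x))
    k_hi = min(config.genotype_k_max, n - 1, n_distinct)
    for k in range(2, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=config.genotype_n_init,
                    random_state=seed & 0x7FFFFFFF)
        labels = km.fit_predict(x.reshape(-1, 1))
        centers = km.cluster_centers_.ravel()
        candidates.append((_calinski_harabasz(x, labels), labels, centers))

    if not candidates:
        return None, "too few distinct depths to cluster"
    consistent = []
    for score, labels, centers in candidates:
        used = np.unique(labels)
        cluster_centers = centers[used]
        ints = np.maximum(np.rint(cluster_centers), 0).astype(int)
        dist = np.abs(cluster_centers - ints)
        if (dist <= config.cluster_match_tolerance).all() and len(set(ints)) == len(ints):
            mapping = {u: ints[i] for i, u in enumerate(used)}
            consistent.append((score, labels, mapping))
    if not consistent:
        return None, "cluster-genotype mismatch"
    # best-supported consistent clustering wins; ties favor fewer clusters
    score, labels, mapping = max(consistent, key=lambda c: (c[0], -len(c[2])))
    return np.array([mapping[l] for l in labels], dtype=int), ""


def genotype_regions(regions: pd.DataFrame, depth: DepthMatrix, config: PipelineConfig,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign integer copy numbers per sample for each retained region.

    Returns ``(copy_numbers, status)`` where copy_numbers is a DataFrame
    (region_id x sample) for the regions that genotyped cleanly, and status
    records every input region with its exclusion reason (empty if kept).
    """
    summary = depth.region_summary(regions, config.region_depth_summary)
    rows = {}
    status = []
    for i, (idx, r) in enumerate(regions.iterrows()):
        cn, reason = _genotype_one(summary.loc[idx].to_numpy(), config, seed + i)
        status.append((r["region_id"], reason == "", reason))
        if cn is not None:
            rows[r["region_id"]] = cn
    cn_df = pd.DataFrame.from_dict(rows, orient="index", columns=depth.samples)
    cn_df.index.name = "region_id"
    status_df = pd.DataFrame(status, columns=["region_id", "genotyped", "reason"])
    return cn_df, status_df


# --------------------------------------------------------------------------
# Sex-specific flagging
# --------------------------------------------------------------------------

def flag_sex_specific(cn: pd.DataFrame, metadata: pd.DataFrame,
                      min_carriers: int = 2) -> pd.DataFrame:
    """Flag regions whose carriers (copy number != 2) are all of one sex.

    Requires at least ``min_carriers`` same-sex carriers and zero carriers
    of the opposite sex; carriers of unknown sex make a region unflaggable.
    """
    sex = metadata.set_index("sample")["sex"]
    flags = []
    for region_id, row in cn.iterrows():
        carriers = row.index[row.to_numpy() != 2]
        sexes = set(sex.reindex(carriers))
        flagged = (len(carriers) >= min_carriers and len(sexes) == 1
                   and next(iter(sexes)) in ("M", "F"))
        flags.append((region_id, flagged, next(iter(sexes)) if flagged else ""))
    return pd.DataFrame(flags, columns=["region_id", "sex_specific", "carrier_sex"])


# --------------------------------------------------------------------------
# Gene overlap and gene-level re-filter
# --------------------------------------------------------------------------

def gene_overlap(regions: pd.DataFrame, genes: pd.DataFrame,
                 full_threshold: float = 0.9) -> pd.DataFrame:
    """One record per (gene, overlapping region), classified full/partial.

    ``full`` means the region covers at least ``full_threshold`` of the
    gene's length (loose breakpoints from read-depth calling motivate the
    slack); anything less is ``partial``.
    """
    records = []
    for chrom, grp in regions.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        g_start = g["txStart"].to_numpy()
        g_end = g["txEnd"].to_numpy()
        for _, r in grp.iterrows():
            ov = np.minimum(g_end, r["end"]) - np.maximum(g_start, r["start"])
            hit = np.where(ov > 0)[0]
            for j in hit:
                frac = ov[j] / (g_end[j] - g_start[j])
                records.append((g.iloc[j]["name"], r["region_id"], r["cnv_class"],
                                float(min(frac, 1.0)),
                                "full" if frac >= full_threshold else "partial"))
    df = pd.DataFrame(records, columns=["gene_id", "region_id", "cnv_class",
                                        "overlap_fraction", "classification"])
    return df.sort_values(["gene_id", "region_id"], kind="mergesort").reset_index(drop=True)


def gene_depth_refilter(gene_cnvs: pd.DataFrame, genes: pd.DataFrame, depth: DepthMatrix,
                        config: PipelineConfig) -> pd.DataFrame:
    """Re-apply the three depth conditions on each CNV gene's own interval.

    A gene-CNV record survives only if the depth signal *within the gene
    coordinates* still shows distinct copy-number differences; this drops
    genes dragged in by a neighboring CNV without depth support of their
    own. Adds ``retained``/``reason`` columns.
    """
    out = gene_cnvs.copy()
    if out.empty:
        out["retained"] = []
        out["reason"] = []
        return out
    gene_ids = out["gene_id"].unique()
    gsub = genes.set_index("name").loc[gene_ids]
    intervals = pd.DataFrame({"chrom": gsub["chrom"].to_numpy(),
                              "start": gsub["txStart"].to_numpy(),
                              "end": gsub["txEnd"].to_numpy()}, index=gene_ids)
    summary = depth.region_summary(intervals, config.region_depth_summary)
    reasons = {gid: _depth_conditions(summary.loc[gid].to_numpy(), config)
               for gid in gene_ids}
    out["reason"] = out["gene_id"].map(reasons)
    out["retained"] = out["reason"] == ""
    return out


def assign_gene_copy_numbers(gene_cnvs: pd.DataFrame, cn: pd.DataFrame) -> pd.DataFrame:
    """Per-gene per-sample copy numbers, inherited from the overlapping
    region (the one with the largest overlap fraction when several)."""
    kept = gene_cnvs[gene_cnvs["region_id"].isin(cn.index)]
    if kept.empty:
        return pd.DataFrame(columns=cn.columns)
    best = (kept.sort_values("overlap_fraction", kind="mergesort")
                .groupby("gene_id").tail(1))
    out = cn.loc[best["region_id"]].copy()
    out.index = best["gene_id"].to_numpy()
    out.index.name = "gene_id"
    return out.sort_index()
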