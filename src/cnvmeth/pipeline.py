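"""End-to-end orchestration: simulate -> CNV -> popgen -> methylation ->
integration, with every intermediate table written as TSV/BED.

Each stage is a plain function over the library modules so the numbered
analysis scripts, the CLI and the tests all share one code path. The
``evaluate_*`` helpers compare pipeline output against the generator's
truth tables (only meaningful on simulated data).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv_consensus as cc
from . import integration as integ
from . import methylation as meth
from . import popgen
from .config import PipelineConfig
from .synthetic_data import SimulatedDataset, SimulationConfig, simulate_dataset


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def run_cnv_stage(ds: SimulatedDataset, config: PipelineConfig, seed: int = 0) -> dict:
    """Caller filters -> consensus -> depth filter -> genotypes -> gene CNVs."""
    sexchroms = tuple(ds.config.sex_chromosomes)
    filtered = cc.filter_caller_calls(ds.caller_calls, config)
    kept = filtered[filtered["kept"]]
    ctype = kept["caller"].map(config.caller_types)
    primary = kept[ctype == "read_depth"]
    others = kept[ctype != "read_depth"]
    regions = cc.consensus_overlap(primary, others, config.consensus_min_overlap)

    depth = cc.normalize_depth(ds.depth_raw, sexchroms)
    region_status = cc.region_depth_filter(regions, depth, config)
    retained = region_status[region_status["retained"]].drop(columns=["retained", "reason"])

    cn, genotype_status = cc.genotype_regions(retained, depth, config, seed=seed)
    flags = cc.flag_sex_specific(cn, ds.metadata, config.sex_specific_min_carriers)
    sex_ids = set(flags.loc[flags["sex_specific"], "region_id"])
    cn_auto = cn.loc[[r for r in cn.index if r not in sex_ids]]
    regions_auto = retained[retained["region_id"].isin(cn_auto.index)]

    gene_cnvs = cc.gene_overlap(regions_auto, ds.genome.genes, config.gene_full_overlap)
    gene_refilt = cc.gene_depth_refilter(gene_cnvs, ds.genome.genes, depth, config)
    gene_kept = gene_refilt[gene_refilt["retained"]].drop(columns=["retained", "reason"])
    gene_cn = cc.assign_gene_copy_numbers(gene_kept, cn_auto)
    return {"caller_calls_filtered": filtered, "regions_consensus": regions,
            "region_status": region_status, "regions": regions_auto,
            "genotype_status": genotype_status, "copy_numbers": cn_auto,
            "sex_flags": flags, "gene_cnvs_all": gene_refilt,
            "gene_cnvs": gene_kept, "gene_copy_numbers": gene_cn,
            "depth": depth}


def run_popgen_stage(cnv: dict, metadata: pd.DataFrame, config: PipelineConfig) -> dict:
    """V_st scan with outliers, frequencies, sharing, per-class PCA."""
    cn = cnv["copy_numbers"]
    vst_table, vst_outliers = popgen.vst_scan(cn, metadata, config)
    freqs = popgen.cnv_frequencies(cn, metadata)
    sharing = popgen.sharing_summary(cn, metadata)
    regions = cnv["regions"].set_index("region_id")
    pcas = {}
    for klass in ("deletion", "duplication"):
        ids = [r for r in cn.index if regions.at[r, "cnv_class"] == klass]
        presence = (cn.loc[ids] != 2).astype(float)
        informative = presence[presence.sum(axis=1) > 0]
        if len(informative) >= 2:
            pcas[klass] = popgen.pca_presence(informative)
    gene_vst = {}
    if len(cnv["gene_copy_numbers"]):
        gene_vst["table"], gene_vst["outliers"] = popgen.vst_scan(
            cnv["gene_copy_numbers"], metadata, config)
    return {"vst_table": vst_table, "vst_outliers": vst_outliers,
            "frequencies": freqs, "sharing": sharing, "pca": pcas,
            "gene_vst": gene_vst}


def run_methylation_stage(ds: SimulatedDataset, config: PipelineConfig) -> dict:
    """Coverage filters -> normalization -> unite -> exclusions -> DMS."""
    m = meth.filter_coverage(ds.cpg_counts, config.coverage_min,
                             config.coverage_upper_percentile)
    m = meth.normalize_coverage(m)
    m = meth.unite_sites(m, ds.metadata, config.unite_min_per_group,
                         config.unite_max_missing)
    m = meth.exclude_sites(m, ds.snp_positions, tuple(ds.config.sex_chromosomes))
    annotation = meth.annotate_cpgs(m, ds.genome.genes,
                                    config.promoter_upstream, config.promoter_downstream)
    promoter_meth = meth.gene_methylation(m, annotation, "promoter")
    body_meth = meth.gene_methylation(m, annotation, "gene_body")
    dms = meth.call_all_pairwise_dms(m, ds.metadata, config)
    dms_sites = meth.unique_dms_sites(dms)
    pops = sorted(ds.metadata["population"].unique())
    pop_specific = {p: meth.population_specific_dms(dms, p) for p in pops}
    pca = None
    if len(dms_sites) >= 2:
        keys = set(zip(dms_sites["chrom"], dms_sites["pos"].astype(int)))
        mask = np.fromiter(((c, int(p)) in keys
                            for c, p in zip(m.sites["chrom"], m.sites["pos"])),
                           dtype=bool, count=m.n_sites)
        props = m.proportions().loc[mask]
        complete = props.dropna(axis=0)
        if len(complete) >= 2:
            pca = popgen.pca_presence(props)
    return {"matrix": m, "annotation": annotation,
            "promoter_methylation": promoter_meth, "body_methylation": body_meth,
            "dms": dms, "dms_sites": dms_sites, "population_specific_dms": pop_specific,
            "pca": pca}


def run_integration_stage(ds: SimulatedDataset, cnv: dict, methyl: dict,
                          config: PipelineConfig, seed: int = 0) -> dict:
    """Correlations, permutation overlap tests, group comparisons, chi-square."""
    gene_cn = cnv["gene_copy_numbers"]
    prom = methyl["promoter_methylation"]
    body = methyl["body_methylation"]
    correlations = {"promoter_global": integ.methylation_cn_correlation(
        prom, gene_cn, ds.metadata, "global", "promoter",
        config.correlation_min_samples)}
    correlations["gene_body_global"] = integ.methylation_cn_correlation(
        body, gene_cn, ds.metadata, "global", "gene_body",
        config.correlation_min_samples)
    for p in sorted(ds.metadata["population"].unique()):
        correlations[f"promoter_{p}"] = integ.methylation_cn_correlation(
            prom, gene_cn, ds.metadata, p, "promoter", config.correlation_min_samples)

    dms_sites = methyl["dms_sites"]
    chrom_lengths = dict(ds.genome.chromosomes)
    for c in ds.config.sex_chromosomes:       # DMS exclude sex chromosomes
        chrom_lengths.pop(c, None)
    perms = {}
    if len(dms_sites):
        cnv_iv = cnv["regions"][["chrom", "start", "end"]]
        if len(cnv_iv):
            perms["cnv"] = integ.permutation_overlap(
                dms_sites, cnv_iv, chrom_lengths, config.n_permutations, seed,
                config.permutation_chromosome_matched)
        genes_idx = ds.genome.genes.set_index("name")
        cnv_gene_ids = [g for g in cnv["gene_cnvs"]["gene_id"].unique()
                        if g in genes_idx.index]
        if cnv_gene_ids:
            gsub = genes_idx.loc[cnv_gene_ids]
            gene_iv = pd.DataFrame({"chrom": gsub["chrom"].to_numpy(),
                                    "start": gsub["txStart"].to_numpy(),
                                    "end": gsub["txEnd"].to_numpy()})
            perms["gene_cnv"] = integ.permutation_overlap(
                dms_sites, gene_iv, chrom_lengths, config.n_permutations, seed + 1,
                config.permutation_chromosome_matched)

    # gene-type and CNV-status comparisons on mean promoter methylation
    mean_prom = prom.mean(axis=1)
    gene_type = ds.genome.genes.set_index("name")["gene_type"]
    is_lsg = mean_prom.index.map(lambda g: gene_type.get(g) == "LSG")
    cnv_genes = set(cnv["gene_cnvs"]["gene_id"])
    is_cnv = mean_prom.index.isin(cnv_genes)
    comparisons = {}
    if is_lsg.to_numpy().any() and (~is_lsg.to_numpy()).any():
        comparisons["lsg_vs_other"] = integ.gene_type_comparison(
            {"LSG": mean_prom[is_lsg].to_numpy(),
             "non-LSG": mean_prom[~is_lsg].to_numpy()})
    if is_cnv.any() and (~is_cnv).any():
        comparisons["cnv_vs_noncnv"] = integ.gene_type_comparison(
            {"CNV": mean_prom[is_cnv].to_numpy(),
             "non-CNV": mean_prom[~is_cnv].to_numpy()})
    klass = cnv["gene_cnvs"].drop_duplicates("gene_id").set_index("gene_id")["cnv_class"]
    dels = [g for g in mean_prom.index if klass.get(g) == "deletion"]
    dups = [g for g in mean_prom.index if klass.get(g) == "duplication"]
    if dels and dups:
        comparisons["deletion_vs_duplication"] = integ.gene_type_comparison(
            {"deletion": mean_prom[dels].to_numpy(),
             "duplication": mean_prom[dups].to_numpy()})

    # low-frequency CNV chi-square over gene CNVs
    chisq = None
    gene_ids = cnv["gene_cnvs"]["gene_id"].unique()
    if len(gene_ids):
        carrier_counts = (cnv["gene_copy_numbers"] != 2).sum(axis=1)
        n = len(ds.metadata)
        low = np.array([
            (carrier_counts.get(g, 0) / n) < config.low_frequency_threshold
            for g in gene_ids])
        has_prom = np.array([g in prom.index for g in gene_ids])
        try:
            chisq = integ.low_frequency_chisq(low, has_prom)
        except Exception:
            chisq = None  # degenerate table on small runs
    return {"correlations": correlations, "permutations": perms,
            "comparisons": comparisons, "low_frequency_chisq": chisq}


# --------------------------------------------------------------------------
# Truth-based evaluation
# --------------------------------------------------------------------------

def truth_gene_copy_numbers(ds: SimulatedDataset) -> pd.DataFrame:
    """Gene x sample copy numbers read straight off the simulation truth
    (the locus overlapping each gene)."""
    rows = {}
    for _, g in ds.genome.genes.iterrows():
        hits = ds.truth.loci[
            (ds.truth.loci["chrom"] == g["chrom"])
            & (ds.truth.loci["start"] < g["txEnd"])
            & (ds.truth.loci["end"] > g["txStart"])]
        if len(hits):
            rows[g["name"]] = ds.truth.copy_numbers.loc[hits.iloc[0]["locus_id"]]
    return pd.DataFrame(rows).T


def match_regions_to_truth(regions: pd.DataFrame, truth_loci: pd.DataFrame) -> dict:
    """Map each called region to the truth locus it overlaps most."""
    mapping = {}
    for _, r in regions.iterrows():
        t = truth_loci[truth_loci["chrom"] == r["chrom"]]
        if t.empty:
            continue
        ov = (np.minimum(t["end"].to_numpy(), r["end"])
              - np.maximum(t["start"].to_numpy(), r["start"]))
        j = int(np.argmax(ov))
        if ov[j] > 0:
            mapping[r["region_id"]] = t.iloc[j]["locus_id"]
    return mapping


def copy_number_concordance(cn: pd.DataFrame, regions: pd.DataFrame,
                            truth) -> float:
    """Fraction of per-sample per-region copy-number calls equal to truth."""
    mapping = match_regions_to_truth(regions, truth.loci)
    agree = total = 0
    for region_id, locus_id in mapping.items():
        if region_id not in cn.index:
            continue
        called = cn.loc[region_id]
        true = truth.copy_numbers.loc[locus_id, called.index]
        agree += int((called.to_numpy() == true.to_numpy()).sum())
        total += len(called)
    return agree / total if total else float("nan")


def vst_outlier_recall(vst_outliers: pd.DataFrame, regions: pd.DataFrame,
                       truth) -> float:
    """Fraction of truth-differentiated loci with >=1 outlier V_st record."""
    mapping = match_regions_to_truth(regions, truth.loci)
    outlier_regions = set(vst_outliers["region_id"])
    hit_loci = {mapping[r] for r in outlier_regions if r in mapping}
    diff_loci = set(truth.loci.loc[truth.loci["differentiated"], "locus_id"])
    if not diff_loci:
        return float("nan")
    return len(diff_loci & hit_loci) / len(diff_loci)


# --------------------------------------------------------------------------
# run-all
# --------------------------------------------------------------------------

def run_all(sim_config: SimulationConfig | None = None,
            config: PipelineConfig | None = None,
            outdir: str | Path | None = None, seed: int | None = None) -> dict:
    """Simulate a cohort and run every stage; optionally write all tables."""
    sim_config = sim_config or SimulationConfig()
    if seed is not None:
        sim_config.seed = seed
    config = config or PipelineConfig()
    ds = simulate_dataset(sim_config)
    cnv = run_cnv_stage(ds, config, seed=sim_config.seed)
    pg = run_popgen_stage(cnv, ds.metadata, config)
    my = run_methylation_stage(ds, config)
    it = run_integration_stage(ds, cnv, my, config, seed=sim_config.seed)
    results = {"dataset": ds, "cnv": cnv, "popgen": pg, "methylation": my,
               "integration": it,
               "concordance": copy_number_concordance(
                   cnv["copy_numbers"], cnv["regions"], ds.truth),
               "vst_recall": vst_outlier_recall(
                   pg["vst_outliers"], cnv["regions"], ds.truth)}
    if outdir is not None:
        write_results(results, outdir, config)
    return results


def write_results(results: dict, outdir: str | Path, config: PipelineConfig) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.echo(out)
    cnv, pg, my, it = (results["cnv"], results["popgen"],
                       results["methylation"], results["integration"])
    cnv["regions"].to_csv(out / "cnv_regions.tsv", sep="\t", index=False)
    cnv["region_status"].to_csv(out / "cnv_region_status.tsv", sep="\t", index=False)
    cnv["copy_numbers"].to_csv(out / "copy_numbers.tsv", sep="\t")
    cnv["sex_flags"].to_csv(out / "sex_specific_flags.tsv", sep="\t", index=False)
    cnv["gene_cnvs_all"].to_csv(out / "gene_cnvs_status.tsv", sep="\t", index=False)
    cnv["gene_copy_numbers"].to_csv(out / "gene_copy_numbers.tsv", sep="\t")
    pg["vst_table"].to_csv(out / "vst_pairwise.tsv", sep="\t", index=False)
    pg["vst_outliers"].to_csv(out / "vst_outliers.tsv", sep="\t", index=False)
    pg["frequencies"].to_csv(out / "cnv_frequencies.tsv", sep="\t", index=False)
    pg["sharing"]["intersections"].to_csv(out / "cnv_sharing.tsv", sep="\t", index=False)
    my["promoter_methylation"].to_csv(out / "promoter_methylation.tsv", sep="\t")
    my["body_methylation"].to_csv(out / "gene_body_methylation.tsv", sep="\t")
    for (a, b), r in my["dms"].items():
        r.table.to_csv(out / f"dms_{a}_vs_{b}.tsv", sep="\t", index=False)
    my["dms_sites"].to_csv(out / "dms_sites.tsv", sep="\t", index=False)
    for name, t in it["correlations"].items():
        t.to_csv(out / f"correlation_{name}.tsv", sep="\t", index=False)
    perm_rows = [(name, r.observed, r.null_mean, r.null_sd, r.p)
                 for name, r in it["permutations"].items()]
    pd.DataFrame(perm_rows, columns=["intervals", "observed", "null_mean",
                                     "null_sd", "p"]).to_csv(
        out / "permutation_overlap.tsv", sep="\t", index=False)
    for name, t in it["comparisons"].items():
        t.to_csv(out / f"comparison_{name}.tsv", sep="\t", index=False)
    summary = {
        "n_regions": len(cnv["regions"]),
        "n_deletions": int((cnv["regions"]["cnv_class"] == "deletion").sum()),
        "n_duplications": int((cnv["regions"]["cnv_class"] == "duplication").sum()),
        "n_gene_cnvs": int(cnv["gene_cnvs"]["gene_id"].nunique()),
        "n_dms_sites": len(my["dms_sites"]),
        "singleton_proportion": pg["sharing"]["singleton_proportion"],
        "copy_number_concordance": results["concordance"],
        "vst_outlier_recall": results["vst_recall"],
    }
    pd.Series(summary).to_csv(out / "summary.tsv", sep="\t", header=False)
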