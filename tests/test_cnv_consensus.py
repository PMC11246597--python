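import numpy as np
import pandas as pd
import pytest

from cnvmeth import cnv_consensus as cc
from cnvmeth.config import PipelineConfig
from cnvmeth.errors import ConfigError, DataError

from conftest import constant_depth_matrix


def make_call(caller, start=1000, end=2000, cnv_class="deletion", pairs=10,
              splits=5, mapq=40.0, cov=20.0, chrom="chr1"):
    return {"caller": caller, "cnv_class": cnv_class, "chrom": chrom,
            "start": start, "end": end, "read_pairs": pairs,
            "split_reads": splits, "mapq": mapq, "max_coverage": cov}


class TestFilterCallerCalls:
    def test_paired_caller_min_read_pairs_boundary(self, config):
        calls = pd.DataFrame([make_call("breakdancer", pairs=3),
                              make_call("breakdancer", pairs=4)])
        out = cc.filter_caller_calls(calls, config)
        assert out["kept"].tolist() == [False, True]
        assert "read pairs" in out.loc[0, "reason"]

    def test_paired_caller_coverage_cap(self, config):
        calls = pd.DataFrame([make_call("breakdancer", cov=51.0),
                              make_call("breakdancer", cov=50.0)])
        assert cc.filter_caller_calls(calls, config)["kept"].tolist() == [False, True]

    def test_paired_split_length_cap(self, config):
        calls = pd.DataFrame([make_call("delly", start=0, end=600_000),
                              make_call("delly", start=0, end=500_000)])
        assert cc.filter_caller_calls(calls, config)["kept"].tolist() == [False, True]

    def test_mapping_quality_exactly_20_dropped(self, config):
        # "above 20" is strict: a call at exactly 20 fails
        calls = pd.DataFrame([make_call("duppy", mapq=20.0),
                              make_call("duppy", mapq=20.01)])
        assert cc.filter_caller_calls(calls, config)["kept"].tolist() == [False, True]

    def test_read_depth_and_split_callers_pass_unchanged(self, config):
        calls = pd.DataFrame([make_call("cnvnator", pairs=0, splits=0, mapq=0.0,
                                        cov=500.0),
                              make_call("pindel", pairs=0, splits=1, mapq=5.0)])
        assert cc.filter_caller_calls(calls, config)["kept"].all()

    def test_unknown_caller_rejected(self, config):
        calls = pd.DataFrame([make_call("mystery")])
        with pytest.raises(ConfigError, match="mystery"):
            cc.filter_caller_calls(calls, config)


class TestConsensusOverlap:
    def _primary(self, **kw):
        return pd.DataFrame([make_call("cnvnator", **kw)])

    @pytest.mark.parametrize("other_start,other_end,expected", [
        (1400, 2600, 1),   # overlap 600/1000 = 0.6 -> retained
        (1501, 2600, 0),   # overlap 499/1000 -> dropped
        (1500, 2600, 1),   # overlap exactly 500/1000 -> retained (inclusive)
    ])
    def test_overlap_fraction_boundary(self, other_start, other_end, expected):
        primary = self._primary(start=1000, end=2000)
        other = pd.DataFrame([make_call("delly", start=other_start, end=other_end)])
        out = cc.consensus_overlap(primary, other, 0.5)
        assert len(out) == expected

    def test_class_must_match(self):
        primary = self._primary(start=1000, end=2000, cnv_class="deletion")
        other = pd.DataFrame([make_call("delly", start=1000, end=2000,
                                        cnv_class="duplication")])
        assert len(cc.consensus_overlap(primary, other, 0.5)) == 0

    def test_breakpoints_are_primary_callers(self):
        primary = self._primary(start=1000, end=2000)
        other = pd.DataFrame([make_call("delly", start=900, end=2100)])
        out = cc.consensus_overlap(primary, other, 0.5)
        assert out.iloc[0]["start"] == 1000 and out.iloc[0]["end"] == 2000

    def test_empty_primary_gives_empty_output(self):
        primary = pd.DataFrame(columns=list(make_call("cnvnator")))
        other = pd.DataFrame([make_call("delly")])
        assert len(cc.consensus_overlap(primary, other, 0.5)) == 0


class TestNormalizeDepth:
    def test_scaling_arithmetic(self):
        raw = constant_depth_matrix([30.0])
        raw.values.iloc[0, 0] = 45.0  # one window at 45x
        out = cc.normalize_depth(raw)
        assert out.values.iloc[0, 0] == pytest.approx(3.0)

    def test_idempotent_on_centered_matrix(self):
        centered = cc.normalize_depth(constant_depth_matrix([10.0, 20.0, 40.0]))
        again = cc.normalize_depth(centered)
        np.testing.assert_allclose(again.values.to_numpy(),
                                   centered.values.to_numpy())

    def test_random_matrix_medians_exactly_two(self):
        rng = np.random.default_rng(0)
        raw = constant_depth_matrix(np.ones(10))
        raw.values.iloc[:, :] = rng.gamma(5.0, 3.0, size=raw.values.shape)
        out = cc.normalize_depth(raw)
        med = out.values.median(axis=0)
        np.testing.assert_allclose(med, 2.0, atol=1e-9)

    def test_all_zero_sample_rejected(self):
        raw = constant_depth_matrix([10.0, 0.0])
        with pytest.raises(DataError, match="zero"):
            cc.normalize_depth(raw)


class TestRegionDepthFilter:
    def _run(self, means, config):
        depth = constant_depth_matrix(means)
        regions = pd.DataFrame({"region_id": ["r0"], "chrom": ["chr1"],
                                "start": [0], "end": [10_000],
                                "cnv_class": ["duplication"]})
        return cc.region_depth_filter(regions, depth, config).iloc[0]

    def test_distinct_spread_retained(self, config):
        row = self._run([1.0, 2.0, 3.1], config)
        assert row["retained"] and row["reason"] == ""

    def test_uniform_diploid_fails_range_condition(self, config):
        row = self._run([2.0, 2.0, 2.01], config)
        assert not row["retained"] and row["reason"].startswith("cond2")

    def test_high_coverage_region_fails_first_condition(self, config):
        row = self._run([3.0, 3.5, 4.2], config)
        assert not row["retained"] and row["reason"].startswith("cond1")

    def test_region_without_windows_is_data_error(self, config):
        depth = constant_depth_matrix([1.0, 2.0, 3.1])
        regions = pd.DataFrame({"region_id": ["r0"], "chrom": ["chr9"],
                                "start": [0], "end": [500],
                                "cnv_class": ["deletion"]})
        with pytest.raises(DataError):
            cc.region_depth_filter(regions, depth, config)


class TestGenotypeRegions:
    def _genotype(self, means, config, seed=0):
        depth = constant_depth_matrix(means)
        regions = pd.DataFrame({"region_id": ["r0"], "chrom": ["chr1"],
                                "start": [0], "end": [10_000],
                                "cnv_class": ["duplication"]})
        return cc.genotype_regions(regions, depth, config, seed=seed)

    def test_clean_integer_means_recover_states(self, config):
        cn, status = self._genotype([0.04, 1.02, 1.98, 3.01], config)
        assert status.iloc[0]["genotyped"]
        assert cn.loc["r0"].tolist() == [0, 1, 2, 3]

    def test_cluster_rule_reassigns_borderline_samples(self, config):
        # two clear clusters near 2 and 3; 2.45 sits in the diploid cluster
        means = [1.95, 2.0, 2.05, 2.45, 2.45, 2.95, 3.0, 3.05]
        cn, status = self._genotype(means, config)
        assert status.iloc[0]["genotyped"]
        assert cn.loc["r0"].tolist() == [2, 2, 2, 2, 2, 3, 3, 3]

    def test_continuum_between_bins_excluded(self, config):
        means = [1.6, 1.65, 1.7, 1.75, 2.25, 2.3, 2.35, 2.4]
        cn, status = self._genotype(means, config)
        assert not status.iloc[0]["genotyped"]
        assert status.iloc[0]["reason"] == "cluster-genotype mismatch"
        assert "r0" not in cn.index

    def test_boundary_tie_goes_to_higher_bin(self):
        assert cc.depth_to_bin(np.array([1.5, 2.5, 0.4999])).tolist() == [2, 3, 0]

    def test_fewer_than_two_samples_rejected(self, config):
        with pytest.raises(DataError):
            self._genotype([2.0], config)


class TestFlagSexSpecific:
    def _meta(self):
        return pd.DataFrame({
            "sample": [f"s{i}" for i in range(8)],
            "population": "p1",
            "sex": ["M", "M", "M", "M", "M", "F", "F", "F"]})

    def test_all_male_carriers_flagged(self):
        cn = pd.DataFrame([[1, 1, 1, 1, 1, 2, 2, 2]],
                          index=["r0"], columns=[f"s{i}" for i in range(8)])
        out = cc.flag_sex_specific(cn, self._meta())
        assert out.iloc[0]["sex_specific"] and out.iloc[0]["carrier_sex"] == "M"

    def test_mixed_sex_carriers_not_flagged(self):
        cn = pd.DataFrame([[1, 1, 1, 2, 2, 1, 2, 2]],
                          index=["r0"], columns=[f"s{i}" for i in range(8)])
        assert not cc.flag_sex_specific(cn, self._meta()).iloc[0]["sex_specific"]

    def test_single_carrier_below_support_threshold(self):
        cn = pd.DataFrame([[1, 2, 2, 2, 2, 2, 2, 2]],
                          index=["r0"], columns=[f"s{i}" for i in range(8)])
        assert not cc.flag_sex_specific(cn, self._meta()).iloc[0]["sex_specific"]


class TestGeneOverlap:
    def _genes(self):
        return pd.DataFrame({"name": ["g1"], "chrom": ["chr1"],
                             "txStart": [0], "txEnd": [1000]})

    @pytest.mark.parametrize("start,end,expected", [
        (0, 900, "full"),      # 0.90 of the gene
        (0, 899, "partial"),   # 0.899
    ])
    def test_ninety_percent_boundary(self, start, end, expected):
        regions = pd.DataFrame({"region_id": ["r0"], "chrom": ["chr1"],
                                "start": [start], "end": [end],
                                "cnv_class": ["deletion"]})
        out = cc.gene_overlap(regions, self._genes())
        assert out.iloc[0]["classification"] == expected

    def test_disjoint_gene_no_record(self):
        regions = pd.DataFrame({"region_id": ["r0"], "chrom": ["chr1"],
                                "start": [5000], "end": [6000],
                                "cnv_class": ["deletion"]})
        assert len(cc.gene_overlap(regions, self._genes())) == 0


class TestGeneDepthRefilter:
    def _fixture(self, gene_means):
        genes = pd.DataFrame({"name": ["g1"], "chrom": ["chr1"],
                              "txStart": [0], "txEnd": [10_000]})
        gene_cnvs = pd.DataFrame({"gene_id": ["g1"], "region_id": ["r0"],
                                  "cnv_class": ["deletion"],
                                  "overlap_fraction": [1.0],
                                  "classification": ["full"]})
        return gene_cnvs, genes, constant_depth_matrix(gene_means)

    def test_distinct_gene_depths_retained(self, config):
        gene_cnvs, genes, depth = self._fixture([1.0, 2.0, 3.1])
        out = cc.gene_depth_refilter(gene_cnvs, genes, depth, config)
        assert out.iloc[0]["retained"]

    def test_flat_gene_depths_dropped(self, config):
        gene_cnvs, genes, depth = self._fixture([1.95, 2.0, 2.05])
        out = cc.gene_depth_refilter(gene_cnvs, genes, depth, config)
        assert not out.iloc[0]["retained"]

    def test_retained_is_subset_of_input(self, config):
        """Brute-force subset property over random fixtures."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            gene_cnvs, genes, depth = self._fixture(rng.uniform(0.0, 4.0, n))
            out = cc.gene_depth_refilter(gene_cnvs, genes, depth, config)
            kept = set(out.loc[out["retained"], "gene_id"])
            assert kept <= set(gene_cnvs["gene_id"])


class TestPipelineMonotonicity:
    def test_tightening_thresholds_never_adds_regions(self, config):
        """Raising the pairwise-difference cutoff or the consensus overlap
        fraction can only shrink the retained set."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_samples = 12
            means = rng.uniform(0.0, 4.0, size=(5, n_samples))
            depth = constant_depth_matrix(np.ones(n_samples), end=50_000)
            # five regions, each owning a 10 kb stretch with its own means
            regions = pd.DataFrame({
                "region_id": [f"r{i}" for i in range(5)],
                "chrom": "chr1",
                "start": np.arange(5) * 10_000,
                "end": (np.arange(5) + 1) * 10_000,
                "cnv_class": "deletion"})
            for i in range(5):
                block = (depth.windows["start"] >= i * 10_000) & \
                        (depth.windows["start"] < (i + 1) * 10_000)
                depth.values.loc[block.to_numpy()] = means[i]
            loose = cc.region_depth_filter(regions, depth, config)
            tight_cfg = PipelineConfig(depth_cond3_min_diff=0.9,
                                       depth_cond2_min_range=1.5)
            tight = cc.region_depth_filter(regions, depth, tight_cfg)
            assert tight["retained"].sum() <= loose["retained"].sum()
            t_set = set(tight.loc[tight["retained"], "region_id"])
            l_set = set(loose.loc[loose["retained"], "region_id"])
            assert t_set <= l_set
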