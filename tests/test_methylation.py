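import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from cnvmeth import methylation as meth
from cnvmeth.config import PipelineConfig
from cnvmeth.errors import ConfigError, DataError


def make_matrix(cov, meth_counts, samples=None, chrom="chr1", start=0, step=100):
    cov = np.asarray(cov, dtype=float)
    meths = np.asarray(meth_counts, dtype=float)
    n_sites, n_samples = cov.shape
    samples = samples or [f"s{i}" for i in range(n_samples)]
    sites = pd.DataFrame({"chrom": chrom,
                          "pos": start + np.arange(n_sites) * step,
                          "strand": "+"})
    return meth.MethylationCountMatrix(
        sites=sites,
        cov=pd.DataFrame(cov, columns=samples),
        meth=pd.DataFrame(meths, columns=samples))


def two_pop_meta(n_per=4, pops=("A", "B")):
    rows = [(f"{p}_s{j}", p, "unknown") for p in pops for j in range(n_per)]
    return pd.DataFrame(rows, columns=["sample", "population", "sex"])


class TestContainer:
    def test_counts_violating_bound_rejected(self):
        with pytest.raises(DataError):
            make_matrix([[10.0]], [[11.0]])

    def test_sites_sorted_by_position(self):
        m = meth.MethylationCountMatrix(
            sites=pd.DataFrame({"chrom": ["chr2", "chr1"], "pos": [5, 9],
                                "strand": ["+", "+"]}),
            cov=pd.DataFrame({"s0": [10.0, 20.0]}),
            meth=pd.DataFrame({"s0": [1.0, 2.0]}))
        assert m.sites["chrom"].tolist() == ["chr1", "chr2"]
        assert m.cov["s0"].tolist() == [20.0, 10.0]


class TestFilterCoverage:
    def test_low_coverage_boundary(self):
        m = make_matrix([[9.0], [10.0]], [[1.0], [2.0]])
        out = meth.filter_coverage(m, min_cov=10, upper_percentile=100.0)
        assert np.isnan(out.cov.iloc[0, 0])
        assert out.cov.iloc[1, 0] == 10.0

    def test_upper_percentile_blanks_pcr_outliers(self):
        cov = np.full((1000, 1), 30.0)
        cov[-1, 0] = 5000.0
        m = make_matrix(cov, np.zeros_like(cov))
        out = meth.filter_coverage(m, min_cov=10, upper_percentile=99.9)
        assert np.isnan(out.cov.iloc[-1, 0])
        assert out.covered().to_numpy().sum() == 999

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(4)
        cov = rng.integers(0, 60, size=(200, 6)).astype(float)
        miss = rng.random((200, 6)) < 0.2
        cov[miss] = np.nan
        meths = np.floor(cov * rng.random((200, 6)))
        m = make_matrix(np.nan_to_num(cov, nan=0) + np.where(np.isnan(cov), np.nan, 0),
                        meths)
        out = meth.filter_coverage(m, min_cov=10, upper_percentile=99.9)
        # oracle: python loop over cells
        expected = 0
        for j in range(6):
            col = cov[:, j]
            obs = col[~np.isnan(col)]
            hi = np.percentile(obs, 99.9)
            for i in range(200):
                c = cov[i, j]
                if not np.isnan(c) and 10 <= c <= hi:
                    expected += 1
        assert int(out.covered().to_numpy().sum()) == expected


class TestNormalizeCoverage:
    def test_equal_medians_unchanged(self):
        cov = np.full((50, 3), 30.0)
        m = make_matrix(cov, cov * 0.4)
        out = meth.normalize_coverage(m)
        np.testing.assert_array_equal(out.cov.to_numpy(), m.cov.to_numpy())
        np.testing.assert_array_equal(out.meth.to_numpy(), m.meth.to_numpy())

    def test_double_coverage_sample_halved(self):
        cov = np.column_stack([np.full(50, 30.0), np.full(50, 30.0),
                               np.full(50, 60.0)])
        m = make_matrix(cov, cov * 0.5)
        out = meth.normalize_coverage(m)
        assert out.cov.iloc[0, 2] == 30.0
        assert out.meth.iloc[0, 2] == 15.0

    def test_proportion_shift_bounded_by_rounding(self):
        rng = np.random.default_rng(6)
        cov = rng.integers(10, 80, size=(300, 5)).astype(float)
        meths = rng.binomial(cov.astype(int), 0.3).astype(float)
        m = make_matrix(cov, meths)
        out = meth.normalize_coverage(m)
        before = m.proportions().to_numpy()
        after = out.proportions().to_numpy()
        bound = 1.0 / out.cov.to_numpy()
        assert (np.abs(after - before) < bound + 1e-12).all()
        assert (out.meth.to_numpy() <= out.cov.to_numpy()).all()

    def test_sample_without_coverage_rejected(self):
        cov = np.array([[30.0, np.nan], [40.0, np.nan]])
        m = make_matrix(cov, np.zeros_like(cov) * cov)
        with pytest.raises(DataError, match="no covered sites"):
            meth.normalize_coverage(m)


class TestUniteSites:
    def test_min_per_group_boundary(self):
        meta = two_pop_meta(n_per=4)
        cov = np.full((2, 8), 20.0)
        cov[1, 0] = np.nan  # site 1: only 3 covered in population A
        m = make_matrix(cov, np.where(np.isnan(cov), np.nan, 0.0),
                        samples=meta["sample"].tolist())
        out = meth.unite_sites(m, meta, min_per_group=4, max_missing=0.5)
        assert out.n_sites == 1
        out2 = meth.unite_sites(m, meta, min_per_group=3, max_missing=0.5)
        assert out2.n_sites == 2

    def test_overall_missingness_cap(self):
        meta = two_pop_meta(n_per=10)
        cov = np.full((1, 20), 20.0)
        cov[0, :6] = np.nan  # 30% of cells missing, both groups still covered
        m = make_matrix(cov, np.where(np.isnan(cov), np.nan, 0.0),
                        samples=meta["sample"].tolist())
        out = meth.unite_sites(m, meta, min_per_group=3, max_missing=0.25)
        assert out.n_sites == 0

    def test_config_error_when_threshold_exceeds_population(self):
        meta = two_pop_meta(n_per=4)
        m = make_matrix(np.full((1, 8), 20.0), np.zeros((1, 8)),
                        samples=meta["sample"].tolist())
        with pytest.raises(ConfigError):
            meth.unite_sites(m, meta, min_per_group=5, max_missing=0.3)

    def test_matches_brute_force_double_filter(self):
        meta = two_pop_meta(n_per=6)
        rng = np.random.default_rng(13)
        cov = rng.integers(10, 40, size=(100, 12)).astype(float)
        cov[rng.random((100, 12)) < 0.35] = np.nan
        m = make_matrix(cov, np.where(np.isnan(cov), np.nan, 0.0),
                        samples=meta["sample"].tolist())
        out = meth.unite_sites(m, meta, min_per_group=4, max_missing=0.30)
        keep = []
        pop = meta.set_index("sample")["population"]
        for i in range(100):
            ok = True
            for p in ("A", "B"):
                cols = [k for k, s in enumerate(m.samples) if pop[s] == p]
                if np.sum(~np.isnan(cov[i, cols])) < 4:
                    ok = False
            if np.mean(np.isnan(cov[i])) > 0.30:
                ok = False
            keep.append(ok)
        assert out.n_sites == sum(keep)


class TestExcludeSites:
    def _matrix(self):
        sites = pd.DataFrame({"chrom": ["chr1", "chr1", "chrXIX"],
                              "pos": [100, 200, 300], "strand": "+"})
        return meth.MethylationCountMatrix(
            sites=sites,
            cov=pd.DataFrame({"s0": [20.0, 20.0, 20.0]}),
            meth=pd.DataFrame({"s0": [5.0, 5.0, 5.0]}))

    def test_snp_position_removed(self):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [100],
                             "substitution": ["C>T"]})
        out = meth.exclude_sites(self._matrix(), snps, ())
        assert out.sites["pos"].tolist() == [200, 300]

    def test_sex_chromosome_removed(self):
        out = meth.exclude_sites(self._matrix(), None, ("chrXIX",))
        assert out.sites["chrom"].tolist() == ["chr1", "chr1"]

    def test_no_exclusions_is_identity(self):
        m = self._matrix()
        out = meth.exclude_sites(m, pd.DataFrame(columns=["chrom", "pos"]), ())
        assert out.n_sites == m.n_sites


class TestAnnotation:
    def _genes(self):
        return pd.DataFrame({
            "name": ["gp", "gm"], "chrom": ["chr1", "chr1"],
            "strand": ["+", "-"],
            "txStart": [10_000, 50_000], "txEnd": [20_000, 60_000],
            "tss": [10_000, 60_000]})

    @pytest.mark.parametrize("pos,expected_class,expected_gene", [
        (9_000, "promoter", "gp"),     # 1000 bp upstream of + TSS
        (10_400, "promoter", "gp"),    # 400 bp downstream of + TSS
        (61_000, "promoter", "gm"),    # 1000 bp upstream of - TSS (to the right)
        (15_000, "gene_body", "gp"),   # inside gene, outside promoter
        (30_000, "intergenic", ""),
    ])
    def test_classification(self, pos, expected_class, expected_gene):
        m = make_matrix([[20.0]], [[5.0]])
        m.sites.loc[0, "pos"] = pos
        ann = meth.annotate_cpgs(m, self._genes())
        assert ann.iloc[0]["region_class"] == expected_class
        assert ann.iloc[0]["gene_id"] == expected_gene


class TestGeneMethylation:
    def test_mean_of_site_proportions(self):
        m = make_matrix([[10.0], [10.0]], [[2.0], [4.0]])
        ann = pd.DataFrame({"region_class": ["promoter", "promoter"],
                            "gene_id": ["g1", "g1"]})
        out = meth.gene_methylation(m, ann, "promoter")
        assert out.loc["g1", "s0"] == pytest.approx(0.3)

    def test_uncovered_gene_missing(self):
        m = make_matrix([[np.nan], [np.nan]], [[np.nan], [np.nan]])
        ann = pd.DataFrame({"region_class": ["promoter", "promoter"],
                            "gene_id": ["g1", "g1"]})
        out = meth.gene_methylation(m, ann, "promoter")
        assert np.isnan(out.loc["g1", "s0"])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(17)
        cov = rng.integers(10, 40, size=(60, 5)).astype(float)
        meths = rng.binomial(cov.astype(int), 0.4).astype(float)
        m = make_matrix(cov, meths)
        genes = rng.choice(["g1", "g2", "g3"], size=60)
        ann = pd.DataFrame({"region_class": "promoter", "gene_id": genes})
        out = meth.gene_methylation(m, ann, "promoter")
        for g in ("g1", "g2", "g3"):
            rows = np.where(genes == g)[0]
            for j, s in enumerate(m.samples):
                want = np.mean([meths[i, j] / cov[i, j] for i in rows])
                assert out.loc[g, s] == pytest.approx(want, abs=1e-12)


def oracle_lrt_p(ma, ca, mb, cb):
    """Independent binomial log-likelihood computation for one site."""
    def ll(m_, c_, p):
        if p <= 0 or p >= 1:
            out = 0.0
            if m_ > 0:
                out += m_ * np.log(p) if p > 0 else -np.inf
            if c_ - m_ > 0:
                out += (c_ - m_) * np.log(1 - p) if p < 1 else -np.inf
            return out
        return m_ * np.log(p) + (c_ - m_) * np.log(1 - p)

    pa, pb = ma / ca, mb / cb
    p0 = (ma + mb) / (ca + cb)
    lrt = 2 * (ll(ma, ca, pa) + ll(mb, cb, pb) - ll(ma + mb, ca + cb, p0))
    return chi2.sf(max(lrt, 0.0), df=1)


class TestCallDms:
    def test_identical_groups_not_dms(self):
        meta = two_pop_meta(n_per=4)
        cov = np.full((5, 8), 30.0)
        meths = np.tile(np.array([3.0, 9.0, 15.0, 21.0, 27.0])[:, None], (1, 8))
        m = make_matrix(cov, meths, samples=meta["sample"].tolist())
        res = meth.call_dms(m, meta, ("A", "B"))
        assert np.allclose(res.table["diff"], 0.0)
        assert np.allclose(res.table["p"], 1.0)
        assert not res.table["dms"].any()

    def test_large_difference_flagged_and_matches_oracle(self):
        meta = two_pop_meta(n_per=12)
        cov = np.full((20, 24), 30.0)
        meths = np.column_stack([np.full((20, 12), 3.0),   # 10% methylated
                                 np.full((20, 12), 12.0)])  # 40% methylated
        m = make_matrix(cov, meths, samples=meta["sample"].tolist())
        res = meth.call_dms(m, meta, ("A", "B"))
        assert res.table["dms"].all()
        assert np.allclose(res.table["diff"], -30.0)
        want_p = oracle_lrt_p(12 * 3.0, 12 * 30.0, 12 * 12.0, 12 * 30.0)
        assert res.table["p"].iloc[0] == pytest.approx(want_p, rel=1e-9)

    def test_small_difference_never_dms_despite_tiny_p(self):
        meta = two_pop_meta(n_per=12)
        cov = np.full((5, 24), 100_000.0)  # enormous coverage: p ~ 0
        meths = np.column_stack([np.full((5, 12), 30_000.0),
                                 np.full((5, 12), 40_000.0)])  # 30% vs 40%
        m = make_matrix(cov, meths, samples=meta["sample"].tolist())
        res = meth.call_dms(m, meta, ("A", "B"))
        assert (res.table["p"] < 1e-10).all()
        assert not res.table["dms"].any()

    def test_uncovered_group_site_skipped(self):
        meta = two_pop_meta(n_per=2)
        cov = np.array([[30.0, 30.0, np.nan, np.nan],
                        [30.0, 30.0, 30.0, 30.0]])
        meths = np.where(np.isnan(cov), np.nan, 3.0)
        m = make_matrix(cov, meths, samples=meta["sample"].tolist())
        res = meth.call_dms(m, meta, ("A", "B"))
        assert res.table["tested"].tolist() == [False, True]

    def test_threshold_monotonicity(self):
        """Raising the difference threshold or lowering the q cap can only
        shrink the DMS set."""
        rng = np.random.default_rng(23)
        meta = two_pop_meta(n_per=8)
        cov = rng.poisson(30, size=(400, 16)).astype(float)
        cov = np.maximum(cov, 1.0)
        p_a = rng.uniform(0.05, 0.95, size=400)
        p_b = np.clip(p_a + rng.normal(0, 0.15, size=400), 0.01, 0.99)
        p_mat = np.column_stack([np.tile(p_a[:, None], (1, 8)),
                                 np.tile(p_b[:, None], (1, 8))])
        meths = rng.binomial(cov.astype(int), p_mat).astype(float)
        m = make_matrix(cov, meths, samples=meta["sample"].tolist())
        base = meth.call_dms(m, meta, ("A", "B"), min_diff=15, q_max=0.0125)
        stricter_diff = meth.call_dms(m, meta, ("A", "B"), min_diff=25, q_max=0.0125)
        stricter_q = meth.call_dms(m, meta, ("A", "B"), min_diff=15, q_max=0.001)
        n_base = base.table["dms"].sum()
        assert stricter_diff.table["dms"].sum() <= n_base
        assert stricter_q.table["dms"].sum() <= n_base
        assert set(base.table.index[stricter_diff.table["dms"]]) <= \
            set(base.table.index[base.table["dms"]])


class TestPopulationSpecificDms:
    def test_requires_all_pairs_involving_population(self):
        meta = two_pop_meta(n_per=12, pops=("A", "B", "C"))
        cov = np.full((10, 36), 50.0)
        meths = np.full((10, 36), 10.0)
        # site 0: population A strongly hypermethylated vs both B and C
        meths[0, :12] = 45.0
        m = make_matrix(cov, meths, samples=meta["sample"].tolist())
        results = meth.call_all_pairwise_dms(m, meta, PipelineConfig())
        spec_a = meth.population_specific_dms(results, "A")
        assert spec_a["pos"].tolist() == [0]
        assert meth.population_specific_dms(results, "B").empty
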