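import numpy as np
import pandas as pd
import pytest

from cnvmeth.cnv_consensus import DepthMatrix
from cnvmeth.config import PipelineConfig
from cnvmeth.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture
def config():
    return PipelineConfig()


def small_sim_config(seed=0, **overrides):
    """A reduced cohort that keeps every structural feature of the default
    design (6 populations, sex chromosome, genic CNVs) but runs in well
    under a second."""
    base = dict(
        seed=seed,
        chromosome_lengths={"chrA": 600_000, "chrB": 500_000, "chrXIX": 300_000},
        n_genes=40,
        n_cnv_loci=25,
        n_intergenic_clusters=40,
        n_differentiated=4,
        n_sex_specific_del=1,
        n_sex_specific_dup=1,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_sim_config(seed=7))


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on the default study design, shared by the
    end-to-end tests."""
    from cnvmeth.pipeline import run_all
    return run_all(seed=0)


def constant_depth_matrix(sample_means, chrom="chr1", start=0, end=10_000,
                          window=500):
    """DepthMatrix in which every window of one region carries the sample's
    target mean exactly; convenient for exercising depth-threshold logic."""
    starts = np.arange(start, end, window)
    windows = pd.DataFrame({"chrom": chrom, "start": starts,
                            "end": np.minimum(starts + window, end)})
    names = [f"s{i}" for i in range(len(sample_means))]
    values = pd.DataFrame(
        np.tile(np.asarray(sample_means, dtype=float), (len(windows), 1)),
        columns=names)
    return DepthMatrix(windows=windows, values=values)
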