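"""Pipeline thresholds.

Every numeric cutoff used downstream lives in :class:`PipelineConfig` so a
run is fully described by one object; the defaults are the values the
analysis is designed around. Configs round-trip through YAML and are echoed
into every results directory for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

#: caller name -> evidence type used by the caller-level filters
DEFAULT_CALLER_TYPES = {
    "cnvnator": "read_depth",
    "breakdancer": "paired",
    "pindel": "split",
    "delly": "paired_split",
    "duppy": "paired_split",
}


@dataclass
class PipelineConfig:
    """Thresholds for CNV consensus, methylation processing and integration.

    Units: genomic coordinates in bp (0-based half-open), depth in
    normalized copies (diploid = 2), methylation differences in percentage
    points, frequencies as fractions in [0, 1].
    """

    # --- caller-level filters ---
    caller_types: dict = field(default_factory=lambda: dict(DEFAULT_CALLER_TYPES))
    paired_max_coverage: float = 50.0        # per-sample coverage cap (x)
    paired_min_read_pairs: int = 4
    paired_split_min_mapq: float = 20.0      # strict: kept iff mapq > 20
    paired_split_min_support: int = 2
    paired_split_max_length: int = 500_000   # bp

    # --- consensus ---
    consensus_min_overlap: float = 0.5       # fraction of the primary call's length

    # --- region depth filter (normalized depth, diploid = 2) ---
    depth_cond1_above: float = 1.5           # some individual must exceed this
    depth_cond1_below: float = 2.5           # some individual must be under this
    depth_cond2_min_range: float = 1.0       # max - min must reach this
    depth_cond3_min_diff: float = 0.45       # strict: some pair differs by more

    # --- genotyping ---
    genotype_k_max: int = 10                 # k-means searched over k = 2..k_max
    genotype_n_init: int = 10
    cluster_match_tolerance: float = 0.35    # center-to-integer distance for reassignment
    region_depth_summary: str = "mean"       # or "median"

    # --- sex-specific flagging ---
    sex_specific_min_carriers: int = 2

    # --- gene overlap ---
    gene_full_overlap: float = 0.9           # fraction of gene length for "full"

    # --- methylation coverage/unite ---
    coverage_min: int = 10                   # reads per CpG per sample
    coverage_upper_percentile: float = 99.9
    unite_min_per_group: int = 11
    unite_max_missing: float = 0.30

    # --- promoter definition (strand-aware, bp around the TSS) ---
    promoter_upstream: int = 1500
    promoter_downstream: int = 500

    # --- differential methylation ---
    dms_min_diff: float = 15.0               # percentage points, pooled difference
    dms_max_q: float = 0.0125

    # --- V_st scan ---
    vst_top_fraction: float = 0.02
    vst_floor: float = 0.1
    vst_unbiased: bool = True
    vst_weighted: bool = False               # population-size-weighted V_pop

    # --- integration ---
    n_permutations: int = 1000
    permutation_chromosome_matched: bool = False
    correlation_min_samples: int = 3
    low_frequency_threshold: float = 0.05    # carrier frequency among all individuals

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("consensus_min_overlap", "gene_full_overlap", "unite_max_missing",
                     "vst_top_fraction", "vst_floor", "low_frequency_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("paired_min_read_pairs", "paired_split_min_support", "coverage_min",
                     "unite_min_per_group", "n_permutations", "correlation_min_samples",
                     "promoter_upstream", "promoter_downstream", "genotype_k_max",
                     "sex_specific_min_carriers"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigError(f"{name} must be non-negative, got {v!r}")
        if not (0.0 < self.coverage_upper_percentile <= 100.0):
            raise ConfigError("coverage_upper_percentile must be in (0, 100]")
        if self.genotype_k_max < 2:
            raise ConfigError("genotype_k_max must be at least 2")
        if self.region_depth_summary not in ("mean", "median"):
            raise ConfigError("region_depth_summary must be 'mean' or 'median'")
        known = {"read_depth", "paired", "split", "paired_split"}
        for caller, ctype in self.caller_types.items():
            if ctype not in known:
                raise ConfigError(f"unknown caller type {ctype!r} for caller {caller!r}")

    # ----- I/O -----
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(d)

    def echo(self, outdir: str | Path, name: str = "pipeline_config.yaml") -> Path:
        """Write the effective config into a results directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / name
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path
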