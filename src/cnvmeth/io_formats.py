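"""Readers and writers for the plain-text formats the pipeline touches.

Conventions
-----------
* All genomic intervals are 0-based half-open internally; BED and genePred
  files follow their native (identical) convention at I/O.
* Readers reject malformed input with :class:`~cnvmeth.errors.ParseError`
  (carrying the line number) rather than silently coercing.
* Writers sort their output so a fixed input always produces an identical
  file.

Formats
-------
BED
    ``chrom  start  end  [name  ...extra]`` — extra columns preserved.
genePred
    ``name  chrom  strand  txStart  txEnd  cdsStart  cdsEnd  exonCount
    exonStarts  exonEnds`` (comma-separated exon lists).
CpG count table (wide TSV)
    ``chrom  pos  strand  cov_<sample>  meth_<sample> ...`` — empty cells
    mean "not covered", which is distinct from coverage 0.
Sample metadata TSV
    ``sample  population  sex  salinity``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, ParseError

VALID_STRANDS = {"+", "-"}
VALID_SEXES = {"M", "F", "unknown"}


# --------------------------------------------------------------------------
# BED
# --------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED(-like) file into a DataFrame with chrom/start/end [+extras].

    Zero-length or inverted intervals are rejected: BED is half-open, so
    ``start == end`` usually indicates accidentally 1-based input.
    """
    rows = []
    n_extra = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("BED line has fewer than 3 columns", str(path), lineno)
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError("non-integer BED coordinates", str(path), lineno)
            if start < 0:
                raise ParseError("negative BED start", str(path), lineno)
            if start >= end:
                raise ParseError(
                    "zero-length or inverted interval (start >= end); "
                    "BED is 0-based half-open", str(path), lineno)
            extras = parts[3:]
            if n_extra is None:
                n_extra = len(extras)
            elif len(extras) != n_extra:
                raise ParseError("inconsistent column count", str(path), lineno)
            rows.append((chrom, start, end, *extras))
    cols = ["chrom", "start", "end"] + [f"col{i+4}" for i in range(n_extra or 0)]
    if rows and n_extra and n_extra >= 1:
        cols[3] = "name"
    df = pd.DataFrame(rows, columns=cols)
    if not df.empty:
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    return df


def write_bed(records: pd.DataFrame, path: str | Path) -> None:
    df = records.copy()
    required = ["chrom", "start", "end"]
    for c in required:
        if c not in df.columns:
            raise DataError(f"write_bed: missing required column {c!r}")
    if (df["start"].astype(int) >= df["end"].astype(int)).any():
        raise DataError("write_bed: start >= end in at least one record")
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    ordered = required + [c for c in df.columns if c not in required]
    df[ordered].to_csv(path, sep="\t", header=False, index=False)


# --------------------------------------------------------------------------
# genePred
# --------------------------------------------------------------------------

GENEPRED_COLUMNS = ["name", "chrom", "strand", "txStart", "txEnd",
                    "cdsStart", "cdsEnd", "exonCount", "exonStarts", "exonEnds"]


def _parse_exon_list(text: str, path: str, lineno: int) -> list[int]:
    try:
        return [int(x) for x in text.rstrip(",").split(",") if x != ""]
    except ValueError:
        raise ParseError("malformed exon list", path, lineno)


def read_genepred(path: str | Path) -> pd.DataFrame:
    """Read a genePred table; adds a strand-aware ``tss`` column.

    TSS is txStart on the + strand and txEnd on the − strand (the position
    just past the interval end, consistent with half-open coordinates).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ParseError("genePred line has fewer than 10 columns", str(path), lineno)
            name, chrom, strand = parts[0], parts[1], parts[2]
            if strand not in VALID_STRANDS:
                raise ParseError(f"unknown strand symbol {strand!r}", str(path), lineno)
            try:
                tx_start, tx_end = int(parts[3]), int(parts[4])
                cds_start, cds_end = int(parts[5]), int(parts[6])
                exon_count = int(parts[7])
            except ValueError:
                raise ParseError("non-integer genePred coordinates", str(path), lineno)
            if tx_start >= tx_end:
                raise ParseError("txStart >= txEnd", str(path), lineno)
            exon_starts = _parse_exon_list(parts[8], str(path), lineno)
            exon_ends = _parse_exon_list(parts[9], str(path), lineno)
            if len(exon_starts) != exon_count or len(exon_ends) != exon_count:
                raise ParseError("exon list length does not match exonCount", str(path), lineno)
            for es, ee in zip(exon_starts, exon_ends):
                if not (tx_start <= es < ee <= tx_end):
                    raise ParseError("exon outside transcript bounds", str(path), lineno)
            tss = tx_start if strand == "+" else tx_end
            rows.append((name, chrom, strand, tx_start, tx_end, cds_start, cds_end,
                         exon_count, tuple(exon_starts), tuple(exon_ends), tss))
    df = pd.DataFrame(rows, columns=GENEPRED_COLUMNS + ["tss"])
    if not df.empty:
        df = df.sort_values(["chrom", "txStart", "txEnd"], kind="mergesort").reset_index(drop=True)
    return df


def write_genepred(genes: pd.DataFrame, path: str | Path) -> None:
    df = genes.copy().sort_values(["chrom", "txStart", "txEnd"], kind="mergesort")
    with open(path, "w") as fh:
        for _, g in df.iterrows():
            starts = ",".join(str(int(x)) for x in g["exonStarts"]) + ","
            ends = ",".join(str(int(x)) for x in g["exonEnds"]) + ","
            fh.write("\t".join(str(x) for x in (
                g["name"], g["chrom"], g["strand"], int(g["txStart"]), int(g["txEnd"]),
                int(g["cdsStart"]), int(g["cdsEnd"]), int(g["exonCount"]), starts, ends)) + "\n")


# --------------------------------------------------------------------------
# Sample metadata
# --------------------------------------------------------------------------

def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "population": str, "sex": str})
    required = {"sample", "population", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"sample metadata missing column(s) {sorted(missing)}", str(path))
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise DataError(f"duplicate sample id {dup!r} in metadata")
    bad = set(df["sex"]) - VALID_SEXES
    if bad:
        raise DataError(f"invalid sex value(s) {sorted(bad)}; expected one of {sorted(VALID_SEXES)}")
    return df.reset_index(drop=True)


def write_sample_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.sort_values("sample", kind="mergesort").to_csv(path, sep="\t", index=False)


def check_samples_known(sample_ids: Iterable[str], metadata: pd.DataFrame) -> None:
    known = set(metadata["sample"])
    unknown = [s for s in sample_ids if s not in known]
    if unknown:
        raise DataError(f"sample(s) absent from metadata: {unknown[:5]}")


# --------------------------------------------------------------------------
# CpG count tables
# --------------------------------------------------------------------------

def read_cpg_counts(path: str | Path, metadata: pd.DataFrame | None = None):
    """Read a wide CpG count TSV into a MethylationCountMatrix.

    Empty cells are missing observations (a site the sample did not cover),
    which is distinct from an observed coverage of 0.
    """
    from .methylation import MethylationCountMatrix

    df = pd.read_csv(path, sep="\t")
    for c in ("chrom", "pos", "strand"):
        if c not in df.columns:
            raise ParseError(f"CpG count table missing column {c!r}", str(path))
    cov_cols = [c for c in df.columns if c.startswith("cov_")]
    samples = [c[len("cov_"):] for c in cov_cols]
    for s in samples:
        if f"meth_{s}" not in df.columns:
            raise ParseError(f"coverage column for sample {s!r} has no meth_ partner", str(path))
    if not samples:
        raise ParseError("no cov_<sample> columns found", str(path))
    if metadata is not None:
        check_samples_known(samples, metadata)
    if df.duplicated(subset=["chrom", "pos"]).any():
        r = df[df.duplicated(subset=["chrom", "pos"])].iloc[0]
        raise DataError(f"duplicate CpG site ({r['chrom']}, {int(r['pos'])})")
    bad_strand = set(df["strand"]) - VALID_STRANDS
    if bad_strand:
        raise ParseError(f"invalid strand value(s) {sorted(bad_strand)}", str(path))
    sites = df[["chrom", "pos", "strand"]].copy()
    cov = df[[f"cov_{s}" for s in samples]].astype(float)
    cov.columns = samples
    meth = df[[f"meth_{s}" for s in samples]].astype(float)
    meth.columns = samples
    neg = (cov.fillna(0) < 0).any().any() or (meth.fillna(0) < 0).any().any()
    if neg:
        raise DataError("negative counts in CpG table")
    excess = (meth > cov)
    if excess.any().any():
        i, s = np.argwhere(excess.to_numpy())[0]
        raise DataError(
            f"methylated > coverage at site ({sites.iloc[i]['chrom']}, "
            f"{int(sites.iloc[i]['pos'])}) for sample {samples[s]!r}")
    return MethylationCountMatrix(sites=sites, cov=cov, meth=meth)


def write_cpg_counts(matrix, path: str | Path) -> None:
    sites = matrix.sites.reset_index(drop=True)
    blocks = [sites[["chrom", "pos", "strand"]]]
    for s in matrix.samples:
        blocks.append(pd.DataFrame({f"cov_{s}": matrix.cov[s].to_numpy(),
                                    f"meth_{s}": matrix.meth[s].to_numpy()}))
    out = pd.concat(blocks, axis=1)
    order = np.lexsort((out["pos"].to_numpy(), out["chrom"].to_numpy()))
    out = out.iloc[order]
    out.to_csv(path, sep="\t", index=False, float_format="%g")
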