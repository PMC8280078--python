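"""Readers and writers for the external formats the pipeline touches.

A single coordinate convention is used internally: positions are 0-based and
intervals are half-open ``[start, end)``, exactly as in BED.  Conversion to
and from 1-based formats (the Bismark coverage dialect) happens only at the
format boundary, in this module.

Multi-sample CpG tables are plain :class:`pandas.DataFrame` objects with
columns ``chrom``, ``pos`` and, for every sample ``s``, ``{s}.meth`` and
``{s}.cov`` (methylated read count and total read count).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "meth_col",
    "cov_col",
    "read_coverage_file",
    "write_coverage_file",
    "merge_samples",
    "read_bed",
    "read_gene_set",
    "write_results_tsv",
    "read_results_tsv",
]


class GenomicInterval(NamedTuple):
    """A 0-based half-open genomic interval, optionally named and stranded."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None


def meth_col(sample: str) -> str:
    return f"{sample}.meth"


def cov_col(sample: str) -> str:
    return f"{sample}.cov"


def read_coverage_file(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Read one Bismark coverage file into a per-sample CpG table.

    The Bismark coverage dialect is a 6-column TSV with 1-based inclusive
    coordinates: chrom, start, end, methylation %, methylated count,
    unmethylated count.  The methylation % column is ignored (it is
    recomputed from the counts); a mismatch between the reported percentage
    and the counts is logged, and the counts win.

    Returns a frame with columns ``chrom`` (str), ``pos`` (0-based int),
    ``meth`` and ``cov``.  Lines with zero total reads are kept with
    ``cov == 0`` (the depth filter drops them later).
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        log.warning("coverage file %s is empty (sample %s)", path, sample_id)
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "pos": pd.Series(dtype=np.int64),
                             "meth": pd.Series(dtype=np.int64),
                             "cov": pd.Series(dtype=np.int64)})
    if raw.shape[1] != 6:
        raise ValueError(
            f"{path}: expected 6 tab-separated columns (Bismark coverage "
            f"format), found {raw.shape[1]}")

    start = pd.to_numeric(raw[1], errors="coerce")
    meth = pd.to_numeric(raw[4], errors="coerce")
    unmeth = pd.to_numeric(raw[5], errors="coerce")
    bad = start.isna() | meth.isna() | unmeth.isna()
    for col in (start, meth, unmeth):
        bad |= col.notna() & (col % 1 != 0)
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 1)[:5].tolist()
        raise ValueError(
            f"{path}: non-integer or non-numeric coordinate/count fields on "
            f"line(s) {lines}")
    if (meth < 0).any() or (unmeth < 0).any():
        raise ValueError(f"{path}: negative counts")

    cov = (meth + unmeth).astype(np.int64)
    meth = meth.astype(np.int64)
    reported_pct = pd.to_numeric(raw[3], errors="coerce")
    with np.errstate(invalid="ignore"):
        recomputed = np.where(cov > 0, 100.0 * meth / cov.replace(0, 1), 0.0)
    mism = reported_pct.notna() & (cov > 0) & (
        (reported_pct - recomputed).abs() > 0.1)
    if mism.any():
        log.warning(
            "%s (sample %s): methylation %% column inconsistent with counts "
            "on %d line(s); counts take precedence", path, sample_id,
            int(mism.sum()))

    return pd.DataFrame({
        "chrom": raw[0].astype(str),
        "pos": (start - 1).astype(np.int64),
        "meth": meth,
        "cov": cov,
    })


def write_coverage_file(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-sample CpG table (chrom/pos/meth/cov) as Bismark coverage.

    Inverse of :func:`read_coverage_file` on counts and positions.
    """
    cov = table["cov"].to_numpy()
    meth = table["meth"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(cov > 0, 100.0 * meth / np.where(cov > 0, cov, 1), 0.0)
    out = pd.DataFrame({
        0: table["chrom"].to_numpy(),
        1: table["pos"].to_numpy() + 1,
        2: table["pos"].to_numpy() + 1,
        3: np.round(pct, 6),
        4: meth,
        5: cov - meth,
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def merge_samples(tables: Mapping[str, pd.DataFrame],
                  samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Merge per-sample CpG tables into one wide table on the position union.

    A sample lacking a site gets ``meth = cov = 0`` there.  Duplicate
    positions within one sample are a hard error.
    """
    if samples is None:
        samples = list(tables)
    if len(samples) < 2:
        raise ValueError("merge_samples requires at least 2 samples")
    frames = []
    for s in samples:
        t = tables[s]
        dup = t.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError(f"sample {s}: duplicate positions, e.g. "
                             f"{t.loc[dup, ['chrom', 'pos']].iloc[0].tolist()}")
        frames.append(t.set_index(["chrom", "pos"])[["meth", "cov"]]
                      .rename(columns={"meth": meth_col(s), "cov": cov_col(s)}))
    merged = pd.concat(frames, axis=1).fillna(0)
    merged = merged.astype(np.int64).sort_index()
    merged = merged.reset_index()
    merged["chrom"] = merged["chrom"].astype(str)
    return merged


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3/BED6 file as 0-based half-open intervals."""
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 else None
            strand = fields[5] if len(fields) > 5 else None
            intervals.append(GenomicInterval(chrom, start, end, name, strand))
    return intervals


def read_gene_set(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene list; case preserved, de-duplicated."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_results_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table with a header and stable column order."""
    table.to_csv(path, sep="\t", index=False)


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
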