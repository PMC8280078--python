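"""Preprocessing chain: depth filter, blacklist exclusion, median coverage
normalization, sliding-window tiling and promoter restriction.

The inference unit downstream is the *tile*: a fixed-width window (default
250 bp, advancing in 125 bp steps) over which methylated and total read
counts of member CpGs are summed per sample.  Only tiles overlapping a
promoter — 2000 bp upstream to 200 bp downstream of a transcription start
site, strand-aware — are kept for testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GenomicInterval, cov_col, meth_col

log = logging.getLogger(__name__)

__all__ = [
    "TilingParams",
    "filter_depth",
    "filter_blacklist",
    "normalize_coverage",
    "make_tiles",
    "promoter_interval",
    "restrict_to_promoters",
]


@dataclass
class TilingParams:
    """Window and filter geometry for the preprocessing chain.

    tile_size / step_size: window width and stride in bp.
    min_depth: minimum reads required in *every* sample for a CpG to enter.
    min_cpgs_per_tile: minimum member CpGs for a candidate window to become
        a tile.
    promoter_upstream / promoter_downstream: promoter extent around the TSS,
        in bp, measured along the gene's strand.
    """

    tile_size: int = 250
    step_size: int = 125
    min_depth: int = 10
    min_cpgs_per_tile: int = 1
    promoter_upstream: int = 2000
    promoter_downstream: int = 200

    def __post_init__(self) -> None:
        if self.tile_size <= 0 or self.step_size <= 0:
            raise ValueError("tile_size and step_size must be positive")
        if self.step_size > self.tile_size:
            raise ValueError("step_size must not exceed tile_size")
        if self.min_depth < 0 or self.min_cpgs_per_tile < 1:
            raise ValueError("min_depth >= 0 and min_cpgs_per_tile >= 1 required")
        if self.promoter_upstream < 0 or self.promoter_downstream < 0:
            raise ValueError("promoter extents must be non-negative")


def filter_depth(table: pd.DataFrame, samples: Sequence[str],
                 min_depth: int) -> pd.DataFrame:
    """Keep CpGs with coverage >= min_depth in every sample (inclusive)."""
    if min_depth <= 0:
        return table.copy()
    covs = table[[cov_col(s) for s in samples]].to_numpy()
    mask = (covs >= min_depth).all(axis=1)
    out = table.loc[mask].reset_index(drop=True)
    if out.empty:
        log.warning("depth filter (min_depth=%d) removed every site", min_depth)
    return out


def _trees(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def filter_blacklist(table: pd.DataFrame,
                     blacklist: Sequence[GenomicInterval]) -> pd.DataFrame:
    """Drop CpGs whose position falls inside any blacklist interval."""
    if not blacklist:
        return table.copy()
    trees = _trees(blacklist)
    keep = np.ones(len(table), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(table["chrom"], table["pos"])):
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps_point(int(pos)):
            keep[i] = False
    return table.loc[keep].reset_index(drop=True)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def normalize_coverage(table: pd.DataFrame, samples: Sequence[str]
                       ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Median-scale per-sample coverage; preserve per-site methylation levels.

    For each sample the median coverage over retained sites is computed; the
    scaling factor is (median of the per-sample medians) / (sample median).
    Coverage is multiplied by the factor and rounded (half away from zero,
    floor 1 for covered sites); the methylated count is rescaled so the
    site's methylation proportion is preserved, then clamped to coverage.
    """
    medians = {}
    for s in samples:
        m = float(np.median(table[cov_col(s)].to_numpy()))
        if m <= 0:
            raise ValueError(f"sample {s}: zero median coverage; cannot "
                             "derive a scaling factor")
        medians[s] = m
    target = float(np.median(list(medians.values())))
    factors = {s: target / medians[s] for s in samples}

    out = table.copy()
    for s in samples:
        cov = table[cov_col(s)].to_numpy(dtype=float)
        meth = table[meth_col(s)].to_numpy(dtype=float)
        new_cov = _round_half_away(cov * factors[s])
        new_cov = np.where(cov > 0, np.maximum(new_cov, 1), 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = np.where(cov > 0, meth / np.where(cov > 0, cov, 1), 0.0)
        new_meth = np.minimum(_round_half_away(prop * new_cov), new_cov)
        out[cov_col(s)] = new_cov.astype(np.int64)
        out[meth_col(s)] = new_meth.astype(np.int64)
    return out, factors


def make_tiles(table: pd.DataFrame, samples: Sequence[str],
               params: TilingParams) -> pd.DataFrame:
    """Sum CpG counts into sliding windows anchored at position 0.

    Candidate windows start at multiples of ``step_size``; a CpG at position
    p is a member of every window w with w.start <= p < w.start + tile_size
    (up to ceil(tile_size / step_size) windows).  A window becomes a tile iff
    it holds at least ``min_cpgs_per_tile`` CpGs.
    """
    tile, step = params.tile_size, params.step_size
    pos = table["pos"].to_numpy()
    j_hi = pos // step
    j_lo = np.maximum((pos - tile) // step + 1, 0)
    n_win = (j_hi - j_lo + 1).astype(np.int64)

    row_idx = np.repeat(np.arange(len(table)), n_win)
    # window index within each CpG's membership range
    offsets = np.concatenate([np.arange(n) for n in n_win]) if len(table) else \
        np.empty(0, dtype=np.int64)
    win_start = (np.repeat(j_lo, n_win) + offsets) * step

    expanded = pd.DataFrame({
        "chrom": table["chrom"].to_numpy()[row_idx],
        "start": win_start,
    })
    for s in samples:
        expanded[meth_col(s)] = table[meth_col(s)].to_numpy()[row_idx]
        expanded[cov_col(s)] = table[cov_col(s)].to_numpy()[row_idx]
    expanded["n_cpgs"] = 1

    agg = expanded.groupby(["chrom", "start"], sort=True).sum().reset_index()
    agg = agg.loc[agg["n_cpgs"] >= params.min_cpgs_per_tile].reset_index(drop=True)
    agg.insert(2, "end", agg["start"] + tile)
    cols = ["chrom", "start", "end", "n_cpgs"] + \
        [c for s in samples for c in (meth_col(s), cov_col(s))]
    return agg[cols]


def promoter_interval(tss: int, strand: str, params: TilingParams
                      ) -> tuple[int, int]:
    """Strand-aware promoter window around a TSS, 0-based half-open.

    Plus strand: [tss - upstream, tss + downstream]; minus strand mirrored.
    """
    if strand == "+":
        lo, hi = tss - params.promoter_upstream, tss + params.promoter_downstream
    elif strand == "-":
        lo, hi = tss - params.promoter_downstream, tss + params.promoter_upstream
    else:
        raise ValueError(f"gene without a valid strand: {strand!r}")
    return max(lo, 0), hi + 1


def gene_tss(gene: GenomicInterval) -> int:
    """TSS of a stranded BED gene record: start for +, end-1 for -."""
    if gene.strand == "+":
        return gene.start
    if gene.strand == "-":
        return gene.end - 1
    raise ValueError(f"gene {gene.name!r} without a valid strand: {gene.strand!r}")


def restrict_to_promoters(tiles: pd.DataFrame,
                          genes: Sequence[GenomicInterval],
                          params: TilingParams) -> pd.DataFrame:
    """Keep tiles overlapping >= 1 promoter; annotate all overlapping genes.

    A tile overlapping the promoters of several genes carries all of their
    symbols (comma-joined, sorted).
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        lo, hi = promoter_interval(gene_tss(g), g.strand, params)
        if lo < hi:
            trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g.name)

    annot: list[str] = []
    keep = np.zeros(len(tiles), dtype=bool)
    for i, (chrom, start, end) in enumerate(
            zip(tiles["chrom"], tiles["start"], tiles["end"])):
        tree = trees.get(chrom)
        hits = tree.overlap(int(start), int(end)) if tree is not None else ()
        if hits:
            keep[i] = True
            annot.append(",".join(sorted({h.data for h in hits})))
    out = tiles.loc[keep].reset_index(drop=True)
    out.insert(4, "genes", annot)
    return out
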