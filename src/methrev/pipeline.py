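"""End-to-end orchestration: read -> filter -> normalize -> tile -> promoter
restrict -> per-contrast DM testing -> reversal classification -> enrichment.

A single :class:`RunConfig` (usually loaded from YAML) drives the run; every
output table is written to the configured directory together with a manifest
recording the resolved configuration, a hash of it, per-stage record counts
and package versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffmeth import DMParams, test_contrast
from .enrichment import ora_multi
from .io import (merge_samples, read_bed, read_coverage_file, read_gene_set,
                 write_results_tsv)
from .reversal import classify_reversal, overlap_contrasts, summarize_genes
from .tiling import (TilingParams, filter_blacklist, filter_depth, make_tiles,
                     normalize_coverage, restrict_to_promoters)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_volcano_table"]

#: cap on -log10(q) in volcano tables when q underflows to 0
VOLCANO_LOG_CAP = 350.0


@dataclass
class Contrast:
    name: str
    control: str
    experimental: str


@dataclass
class RunConfig:
    """Paths, parameters and contrast definitions for one pipeline run.

    ``samples`` maps sample id -> group label; ``coverage_files`` maps sample
    id -> Bismark coverage path.  ``contrasts`` are ordered (control,
    experimental) group pairs; ``reversal`` names the injury and treatment
    contrasts to overlap.
    """

    samples: dict[str, str]
    coverage_files: dict[str, str]
    gene_table: str
    out_dir: str
    blacklist: str | None = None
    gene_sets: dict[str, str] = field(default_factory=dict)
    tiling: TilingParams = field(default_factory=TilingParams)
    dm: DMParams = field(default_factory=DMParams)
    contrasts: list[Contrast] = field(default_factory=lambda: [
        Contrast("injury", "Sham-Vehicle", "SNI-Vehicle"),
        Contrast("treatment", "SNI-Vehicle", "SNI-SAM"),
    ])
    reversal: dict[str, str] = field(default_factory=lambda: {
        "injury": "injury", "treatment": "treatment"})
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.tiling, dict):
            self.tiling = TilingParams(**self.tiling)
        if isinstance(self.dm, dict):
            self.dm = DMParams(**self.dm)
        self.contrasts = [Contrast(**c) if isinstance(c, dict) else c
                          for c in self.contrasts]
        groups = set(self.samples.values())
        for c in self.contrasts:
            for g in (c.control, c.experimental):
                if g not in groups:
                    raise ValueError(
                        f"contrast {c.name!r} references group {g!r} which "
                        f"no sample belongs to")
        missing = set(self.samples) - set(self.coverage_files)
        if missing:
            raise ValueError(f"samples without coverage files: {sorted(missing)}")
        names = {c.name for c in self.contrasts}
        for role, cname in self.reversal.items():
            if cname not in names:
                raise ValueError(
                    f"reversal {role} contrast {cname!r} is not defined")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def group_samples(self, group: str) -> list[str]:
        return [s for s, g in self.samples.items() if g == group]

    def resolved(self) -> dict:
        d = asdict(self)
        return d


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.resolved(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the result bundle.

    The bundle holds the promoter tile table, one contrast table per
    configured contrast, the reversal records and summary, gene summaries,
    the enrichment table (when gene sets are configured) and the manifest.
    All of these are also written under ``cfg.out_dir``.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = list(cfg.samples)
    counts: dict[str, int] = {}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    tables = {s: stage(f"read:{s}", read_coverage_file,
                       cfg.coverage_files[s], s) for s in samples}
    merged = stage("merge", merge_samples, tables, samples)
    counts["cpgs_raw"] = len(merged)

    merged = stage("depth_filter", filter_depth, merged, samples,
                   cfg.tiling.min_depth)
    counts["cpgs_depth_filtered"] = len(merged)

    if cfg.blacklist:
        blacklist = stage("read_blacklist", read_bed, cfg.blacklist)
        merged = stage("blacklist_filter", filter_blacklist, merged, blacklist)
    counts["cpgs_blacklist_filtered"] = len(merged)

    merged, factors = stage("normalize", normalize_coverage, merged, samples)

    tiles = stage("tiling", make_tiles, merged, samples, cfg.tiling)
    counts["tiles"] = len(tiles)

    genes = stage("read_genes", read_bed, cfg.gene_table)
    tiles = stage("promoter_restrict", restrict_to_promoters, tiles, genes,
                  cfg.tiling)
    counts["promoter_tiles"] = len(tiles)
    write_results_tsv(tiles, out_dir / "tiles.tsv")

    contrast_tables: dict[str, pd.DataFrame] = {}
    pi0s: dict[str, float] = {}
    for c in cfg.contrasts:
        res = stage(f"diffmeth:{c.name}", test_contrast, tiles,
                    cfg.group_samples(c.control),
                    cfg.group_samples(c.experimental), cfg.dm)
        contrast_tables[c.name] = res
        pi0s[c.name] = res.attrs["pi0"]
        counts[f"dm_tiles_{c.name}"] = int(
            (res["status"] != "not_significant").sum())
        write_results_tsv(res, out_dir / f"contrast_{c.name}.tsv")

    injury = contrast_tables[cfg.reversal["injury"]]
    treatment = contrast_tables[cfg.reversal["treatment"]]
    paired, overlap_counts = stage("overlap", overlap_contrasts, injury,
                                   treatment)
    records, summary = stage("classify_reversal", classify_reversal, paired)
    summary["overlap"] = overlap_counts
    counts["paired_dm_tiles"] = overlap_counts["paired"]
    write_results_tsv(records, out_dir / "reversal.tsv")
    gene_summary = stage("summarize_genes", summarize_genes, records)
    write_results_tsv(gene_summary, out_dir / "gene_summary.tsv")
    with open(out_dir / "reversal_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    enrichment_table = None
    if cfg.gene_sets:
        population = _unique_genes(tiles["genes"])
        gene_sets = {name: read_gene_set(path)
                     for name, path in cfg.gene_sets.items()}
        frames = []
        hit_sets = {
            f"dm_{name}": _unique_genes(
                tab.loc[tab["status"] != "not_significant", "genes"])
            for name, tab in contrast_tables.items()
        }
        hit_sets["reversing"] = _unique_genes(
            records.loc[records["reversal_class"].str.startswith("reversal"),
                        "genes_injury"]) if len(records) else set()
        for condition, hits in hit_sets.items():
            tab = stage(f"enrichment:{condition}", ora_multi, population,
                        gene_sets, hits & population)
            tab.insert(0, "condition", condition)
            frames.append(tab)
        enrichment_table = pd.concat(frames, ignore_index=True)
        write_results_tsv(enrichment_table, out_dir / "enrichment.tsv")

    manifest = {
        "config": cfg.resolved(),
        "config_hash": _config_hash(cfg),
        "version": __version__,
        "seed": cfg.seed,
        "stage_counts": counts,
        "normalization_factors": factors,
        "pi0": pi0s,
        "adjustment_method": cfg.dm.adjustment_method,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return {
        "tiles": tiles,
        "contrasts": contrast_tables,
        "reversal_records": records,
        "reversal_summary": summary,
        "gene_summary": gene_summary,
        "enrichment": enrichment_table,
        "manifest": manifest,
    }


def _unique_genes(series: pd.Series) -> set[str]:
    genes: set[str] = set()
    for g in series.dropna():
        genes.update(str(g).split(","))
    genes.discard("")
    return genes


def make_volcano_table(contrast: pd.DataFrame,
                       params: DMParams | None = None) -> pd.DataFrame:
    """Table behind a volcano plot: meth_diff vs -log10(q) with categories.

    Categories follow the usual volcano legend: hyper / hypo (significant and
    large difference), nonsignificant_large_diff, significant_small_diff and
    not_different.  -log10(q) is capped at VOLCANO_LOG_CAP when q underflows.
    """
    params = params or DMParams()
    q = contrast["q_value"].to_numpy()
    diff = contrast["meth_diff"].to_numpy()
    with np.errstate(divide="ignore"):
        neg_log_q = np.where(q > 0, -np.log10(np.where(q > 0, q, 1.0)),
                             VOLCANO_LOG_CAP)
    neg_log_q = np.minimum(neg_log_q, VOLCANO_LOG_CAP)
    sig = q < params.q_threshold
    large = np.abs(diff) > params.diff_threshold_percent
    category = np.full(len(contrast), "not_different", dtype=object)
    category[sig & large & (diff > 0)] = "hyper"
    category[sig & large & (diff < 0)] = "hypo"
    category[~sig & large] = "nonsignificant_large_diff"
    category[sig & ~large] = "significant_small_diff"
    out = contrast[["chrom", "start", "end"]].copy()
    out["meth_diff"] = diff
    out["neg_log10_q"] = neg_log_q
    out["category"] = category
    return out
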