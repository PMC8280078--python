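"""Dual-contrast reversal analysis.

The injury contrast (injured vs uninjured controls) and the treatment
contrast (treated-injured vs untreated-injured) are overlapped on exact tile
coordinates.  A tile that is differentially methylated in *both* contrasts
is classified by the sign rule:

* injury hyper, treatment hypo  -> reversal_of_hypermethylation
* injury hypo,  treatment hyper -> reversal_of_hypomethylation
* same status in both           -> no_reversal

Under exact coordinate matching the rule is exhaustive; the ``unclear``
class only arises in the optional overlap-based matching mode when partially
overlapping tiles of one gene disagree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "REVERSAL_CLASSES",
    "overlap_contrasts",
    "classify_reversal",
    "reversal_percentages",
    "summarize_genes",
]

REVERSAL_CLASSES = (
    "reversal_of_hypermethylation",
    "reversal_of_hypomethylation",
    "no_reversal",
    "unclear",
)

_KEY = ["chrom", "start", "end"]


def _dm(table: pd.DataFrame) -> pd.DataFrame:
    return table.loc[table["status"].isin(["hyper", "hypo"])]


def overlap_contrasts(injury: pd.DataFrame, treatment: pd.DataFrame
                      ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Pair tiles DM in both contrasts on exact (chrom, start, end) keys.

    Returns the paired table (columns suffixed ``_injury``/``_treatment``)
    and tallies of tiles DM in only one contrast.  If the two tables share
    no exact keys at all but their DM intervals overlap heavily, the tiling
    parameters almost certainly differ and a hard error is raised.
    """
    dm_i, dm_t = _dm(injury), _dm(treatment)
    paired = dm_i.merge(dm_t, on=_KEY, suffixes=("_injury", "_treatment"))
    counts = {
        "paired": len(paired),
        "injury_only": len(dm_i) - len(paired),
        "treatment_only": len(dm_t) - len(paired),
    }
    if paired.empty and not dm_i.empty and not dm_t.empty:
        n_partial = _count_partial_overlaps(dm_i, dm_t)
        if n_partial >= max(10, 0.1 * min(len(dm_i), len(dm_t))):
            raise ValueError(
                "no exact tile matches between contrasts but "
                f"{n_partial} partial overlaps found; the two contrast "
                "tables were likely produced with different tiling parameters")
    return paired, counts


def _count_partial_overlaps(a: pd.DataFrame, b: pd.DataFrame) -> int:
    n = 0
    for chrom, ga in a.groupby("chrom"):
        gb = b.loc[b["chrom"] == chrom]
        if gb.empty:
            continue
        starts = gb["start"].to_numpy()
        ends = gb["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        for s, e in zip(ga["start"], ga["end"]):
            i = np.searchsorted(starts, e)
            if np.any(ends[:i] > s):
                n += 1
    return n


def classify_reversal(paired: pd.DataFrame
                      ) -> tuple[pd.DataFrame, dict]:
    """Assign one reversal class per paired tile and summarize.

    The summary holds counts, percentages (one decimal) and unique gene
    counts per class; a gene belongs to a class if at least one of its tiles
    does.
    """
    records = paired.copy()
    si = records["status_injury"].to_numpy()
    st = records["status_treatment"].to_numpy()
    cls = np.where(
        (si == "hyper") & (st == "hypo"), "reversal_of_hypermethylation",
        np.where((si == "hypo") & (st == "hyper"),
                 "reversal_of_hypomethylation", "no_reversal"))
    records["reversal_class"] = cls

    counts = {c: int((cls == c).sum()) for c in REVERSAL_CLASSES}
    summary = {
        "n_paired": len(records),
        "counts": counts,
        "percentages": reversal_percentages(counts),
        "n_reversing": counts["reversal_of_hypermethylation"]
        + counts["reversal_of_hypomethylation"],
    }
    if "genes_injury" in records.columns:
        genes_per_class = {}
        for c in REVERSAL_CLASSES:
            sub = records.loc[records["reversal_class"] == c, "genes_injury"]
            genes = set()
            for g in sub.dropna():
                genes.update(str(g).split(","))
            genes.discard("")
            genes_per_class[c] = len(genes)
        summary["genes_per_class"] = genes_per_class
    return records, summary


def reversal_percentages(counts: dict[str, int]) -> dict[str, float]:
    """Percent of paired tiles per class, rounded to one decimal.

    Pure bookkeeping on class counts, usable with externally reported tile
    tallies as well as with counts from :func:`classify_reversal`.
    """
    total = sum(counts.values())
    if total == 0:
        return {c: 0.0 for c in counts}
    return {c: round(100.0 * n / total, 1) for c, n in counts.items()}


def summarize_genes(records: pd.DataFrame) -> pd.DataFrame:
    """Gene-level aggregation: mean tile meth_diff per contrast.

    For each gene (a tile annotated to several genes contributes to each),
    the mean of its tiles' methylation differences is reported per contrast,
    with the standard error across tiles when a gene has >= 2 tiles (NaN for
    singletons).
    """
    if records.empty:
        return pd.DataFrame(columns=[
            "gene", "n_tiles", "mean_meth_diff_injury", "se_meth_diff_injury",
            "mean_meth_diff_treatment", "se_meth_diff_treatment"])
    work = records[["genes_injury", "meth_diff_injury",
                    "meth_diff_treatment"]].copy()
    work["gene"] = work["genes_injury"].astype(str).str.split(",")
    work = work.explode("gene")
    work = work.loc[work["gene"] != ""]

    def _agg(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        res = {
            "n_tiles": n,
            "mean_meth_diff_injury": g["meth_diff_injury"].mean(),
            "mean_meth_diff_treatment": g["meth_diff_treatment"].mean(),
            "se_meth_diff_injury": (g["meth_diff_injury"].std(ddof=1)
                                    / np.sqrt(n)) if n >= 2 else np.nan,
            "se_meth_diff_treatment": (g["meth_diff_treatment"].std(ddof=1)
                                       / np.sqrt(n)) if n >= 2 else np.nan,
        }
        return pd.Series(res)

    out = work.groupby("gene", sort=True).apply(_agg, include_groups=False)
    out = out.reset_index()
    out["n_tiles"] = out["n_tiles"].astype(int)
    return out[["gene", "n_tiles", "mean_meth_diff_injury",
                "se_meth_diff_injury", "mean_meth_diff_treatment",
                "se_meth_diff_treatment"]]
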