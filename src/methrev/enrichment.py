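"""Hypergeometric over-representation of curated gene sets.

The population is the set of unique genes the pipeline could actually
evaluate (genes whose promoters yielded at least one analyzable tile); the
test asks whether a curated set (e.g. pain-related genes) is over-represented
among the hit genes (differentially methylated, or reversing).  The p-value
is the exact upper-tail hypergeometric probability P(X >= k), computed by
explicit summation of probability mass terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy.stats import hypergeom

from .diffmeth import qvalues_from_pi0

log = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "hypergeom_enrichment", "ora_multi"]


@dataclass
class EnrichmentResult:
    """Summary of one gene-set over-representation test.

    N: population size; K: gene-set members inside the population;
    n: number of hit genes; k: hits that are gene-set members;
    p_value: P(X >= k) for X ~ Hypergeometric(N, K, n).
    """

    name: str
    N: int
    K: int
    n: int
    k: int
    p_value: float
    n_dropped: int = 0  # gene-set members absent from the population


def hypergeom_enrichment(population: set[str], gene_set: set[str],
                         hits: set[str], name: str = "gene_set"
                         ) -> EnrichmentResult:
    """Exact upper-tail hypergeometric over-representation test.

    ``hits`` must be a subset of ``population``; gene-set members outside the
    population are dropped (and counted in ``n_dropped``) before testing.
    """
    if not population:
        raise ValueError("population is empty")
    if not hits <= population:
        extra = sorted(hits - population)[:5]
        raise ValueError(f"hits not contained in population, e.g. {extra}")
    in_pop = gene_set & population
    n_dropped = len(gene_set) - len(in_pop)
    if n_dropped:
        log.info("gene set %s: %d member(s) absent from the population",
                 name, n_dropped)
    N, K, n = len(population), len(in_pop), len(hits)
    k = len(hits & in_pop)
    upper = min(K, n)
    p = float(sum(hypergeom.pmf(range(k, upper + 1), N, K, n)))
    p = min(max(p, 0.0), 1.0)
    return EnrichmentResult(name, N, K, n, k, p, n_dropped)


def ora_multi(population: set[str], gene_sets: Mapping[str, set[str]],
              hits: set[str]) -> pd.DataFrame:
    """Over-representation of several gene sets, BH-adjusted across sets.

    Returns one row per set sorted by p-value, with N, K, n, k, p_value and
    q_value columns.
    """
    if not gene_sets:
        raise ValueError("at least one gene set is required")
    results = [hypergeom_enrichment(population, gs, hits, name)
               for name, gs in gene_sets.items()]
    table = pd.DataFrame([r.__dict__ for r in results])
    table["q_value"] = qvalues_from_pi0(table["p_value"].to_numpy(), 1.0)
    table = table.sort_values("p_value", kind="stable").reset_index(drop=True)
    return table[["name", "N", "K", "n", "k", "p_value", "q_value",
                  "n_dropped"]]
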