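"""Per-tile two-group differential methylation testing.

The model is a binomial logistic regression with a single group indicator:
logit(pi_i) = b0 + b1 * group_i over the per-sample (methylated, total)
observations of one tile.  Because the only covariate is the group label,
the maximum-likelihood fit has a closed form — the fitted proportions are
the pooled group proportions — so the likelihood-ratio statistic against
the null (b1 = 0) is computed directly and referred to chi-square(1).

The control group is the reference: positive meth_diff / log odds ratio
means the experimental group is more methylated (hypermethylation).

P-values are converted to q-values either by Benjamini-Hochberg or by a
pi0-scaled BH in which pi0 (the proportion of true nulls) is estimated with
a sliding-linear-model (SLIM) fit to the p-value ECDF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2

from .io import cov_col, meth_col

__all__ = [
    "DMParams",
    "logistic_dm_test",
    "test_contrast",
    "estimate_pi0_slim",
    "qvalues_from_pi0",
    "slim_adjust",
    "call_status",
]

# proportions are clamped here when forming the log odds ratio, which caps
# |log OR| on separated (0% or 100%) tiles; equivalent to a tiny ridge
_PROP_EPS = 1e-8
_STATUSES = ("hyper", "hypo", "not_significant")


@dataclass
class DMParams:
    """Significance thresholds and adjustment method for DM calling.

    A tile is differentially methylated when its adjusted p-value is below
    ``q_threshold`` (default 0.1, exploratory) *and* its absolute pooled
    methylation difference exceeds ``diff_threshold_percent`` (default 5).
    Tiles additionally below ``robust_threshold`` are flagged robust.
    """

    q_threshold: float = 0.1
    diff_threshold_percent: float = 5.0
    robust_threshold: float = 1e-7
    adjustment_method: str = "SLIM"

    def __post_init__(self) -> None:
        if not (0 < self.robust_threshold < self.q_threshold <= 1):
            raise ValueError("need 0 < robust_threshold < q_threshold <= 1")
        if self.adjustment_method not in ("SLIM", "BH"):
            raise ValueError("adjustment_method must be 'SLIM' or 'BH'")


def _binom_loglik(meth: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Maximized binomial log-likelihood of pooled counts (up to constants)."""
    unmeth = total - meth
    with np.errstate(invalid="ignore", divide="ignore"):
        return xlogy(meth, meth / total) + xlogy(unmeth, unmeth / total)


def _lrt_arrays(mc: np.ndarray, tc: np.ndarray, me: np.ndarray, te: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized LRT on pooled group counts.

    Returns (log_odds_ratio, p_value, meth_diff_percent, lrt_statistic).
    """
    mc, tc, me, te = (np.asarray(a, dtype=float) for a in (mc, tc, me, te))
    if np.any(tc <= 0) or np.any(te <= 0):
        raise ValueError("a group has zero total reads in at least one tile")
    ll_full = _binom_loglik(mc, tc) + _binom_loglik(me, te)
    ll_null = _binom_loglik(mc + me, tc + te)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = chi2.sf(lrt, df=1)

    pc = mc / tc
    pe = me / te
    meth_diff = 100.0 * (pe - pc)
    pc_c = np.clip(pc, _PROP_EPS, 1 - _PROP_EPS)
    pe_c = np.clip(pe, _PROP_EPS, 1 - _PROP_EPS)
    log_or = np.log(pe_c / (1 - pe_c)) - np.log(pc_c / (1 - pc_c))
    # both groups fully unmethylated or fully methylated: no information
    degenerate = (pc == pe) & ((pc == 0.0) | (pc == 1.0))
    log_or = np.where(degenerate, 0.0, log_or)
    p = np.where(degenerate, 1.0, p)
    return log_or, p, meth_diff, lrt


def logistic_dm_test(tile, control_samples: Sequence[str],
                     experimental_samples: Sequence[str]
                     ) -> tuple[float, float, float]:
    """Test one tile; returns (log_odds_ratio, p_value, meth_diff_percent).

    ``tile`` is any mapping (e.g. a tile-table row) holding ``{s}.meth`` and
    ``{s}.cov`` entries for every listed sample.  Every sample must have
    positive total coverage in the tile.
    """
    for s in list(control_samples) + list(experimental_samples):
        if tile[cov_col(s)] <= 0:
            raise ValueError(f"sample {s} has zero total in this tile")
    mc = sum(tile[meth_col(s)] for s in control_samples)
    tc = sum(tile[cov_col(s)] for s in control_samples)
    me = sum(tile[meth_col(s)] for s in experimental_samples)
    te = sum(tile[cov_col(s)] for s in experimental_samples)
    log_or, p, diff, _ = _lrt_arrays(
        np.array([mc]), np.array([tc]), np.array([me]), np.array([te]))
    return float(log_or[0]), float(p[0]), float(diff[0])


def estimate_pi0_slim(p_values: np.ndarray, sta: float = 0.1, divi: int = 10,
                      pz: float = 0.05, n_quantiles: int = 100) -> float:
    """Sliding-linear-model estimate of pi0, the true-null proportion.

    The ECDF of the p-values is fit by least squares in ``divi`` sliding
    windows covering [sta, 1]; each window's slope estimates the null
    density (hence pi0) under the assumption that non-null mass above the
    window start is negligible.  Candidate pi0 values (quantiles of the
    window slopes) are screened by a consistency rule: the smallest
    candidate is accepted whose implied discovery count at its own maximum
    FDR (evaluated at the raw cutoff ``pz``) does not exceed the raw
    discovery count at ``pz``.  Degenerate estimates fall back to pi0 = 1,
    i.e. plain Benjamini-Hochberg.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return 1.0
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    p_sorted = np.sort(p)
    itv = (1.0 - sta) / divi
    slopes = []
    for i in range(divi):
        lam = np.linspace(sta + i * itv, sta + (i + 1) * itv, 11)
        ecdf = np.searchsorted(p_sorted, lam, side="right") / m
        slopes.append(np.polyfit(lam, ecdf, 1)[0])
    slopes = np.clip(np.array(slopes), 0.0, None)

    n_raw = int((p < pz).sum())
    chosen = None
    for qp in np.linspace(0.01, 0.99, n_quantiles):
        pi0 = float(min(np.quantile(slopes, qp), 1.0))
        if pi0 <= 0:
            continue
        max_fdr = pi0 * pz / (1.0 - (1.0 - pz) * pi0)
        n_com = int((qvalues_from_pi0(p, pi0) < max_fdr).sum())
        if n_com <= n_raw:
            chosen = pi0
            break
    if chosen is None:
        chosen = float(min(np.quantile(slopes, 0.5), 1.0))
    if not np.isfinite(chosen) or chosen <= 0:
        chosen = 1.0
    return float(chosen)


def qvalues_from_pi0(p_values: np.ndarray, pi0: float) -> np.ndarray:
    """pi0-scaled step-up FDR adjustment; pi0 = 1 is exactly BH."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    raw = pi0 * p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(adjusted, 0.0, 1.0)
    return q


def slim_adjust(p_values: np.ndarray, method: str = "SLIM",
                return_pi0: bool = False):
    """Adjust p-values to q-values by SLIM (pi0-scaled BH) or plain BH.

    Order-preserving: q_i <= q_j whenever p_i <= p_j.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "BH":
        pi0 = 1.0
    elif method == "SLIM":
        pi0 = estimate_pi0_slim(p) if p.size else 1.0
    else:
        raise ValueError("method must be 'SLIM' or 'BH'")
    q = qvalues_from_pi0(p, pi0)
    return (q, pi0) if return_pi0 else q


def call_status(results: pd.DataFrame, params: DMParams) -> pd.DataFrame:
    """Assign hyper / hypo / not_significant status and the robust flag.

    hyper: q < q_threshold and meth_diff > diff_threshold (strict);
    hypo mirrored; both thresholds are strict inequalities.
    """
    out = results.copy()
    q = out["q_value"].to_numpy()
    diff = out["meth_diff"].to_numpy()
    sig = q < params.q_threshold
    status = np.full(len(out), "not_significant", dtype=object)
    status[sig & (diff > params.diff_threshold_percent)] = "hyper"
    status[sig & (diff < -params.diff_threshold_percent)] = "hypo"
    out["status"] = status
    out["robust"] = (q < params.robust_threshold) & (status != "not_significant")
    return out


def test_contrast(tiles: pd.DataFrame, control_samples: Sequence[str],
                  experimental_samples: Sequence[str],
                  params: DMParams | None = None) -> pd.DataFrame:
    """Run the DM test over a tile table for one control/experimental pair.

    Returns one row per tile: coordinates, gene annotation (if present),
    pooled methylation difference (experimental minus control, percent),
    log odds ratio, p-value, SLIM/BH q-value, status and robust flag.
    The resulting frame carries the fitted pi0 in ``.attrs['pi0']``.
    """
    params = params or DMParams()
    mc = tiles[[meth_col(s) for s in control_samples]].sum(axis=1).to_numpy()
    tc = tiles[[cov_col(s) for s in control_samples]].sum(axis=1).to_numpy()
    me = tiles[[meth_col(s) for s in experimental_samples]].sum(axis=1).to_numpy()
    te = tiles[[cov_col(s) for s in experimental_samples]].sum(axis=1).to_numpy()
    log_or, p, diff, _ = _lrt_arrays(mc, tc, me, te)

    cols = {"chrom": tiles["chrom"], "start": tiles["start"], "end": tiles["end"]}
    if "genes" in tiles.columns:
        cols["genes"] = tiles["genes"]
    if "n_cpgs" in tiles.columns:
        cols["n_cpgs"] = tiles["n_cpgs"]
    out = pd.DataFrame(cols)
    out["meth_diff"] = diff
    out["log_odds_ratio"] = log_or
    out["p_value"] = p
    q, pi0 = slim_adjust(p, method=params.adjustment_method, return_pi0=True)
    out["q_value"] = q
    out = call_status(out, params)
    out.attrs["pi0"] = pi0
    out.attrs["adjustment_method"] = params.adjustment_method
    return out.reset_index(drop=True)
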