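"""Seeded generator of a toy genome and four-group bisulfite count data.

The generator emulates a promoter-capture bisulfite experiment in the
four-group design of a nerve-injury / methyl-donor-treatment study:
Sham-Vehicle (n=3), Sham-SAM (n=3), SNI-Vehicle (n=4), SNI-SAM (n=4).

Genes with stranded TSSs are packed on one synthetic chromosome; CpG sites
are placed at exponential spacing inside each promoter window.  Methylation
effects are planted per 250 bp block (every CpG in a block shares its
group-level mean) so the tiling stage downstream is the natural recovery
unit:

* both Sham groups share a Beta-distributed baseline level;
* a fraction of blocks receive a signed injury effect in SNI-Vehicle
  (positive with probability ``hyper_fraction``);
* a ``reversal_fraction`` subset of the injury blocks has the SNI-SAM mean
  moved back past the baseline (sign change of the treatment contrast),
  while the remainder continues in the injury direction.

Coverage is negative-binomial with per-sample log-normal depth multipliers
(so coverage normalization has real work to do); methylated counts are
beta-binomial around the group mean of the block with intra-CpG
correlation ``meth_overdispersion``.  All randomness flows from
``SimConfig.seed`` through per-(seed, sample, chromosome) generator streams,
so identical configurations yield byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_coverage_file

__all__ = ["GROUPS", "SimConfig", "generate_genome", "generate_counts",
           "simulate_dataset"]

GROUPS = ("Sham-Vehicle", "Sham-SAM", "SNI-Vehicle", "SNI-SAM")

#: width of the effect-planting block, matching the default analysis tile
BLOCK_SIZE = 250

_CHROM = "chr1"
# promoter geometry inside each gene slot: [base+150, base+2351), with the
# TSS placed so a +/- strand promoter (-2000/+200 of the TSS) fills it
_SLOT_MIN = 2600
_PROM_OFFSET = 150
_PROM_SPAN = 2201


def _default_group_sizes() -> dict[str, int]:
    return {"Sham-Vehicle": 3, "Sham-SAM": 3, "SNI-Vehicle": 4, "SNI-SAM": 4}


@dataclass
class SimConfig:
    """Study conditions for the synthetic four-group experiment.

    coverage_mean: mean read depth per CpG per sample (before the per-sample
        log-normal multiplier, sigma = 0.2).
    coverage_dispersion: negative-binomial size parameter k
        (variance = mu + mu^2 / k; larger k = tighter coverage).
    baseline_meth_alpha/beta: Beta shape parameters of the per-block baseline
        methylation level (clipped to [0.2, 0.8] so effects fit).
    meth_overdispersion: beta-binomial intra-CpG correlation rho of the
        methylated counts (0 = pure binomial).
    frac_injury_tiles: fraction of blocks given an injury effect.
    injury_effect_range: (low, high) percent magnitude of injury effects;
        low must be >= 5 so planted effects clear the DM threshold.
    hyper_fraction: probability an injury effect is positive.
    reversal_fraction: fraction of injury blocks whose SNI-SAM mean crosses
        back past the Sham baseline (treatment contrast changes sign).
    """

    n_genes: int = 100
    chrom_length: int = 1_000_000
    cpg_spacing_mean: float = 40.0
    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    coverage_mean: float = 30.0
    coverage_dispersion: float = 20.0
    baseline_meth_alpha: float = 2.0
    baseline_meth_beta: float = 2.0
    meth_overdispersion: float = 0.02
    frac_injury_tiles: float = 0.3
    injury_effect_range: tuple[float, float] = (10.0, 25.0)
    hyper_fraction: float = 0.6
    reversal_fraction: float = 0.927
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_injury_tiles", "hyper_fraction",
                     "reversal_fraction", "meth_overdispersion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.injury_effect_range
        if lo < 5 or hi < lo:
            raise ValueError("injury_effect_range low must be >= 5 percent "
                             "and the range non-decreasing")
        if set(self.group_sizes) != set(GROUPS):
            raise ValueError(f"group_sizes must define exactly {GROUPS}")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 samples")
        if self.n_genes < 1 or self.chrom_length < 1:
            raise ValueError("n_genes and chrom_length must be positive")
        if self.cpg_spacing_mean < 2:
            raise ValueError("cpg_spacing_mean must be >= 2 bp")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")

    @property
    def samples(self) -> list[str]:
        return [f"{g}_{i + 1}" for g in GROUPS
                for i in range(self.group_sizes[g])]

    @property
    def sample_groups(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.samples}


def generate_genome(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out genes and promoter CpG sites on one synthetic chromosome.

    Returns ``(genes, sites)``: a stranded BED-like gene table (chrom, start,
    end, name, score, strand, tss) and a CpG site table (chrom, pos, gene,
    block_start).  Raises if the chromosome cannot hold ``n_genes``
    non-overlapping promoters.
    """
    slot = cfg.chrom_length // cfg.n_genes
    if slot < _SLOT_MIN:
        raise ValueError(
            f"chrom_length {cfg.chrom_length} too small for {cfg.n_genes} "
            f"non-overlapping promoters; need at least "
            f"{cfg.n_genes * _SLOT_MIN} bp")
    rng = np.random.default_rng([cfg.seed, 11])
    strands = rng.choice(["+", "-"], size=cfg.n_genes)

    genes, site_rows = [], []
    for i in range(cfg.n_genes):
        base = i * slot
        prom_start = base + _PROM_OFFSET
        prom_end = prom_start + _PROM_SPAN
        strand = strands[i]
        # TSS such that the strand-aware promoter window fills the slot
        tss = prom_start + 2000 if strand == "+" else prom_start + 200
        name = f"G{i:04d}"
        if strand == "+":
            g_start, g_end = tss, min(tss + 1000, cfg.chrom_length)
        else:
            g_start, g_end = max(tss - 999, 0), tss + 1
        genes.append((_CHROM, g_start, g_end, name, 0, strand, tss))

        gaps = rng.exponential(cfg.cpg_spacing_mean,
                               size=int(_PROM_SPAN / max(cfg.cpg_spacing_mean, 2)) * 3 + 8)
        pos = prom_start + np.cumsum(np.maximum(np.rint(gaps), 2)).astype(np.int64)
        pos = np.unique(pos[pos < prom_end])
        for p in pos:
            site_rows.append((p, name))

    genes_df = pd.DataFrame(genes, columns=["chrom", "start", "end", "name",
                                            "score", "strand", "tss"])
    sites = pd.DataFrame(site_rows, columns=["pos", "gene"])
    sites.insert(0, "chrom", _CHROM)
    sites["block_start"] = (sites["pos"] // BLOCK_SIZE) * BLOCK_SIZE
    return genes_df, sites.sort_values("pos", ignore_index=True)


def _plant_effects(cfg: SimConfig, sites: pd.DataFrame, rng: np.random.Generator
                   ) -> tuple[pd.DataFrame, dict[str, np.ndarray], np.ndarray]:
    """Draw per-block baselines and effects; return truth, group means and
    the per-site block index."""
    blocks = sites[["chrom", "block_start", "gene"]].drop_duplicates(
        subset=["chrom", "block_start"]).reset_index(drop=True)
    nb = len(blocks)
    block_key = {(c, b): i for i, (c, b) in
                 enumerate(zip(blocks["chrom"], blocks["block_start"]))}
    site_block = np.array([block_key[(c, b)] for c, b in
                           zip(sites["chrom"], sites["block_start"])])

    baseline = np.clip(rng.beta(cfg.baseline_meth_alpha,
                                cfg.baseline_meth_beta, nb), 0.2, 0.8)
    injury = np.zeros(nb)
    treatment = np.zeros(nb)
    label = np.full(nb, "null", dtype=object)

    n_injury = int(round(cfg.frac_injury_tiles * nb))
    inj_idx = rng.choice(nb, size=n_injury, replace=False)
    sign = np.where(rng.random(n_injury) < cfg.hyper_fraction, 1.0, -1.0)
    lo, hi = cfg.injury_effect_range
    inj_eff = sign * rng.uniform(lo, hi, n_injury) / 100.0

    n_rev = int(round(cfg.reversal_fraction * n_injury))
    rev_pick = rng.choice(n_injury, size=n_rev, replace=False)
    is_rev = np.zeros(n_injury, dtype=bool)
    is_rev[rev_pick] = True
    # reversal: cross back past the Sham baseline by 10-40% of the injury
    # magnitude; no reversal: continue in the injury direction with a
    # comparable-magnitude treatment shift (so both classes are detectable)
    overshoot = rng.uniform(0.1, 0.4, n_injury)
    continuation = rng.uniform(0.8, 1.2, n_injury)
    treat_eff = np.where(is_rev, -inj_eff * (1.0 + overshoot),
                         inj_eff * continuation)

    injury[inj_idx] = inj_eff
    treatment[inj_idx] = treat_eff
    label[inj_idx] = np.where(is_rev, "true_reversal", "no_reversal")

    mu_sham = baseline
    mu_sni_veh = np.clip(baseline + injury, 0.01, 0.99)
    mu_sni_sam = np.clip(baseline + injury + treatment, 0.01, 0.99)
    clamped = ((baseline + injury) != mu_sni_veh) | \
        ((baseline + injury + treatment) != mu_sni_sam)

    truth = blocks.copy()
    truth.rename(columns={"block_start": "start"}, inplace=True)
    truth["end"] = truth["start"] + BLOCK_SIZE
    truth["baseline_meth"] = baseline
    truth["injury_effect_percent"] = 100.0 * injury
    truth["treatment_effect_percent"] = 100.0 * treatment
    truth["label"] = label
    truth["clamped"] = clamped
    truth = truth[["chrom", "start", "end", "gene", "baseline_meth",
                   "injury_effect_percent", "treatment_effect_percent",
                   "label", "clamped"]]

    group_means = {
        "Sham-Vehicle": mu_sham,
        "Sham-SAM": mu_sham,
        "SNI-Vehicle": mu_sni_veh,
        "SNI-SAM": mu_sni_sam,
    }
    return truth, group_means, site_block


def generate_counts(cfg: SimConfig, genes: pd.DataFrame, sites: pd.DataFrame,
                    out_dir: str | Path | None = None
                    ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate per-sample bisulfite counts over the generated genome.

    Returns ``(tables, truth)`` where ``tables`` maps sample id to a
    chrom/pos/meth/cov frame and ``truth`` is the per-block ground-truth
    table.  When ``out_dir`` is given, Bismark coverage files (one per
    sample), the gene table (BED6), the ground truth (TSV) and a ready-to-run
    pipeline configuration are written there.
    """
    truth, group_means, site_block = _plant_effects(
        cfg, sites, np.random.default_rng([cfg.seed, 23]))

    mult_rng = np.random.default_rng([cfg.seed, 31])
    multipliers = mult_rng.lognormal(mean=0.0, sigma=0.2,
                                     size=len(cfg.samples))
    # mean-one depth multipliers: relative library-size differences remain
    # (normalization has work to do) but marginal coverage stays calibrated
    multipliers /= multipliers.mean()

    k = cfg.coverage_dispersion
    rho = cfg.meth_overdispersion
    n_sites = len(sites)
    tables: dict[str, pd.DataFrame] = {}
    for i, sample in enumerate(cfg.samples):
        group = cfg.sample_groups[sample]
        rng = np.random.default_rng([cfg.seed, 1009 + i, 0])
        mu_cov = cfg.coverage_mean * multipliers[i]
        cov = rng.negative_binomial(k, k / (k + mu_cov), size=n_sites)
        mu = group_means[group][site_block]
        if rho > 0:
            shape = 1.0 / rho - 1.0
            p = rng.beta(mu * shape, (1.0 - mu) * shape)
        else:
            p = mu
        meth = rng.binomial(cov, p)
        tables[sample] = pd.DataFrame({
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "meth": meth.astype(np.int64),
            "cov": cov.astype(np.int64),
        })

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sample, table in tables.items():
            write_coverage_file(table, out_dir / f"{sample}.cov.tsv")
        genes[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
            out_dir / "genes.bed", sep="\t", header=False, index=False)
        truth.to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
    return tables, truth


def simulate_dataset(cfg: SimConfig, out_dir: str | Path | None = None,
                     seed: int | None = None):
    """Convenience wrapper: genome + counts in one call.

    Returns ``(genes, sites, tables, truth)``; ``seed`` overrides
    ``cfg.seed`` when given.
    """
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    genes, sites = generate_genome(cfg)
    tables, truth = generate_counts(cfg, genes, sites, out_dir=out_dir)
    return genes, sites, tables, truth
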