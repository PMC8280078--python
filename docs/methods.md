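# Methods

## Statistical model

Each tile t in one two-group contrast is modelled with a binomial logistic
regression over its per-sample observations: sample i contributes
(m_i, n_i) — methylated and total reads summed over the tile's CpGs — and

    logit(π_i) = β₀ + β₁·g_i,    m_i ~ Binomial(n_i, π_i),

with g_i = 0 for the control group and 1 for the experimental group. With a
single group indicator the MLE is available in closed form: the fitted
proportions are the pooled group proportions p̂_c = Σm_c/Σn_c and
p̂_e = Σm_e/Σn_e, and β̂₁ = logit(p̂_e) − logit(p̂_c). The likelihood-ratio
statistic against β₁ = 0 therefore reduces to the 2×2 likelihood-ratio
(G) chi-square on the pooled table and is computed directly, without
iterative fitting; the unit tests verify agreement with an iteratively fitted
per-sample binomial GLM to ~1e−13 relative in the p-value. The statistic is
referred to χ²(1).

Reported effect size is the pooled methylation difference
100·(p̂_e − p̂_c) (the control group is the reference: positive =
hypermethylation). Degenerate tiles with both groups entirely unmethylated
or entirely methylated carry no information and return p = 1, log OR = 0;
otherwise the log odds ratio is computed from proportions clamped to
[1e−8, 1−1e−8], which caps |log OR| at ≈ 36.8 on separated tiles (the
p-value itself needs no cap — the likelihood is bounded).

The model is purely binomial: between-replicate (biological) overdispersion
is *not* absorbed, so p-values are anti-conservative in proportion to the
extra-binomial variance (see "Synthetic data" below for how much). This is a
deliberate scope decision — beta-binomial regression and overdispersion-
corrected F-tests are out of scope — and the null-calibration test quantifies
the consequence under the default simulation conditions.

### Multiple testing: SLIM q-values

π₀ (the proportion of true nulls) is estimated with a sliding-linear-model
fit: the ECDF of the p-values is regressed on λ in 10 equal windows covering
[0.1, 1]; each window's OLS slope estimates the null density (≈ π₀) under
the assumption that non-null mass above the window start is negligible.
Candidate estimates — quantiles (0.01…0.99) of the 10 window slopes, capped
at 1 — are screened in increasing order by a consistency rule: a candidate
π₀ implies a maximum FDR at the raw cutoff P_z = 0.05,
maxFDR = π₀·P_z / (1 − (1 − P_z)·π₀), and the first candidate whose
discovery count at q < maxFDR does not exceed the raw count of p < P_z is
accepted (median slope as fallback). Degenerate outcomes (π₀ ≤ 0,
non-finite) fall back to π₀ = 1. Q-values are then the π₀-scaled step-up
adjustment q_(i) = min_{j≥i} π₀·p_(j)·m/j, clipped to [0, 1]; π₀ = 1
reproduces Benjamini–Hochberg exactly, and the adjustment is order-preserving
by construction. On 10,000 uniform p-values the estimator returns
π₀ ≈ 0.94–0.97 (slightly liberal, as any upper-tail slope estimator is);
with planted signal it drops well below 1.

### Calling and reversal classification

A tile is hyper(hypo)methylated when q < 0.1 and meth_diff > 5 (< −5); both
inequalities are strict. The 0.1 threshold is deliberately permissive
(exploratory screening); tiles with q < 1e−7 are flagged robust. The injury
and treatment contrast tables are intersected on exact (chrom, start, end)
keys — both must come from the same tiling parameters, and a table pair with
zero exact matches but many partial interval overlaps raises an error rather
than silently pairing nothing. Tiles DM in both contrasts are classified by
the sign rule (opposite status = reversal, same status = no reversal), which
is exhaustive under exact matching; percentages are reported per class over
the paired tiles, and a gene counts in a class if any of its tiles does.
Gene-level effect sizes are the arithmetic mean of a gene's DM tile
differences per contrast, with the standard error across tiles when a gene
has ≥ 2 tiles. Reversal requires opposite sign only, not magnitude parity:
the overlap step has already enforced |diff| > 5% in both contrasts.

### Enrichment

Over-representation of a curated set among hit genes (DM or reversing) is
the exact upper-tail hypergeometric probability P(X ≥ k), computed by
explicit summation of pmf terms; the population is the set of unique genes
with ≥ 1 analyzable promoter tile, so the test conditions on what was
measurable. Gene-set members outside the population are dropped (and
counted) before testing; matching is exact and case-sensitive. Only
enrichment (upper tail) is tested. Across several sets, BH q-values are
added.

## Preprocessing choices

Filter order is depth filter → blacklist → median normalization → tiling →
promoter restriction (the common filter-then-normalize convention of
tile-based DM tools). Depth filtering requires ≥ min_depth (default 10)
reads in *every* sample, boundary inclusive; a missing site in one sample is
coverage 0, never imputed, and is therefore removed by the depth filter.
Normalization scales each sample's coverage by (median of per-sample median
coverages)/(sample median), rounding half away from zero with a floor of 1
for covered sites; methylated counts are rescaled to preserve each site's
methylation proportion and clamped to coverage — counts must stay integral
for the count-based test. Tiling windows are anchored at position 0 of each
chromosome (multiples of the 125 bp step), so a CpG belongs to at most
⌈250/125⌉ = 2 windows; a window becomes a tile with ≥ min_cpgs_per_tile
member CpGs (default 1, exposed in config). Promoters are TSS −2000/+200
(strand-aware, end-inclusive); promoter restriction is tile-level interval
overlap, keeping all overlapping gene symbols — equivalent to a CpG-level
promoter filter when effects are promoter-local, and simpler to reason
about.

## Synthetic data

The generator emulates the study conditions, not real capture data. One
synthetic chromosome holds `n_genes` equally spaced gene slots; each slot
carries a stranded TSS whose promoter window spans a fixed 2201 bp region,
inside which CpGs are placed at exponential spacing (mean 40 bp, roughly
CpG-island-like: ~6 CpGs per 250 bp tile). Effects are planted per
non-overlapping 250 bp block — every CpG in a block shares its group-level
mean — because the tile is the downstream inference unit.

Group means per block: both Sham groups share a Beta(2, 2) baseline clipped
to [0.2, 0.8] (room to plant ±25% shifts with rare boundary clamping); a
fraction `frac_injury_tiles` (default 0.3) of blocks receives a signed
injury effect in SNI-Vehicle, uniform in ±[10, 25]% and positive with
probability 0.6 (the observed hyper:hypo imbalance of the motivating study);
of the injury blocks, `reversal_fraction` (default 0.927, the study's
reversing share) have the SNI-SAM mean crossing back past the Sham baseline
by 10–40% of the injury magnitude, while the rest continue in the injury
direction by 80–120% of it — the continuation magnitude is kept comparable
to the reversal magnitude so that detection power is similar in both classes
and the recovered reversing percentage is not selection-biased. Means pushed
outside (0, 1) are clamped to [0.01, 0.99] and flagged in the ground truth.

Coverage is negative binomial with mean 30 and size 20 (variance
μ + μ²/20 ≈ 75 at the default mean — typical capture-bisulfite depth, and
deep enough that the ≥10-in-every-sample depth filter retains most sites),
scaled per sample by log-normal (σ = 0.2) depth multipliers normalized to
mean 1 — relative library-size differences remain, so the normalization
stage has real work to do. Methylated counts are beta-binomial per CpG per
sample around the block's group mean with intra-CpG correlation ρ
(`meth_overdispersion`, default 0.02).

The ρ default matters for calibration: a binomial test under beta-binomial
counts has its chi-square statistic inflated by ≈ 1 + ρ·E[c(c−1)]/E[c]
(c = coverage). At the default coverage law E[c(c−1)]/E[c] ≈ 31, so
ρ = 0.02 gives a ≈ 1.6× inflation and an empirical q < 0.1 null rate of
~2–4%, while ρ = 0.05 would give ≈ 2.6× and a null rate near 13% — beyond
what we consider a usable null testbed for this test. The default therefore
models *mild* biological overdispersion; larger values are legitimate stress
settings, with the explicit expectation that the binomial test is then
anti-conservative. This is also what passing tests do and do not show about
real data: real bisulfite replicates can be far more overdispersed than the
default, in which case the pipeline's q-values screen rather than control
FDR — exactly why the motivating analysis is exploratory (q < 0.1). Other
real-data features the generator does not emulate: non-uniform CpG density
and capture efficiency, bisulfite conversion error, correlated methylation
between neighbouring tiles beyond shared CpGs, chromosome structure, and
read-level artefacts.

Randomness is keyed hierarchically: one stream per (seed, purpose) for the
genome, effects and multipliers, and one per (seed, sample, chromosome) for
counts, so identical configurations yield byte-identical output files and
samples can be regenerated independently.

## Numerical and design notes

* Coordinates are 0-based half-open internally; 1-based Bismark input/output
  converts only at the format boundary. Bismark coverage is the sole count
  input dialect (minimal standard output of the upstream caller); strand
  collapsing of symmetric CpGs is assumed done upstream.
* Ties and degenerate inputs: empty p-value vectors adjust to empty; all
  p = 1 yields all q = 1; zero-total groups are hard errors (the depth
  filter prevents them in the pipeline); an empty depth-filtered table is a
  warning, not an error.
* The `unclear` reversal class is reserved for the optional non-exact
  (interval-overlap) matching mode when partially overlapping tiles
  disagree; under default exact matching the sign rule is exhaustive and no
  tile is unclear. The motivating study reports a small unclear fraction
  without defining its criterion, so this package does not attempt to
  reproduce that rule — percentages over externally supplied class tallies
  (including an unclear count) are supported by the bookkeeping function.
* Problem sizes used in the shipped tests and the acceptance script — ~5.6k
  promoter tiles for null calibration, ~2.4k planted injury blocks for
  reversing-fraction recovery — were chosen as the smallest sizes at which
  the binomial sampling error of the measured rates is well inside the
  asserted bounds; each run takes a few seconds.

## Known limitations

No covariates, paired designs, or beta-binomial regression; no CpG-level
(untiled) testing; enhancer regions are ignored by design (promoter-only
restriction); gene-symbol matching has no homology conversion; the SLIM π₀
estimator is this package's implementation of the sliding-linear-model idea
and is liberal by a few percent under a pure null (its q-values are still
conservative relative to BH only when π₀ < 1 is genuine).
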