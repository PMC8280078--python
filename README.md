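# methrev

Promoter-tile differential methylation and treatment-reversal analysis for
bisulfite capture sequencing.

`methrev` is built for studies that ask whether an intervention *reverses* a
disease-induced DNA methylation signature. The motivating design is a mouse
neuropathic-pain experiment with four groups — Sham-Vehicle (n=3), Sham-SAM
(n=3), SNI-Vehicle (n=4), SNI-SAM (n=4), where SNI is spared nerve injury and
SAM is the methyl donor S-adenosyl methionine — but the pipeline applies to
any design with an *injury* contrast (condition vs control) and a *treatment*
contrast (treated-condition vs untreated-condition).

## What it computes

Starting from per-sample CpG methylation counts in Bismark coverage format
(`chrom  start  end  meth%  count_methylated  count_unmethylated`, 1-based),
the pipeline:

1. **Filters** CpGs to a minimum depth of 10 reads *in every sample* and
   removes sites in a user-supplied blacklist BED.
2. **Normalizes** per-sample coverage by median scaling factors
   (s_i = median-of-medians / sample median), preserving per-site methylation
   proportions.
3. **Tiles** the genome in 250 bp windows advancing in 125 bp steps, summing
   methylated/total counts per sample, and keeps tiles overlapping a promoter
   (TSS −2000 bp to +200 bp, strand-aware) of a user-supplied gene table.
4. **Tests** each tile per contrast with a binomial logistic regression
   logit(π_i) = β₀ + β₁·group_i over per-sample counts; the likelihood-ratio
   statistic vs χ²(1) gives the p-value, β̂₁ the log odds ratio, and the
   pooled difference (experimental − control, control as reference) the
   methylation difference. P-values become q-values by a sliding-linear-model
   (SLIM) π₀-scaled FDR adjustment (plain BH available). A tile is
   **hyper**/**hypo**methylated when q < 0.1 and meth_diff > +5% / < −5%
   (strict), and **robust** when additionally q < 1e−7.
5. **Overlaps** the injury and treatment contrast tables on exact tile
   coordinates and classifies each tile DM in both as
   *reversal_of_hypermethylation* (injury hyper → treatment hypo),
   *reversal_of_hypomethylation* (injury hypo → treatment hyper) or
   *no_reversal*, with per-class counts, percentages and unique gene counts,
   plus per-gene mean methylation differences (± SE over tiles).
6. **Tests enrichment** of curated gene sets (e.g. pain-related genes) among
   DM or reversing genes with an exact upper-tail hypergeometric test,
   conditioned on the genes the pipeline could actually evaluate.

A seeded synthetic-data module generates a toy genome and four-group
beta-binomial bisulfite counts with planted tile-level injury effects and a
configurable reversing fraction, in exactly the formats the pipeline reads —
so the whole chain is testable end to end with known ground truth.

## Worked example

```sh
methrev simulate --out-dir demo --seed 5
methrev run --config demo/run_config.yaml
```

prints the per-stage record counts of the run:

```
{
  "cpgs_raw": 5435,
  "cpgs_depth_filtered": 5007,
  "cpgs_blacklist_filtered": 5007,
  "tiles": 1885,
  "promoter_tiles": 1885,
  "dm_tiles_injury": 782,
  "dm_tiles_treatment": 788,
  "paired_dm_tiles": 618
}
```

Reading: the simulated dataset has 5435 CpGs, of which 5007 are covered by
≥10 reads in all 14 samples; they form 1885 promoter tiles. 782 tiles are
differentially methylated in the injury contrast, 788 in the treatment
contrast, and 618 in both; `demo/results/reversal_summary.json` then reports
how those 618 split into reversal classes, and `demo/results/` holds the tile
(`tiles.tsv`), per-contrast (`contrast_*.tsv`), reversal (`reversal.tsv`,
`gene_summary.tsv`) and manifest outputs. `methrev volcano` converts a
contrast table into a plotting table with the usual volcano categories, e.g.
for the injury contrast above:

```
not_different                959
hyper                        462
hypo                         320
nonsignificant_large_diff     99
significant_small_diff       45
```

Column dictionaries: contrast tables carry `chrom,start,end,genes,n_cpgs,
meth_diff,log_odds_ratio,p_value,q_value,status,robust`; reversal tables the
paired per-contrast columns plus `reversal_class`; enrichment tables
`condition,name,N,K,n,k,p_value,q_value,n_dropped`.

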