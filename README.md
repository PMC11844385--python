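# sortscreen

Analysis pipeline for pooled CRISPRi screens read out by
fluorescence-activated sorting, and for their CROP-seq follow-ups. The
motivating application is a screen for modifiers of neuronal
excitability: iPSC-derived neurons expressing the calcium integrator
CaMPARI2 are photoconverted in proportion to activity, sorted into the
top and bottom 35% of the red/green ratio distribution, and the sgRNA
cassette is sequenced from each bin. sortscreen covers everything
between raw reads and hit lists, plus the single-cell follow-up
statistics:

- **counting** — protospacer extraction from FASTQ and per-sample
  library counts with mapping statistics and rank-order QC;
- **screen** — hit calling with a non-targeting-control (NTC) empirical
  null: per-sgRNA log2 fold change between bins, per-gene Mann-Whitney
  U against pooled NTC sgRNAs, and *quasi-genes* (k NTC sgRNAs sampled
  with replacement, scored like real genes) to calibrate an empirical
  false-discovery-rate cutoff;
- **flow** — per-event red/green CaMPARI ratios, well means, and
  normalization to no-sgRNA reference wells;
- **assign** — CROP-seq per-cell guide assignment by hypergeometric
  test, log2 odds ratio, and a UMI floor, yielding the MOI-1 cell set;
- **qc** — single-cell QC gates, target-sum log normalization, and raw
  pseudobulk aggregation for external DE engines;
- **cshift** — cluster-occupancy-shift chi-square statistics per
  (knockdown, cluster) against each NTC group, geometric-mean
  aggregation, BH correction;
- **simulate** — seeded generators for every input above, with ground
  truth, used by the test-suite to verify calibration and power.

## The core statistic

For gene *g* with member sgRNA fold changes
`lfc_i = log2(cpm_high,i / cpm_low,i)` and the pooled NTC fold changes
as reference, the two-sided Mann-Whitney p-value `p_g` and the mean
member fold change `LFC_g` combine into

```
GeneScore_g = LFC_g × (−log10 p_g)
```

Quasi-genes traverse the identical path, so for any threshold *t*

```
FDR(t) = ( #quasi p ≤ t / #quasi ) / ( #real p ≤ t / #real )
```

estimates the false-discovery rate without distributional assumptions;
hits are the real genes at or below the largest *t* whose (monotonized)
estimate stays within the target level (default 10%), with direction
given by the sign of `LFC_g`.

## Worked example

Simulate a small screen (40 genes × 5 sgRNAs + 40 NTCs, 10% of genes
with a ±2-SD latent effect) and call hits:

```sh
sortscreen simulate screen --n-genes 40 --n-ntc 40 \
    --cells-per-sgrna 50 --reads-per-bin 100000 --seed 11 --outdir sim
sortscreen screen call-hits --counts sim/counts.tsv \
    --library sim/library.tsv --seed 1 --outdir hits
```

which prints

```
4 hits at empirical FDR 0.1 (p cutoff 0.00032624345759000727)
```

`hits/gene_results.tsv` then holds one row per real gene and quasi-gene;
the four hits are exactly the four planted effect genes recorded in
`sim/truth_effects.tsv`:

```
 gene  lfc_gene  p_value  gene_score  is_quasi hit_direction
G0004  6.198119 0.000326   21.609484     False      increase
G0019 -8.270824 0.000326  -28.835881     False      decrease
G0023  7.979627 0.000326   27.820637     False      increase
G0030 -8.266012 0.000326  -28.819104     False      decrease
```

A positive `lfc_gene` means the knockdown enriches in the high-activity
bin (increased excitability); `gene_score` is the signed ranking
statistic above; the cutoff is the largest p whose quasi-gene-estimated
FDR stays at or below 10%. (At this toy depth a ±2-SD effect nearly
empties one bin, so the fold changes are extreme and the Mann-Whitney
p saturates at the complete-separation value for all four genes.) The same library/counts formats work for
real data: a TSV library (id, protospacer, gene) and a TSV count matrix
(elements × samples), produced from FASTQ by `sortscreen count`.

## Layout

```
src/sortscreen/    library, counting, screen, flow, assign, qc, cshift,
                   simulate, cli
tests/             pytest suite (unit, property, calibration checks)
docs/methods.md    models, assumptions, parameter choices, limitations
scripts/           acceptance.py
```
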