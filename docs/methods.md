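# Methods

This note documents the statistical procedures sortscreen implements, the
assumptions behind them, the parameters that matter, and what the
synthetic-data generators do and do not emulate.

## Sorted-bin screen hit calling (`sortscreen.screen`)

### Model and procedure

A pooled CRISPRi screen with a fluorescence-activated sort produces two
sequenced populations: cells in the top and bottom tails of a continuous
per-cell phenotype (here, the CaMPARI red/green photoconversion ratio, a
readout of integrated neuronal activity). A guide that shifts the
phenotype changes its representation in the two tails, so the per-sgRNA
log2 fold change between bins is the elementary effect measurement.

The stages are:

1. **Normalization.** Counts-per-million with a pseudocount:
   `cpm = (c + pc) / Σ(c + pc) × 10⁶` per sample, `pc = 1` by default.
   CPM makes fold changes invariant to sequencing depth; the pseudocount
   keeps log fold changes finite for dropout guides.
2. **sgRNA phenotype.** `lfc = log2(cpm_high / cpm_low)` per guide,
   including non-targeting controls (NTCs).
3. **Gene test.** For each gene, a two-sided Mann-Whitney U test of its
   member sgRNA LFCs against the pooled NTC sgRNA LFCs; the gene-level
   LFC is the mean of member LFCs (median available by option), and the
   ranking statistic is `gene_score = lfc_gene × (−log10 p)`.
4. **Quasi-genes.** Pseudo-genes are built by sampling k = 5 NTC sgRNA
   ids uniformly **with replacement** and scored through the identical
   path. Because their members are genuinely inert, their score
   distribution is an empirical null for the whole pipeline — including
   any artifacts of normalization, the test, or count noise.
5. **Empirical FDR.** For a p threshold t,
   `FDR(t) = [#quasi p ≤ t / #quasi] / [#real p ≤ t / #real]`.
   The curve is monotonized by the running minimum over thresholds ≥ t
   (so hit sets are nested in the target level), and the cutoff is the
   largest observed real p with monotonized FDR ≤ α (default α = 0.10).
   Hit direction is the sign of the gene-level LFC; a single cutoff
   spans both directions.

### Mann-Whitney implementation

U is computed from midranks (½ credit per tied pair). The exact null
distribution of U is computed by the standard counting recurrence
N(u; n, m) = N(u−m; n−1, m) + N(u; n, m−1) and is used when
n + m ≤ 25 and the pooled sample is tie-free; the two-sided p is twice
the smaller tail, clipped at 1. Otherwise a tie-corrected normal
approximation with continuity correction is used. The exact path is
verified in the test-suite against brute-force enumeration of all
C(n+m, n) labelings for every size pair with n + m ≤ 10, and against an
independent library implementation.

### Choice of the quasi-gene family size

The number of quasi-genes is a pure precision parameter: the numerator
of the FDR estimate is a quasi discovery *fraction*, so the estimate is
unbiased at any family size, but its noise scales as the inverse square
root of the family size. Because the hit cutoff is chosen to maximize
hits subject to the estimated FDR, noise in the estimate converts into
an upward bias of the *realized* false-discovery proportion (a selection
effect: thresholds where the quasi count is favorably low by chance are
preferred). The default is therefore a family substantially larger than
the gene set (`n_quasi = 10 × n_genes`, with k = 5 members each), which
makes the quasi discovery count at a typical cutoff large enough for
the selection bias to be negligible while costing only seconds of
compute. A family equal in size to the gene set is available by option
and reproduces the noisier behavior.

### Assumptions and limitations

- Guides are assumed independent; clonal or positional effects are not
  modeled.
- The pooled-NTC reference assumes NTC sgRNA LFCs are exchangeable with
  null targeting sgRNAs. Off-target depletion of targeting guides (e.g.
  essentiality) would violate this and is not corrected.
- The test compares each gene to pooled NTC sgRNAs; comparing to the
  quasi-gene score distribution instead is a supported variant, but the
  pooled comparison is the default because it uses the raw measurement
  unit (sgRNA LFCs) on both sides.

## Synthetic screen generator (`sortscreen.simulate.simulate_screen`)

The generator encodes the study conditions used throughout the tests:
500 genes × 5 sgRNAs plus 250 NTCs; 10% of genes carry a latent effect
of ±2 in units of the noise SD (alternating sign); 300 cells per sgRNA;
gates collecting the top and bottom 35% of cells; 5,000,000 reads per
bin drawn as a single multinomial over the bin's sgRNA cell tallies.

Mechanism: each cell's latent phenotype is `β(gene) + Normal(0, σ)`;
cells are ranked and the exact top/bottom `round(0.35 × n)` cells are
collected — mirroring a sorter gated on fixed percentiles of the live
distribution, so bin sizes are exact, not binomial. Sequencing is
multinomial (no PCR amplification bias); a Dirichlet-multinomial
overdispersion option exists to stress FDR calibration.

What it does **not** emulate: guide-to-guide knockdown heterogeneity
(all sgRNAs of a gene share β; real "top-two guide" selection exploits
real heterogeneity), cell-cycle or viability covariates, PCR jackpots,
index hopping, or day-to-day sort drift. Passing calibration tests on
this generator therefore demonstrates correctness of the statistics
under the stated model, not robustness to those artifacts.

## Read counting (`sortscreen.counting`)

Protospacers are cropped from reads either by fixed slice (offset +
length) or by searching for a constant anchor sequence (first occurrence
wins) — the amplicon structure is fully configurable because vector
layouts differ between libraries. Matching against the library is exact,
or optionally tolerates one substitution (Hamming distance only — the
amplicons are fixed-length, so indels are not expected) with a
unique-best-match rule: a read within distance 1 of two library elements
is discarded as unmapped. Reverse-complement scanning is off by default
and available by flag. The conservation `mapped + unmapped = total` is
enforced structurally.

## Guide assignment (`sortscreen.assign`)

Each cell is assigned to its majority guide when all three default
gates pass: BH-adjusted hypergeometric upper-tail p < 0.05, log2 odds
ratio between top and second counts > 1, and total UMIs > 5 (strict, so
a 5-UMI cell is never assignable). The hypergeometric margins are:
population = grand-total UMIs in the experiment, successes = the top
guide's column total, draws = the cell's total. This asks whether the
cell's concentration on the guide is surprising given the guide's
overall abundance — the natural reading when ambient molecules mirror
library composition. BH runs across cells (one test per cell, its top
guide); within-cell correction across guides is the noted alternative.
With a zero second count the log-odds is +∞, so clean single-guide
cells pass the odds gate by construction. Ties for the top count are
never assigned (deterministic, no RNG).

## Cell QC and pseudobulk (`sortscreen.qc`)

Defaults: total counts ≥ 2000, detected genes ≥ 100, ribosomal content
strictly between 3% and 8%, mitochondrial content strictly below 6.5%.
The ribosomal window is an *open* interval and the mitochondrial bound
*strict*; cells sitting exactly on a boundary are removed. Boundary
semantics are unit-tested and every threshold is configurable. Mito/ribo
genes are identified by symbol prefix (`MT-`; `RPS`/`RPL`), also
configurable since annotation conventions vary.

Normalization scales each cell to a target sum of 1000 followed by
log1p, delegated to scanpy's standard implementation. Pseudobulk
aggregation sums **raw** counts per (knockdown, GEM library) group —
count-model DE engines (e.g. DESeq2/edgeR) require untransformed counts
— and is implemented as a sparse indicator-matrix product, verified
against brute-force group sums.

## Cluster occupancy shifts (`sortscreen.cshift`)

For each knockdown group and cluster, a 2×2 Pearson chi-square
(in-cluster vs out-of-cluster; no Yates correction, flag available)
is computed against every NTC group separately; per-NTC p-values are
combined by geometric mean; BH runs across all (knockdown, cluster)
pairs; significance is q < 0.05. A zero row or column margin carries no
information and returns p = 1 by convention. Effect size is
`100 × (f_kd − f_ntc) / f_ntc` with the pooled, size-weighted NTC
occupancy as reference.

Per-cluster 2×2 tests (rather than one K-cluster homogeneity test per
knockdown) give a verdict per cluster at the cost of dependence between
a group's tests. The geometric mean is a heuristic combination — it is
not a calibrated p-value — so the null behavior is established
empirically: on fully null simulations the significant-pair fraction at
q < 0.05 stays well below 0.05 (the aggregation is conservative). That
empirical check, run in the test-suite over 100 seeded replicates, is
the contract.

## Flow ratios (`sortscreen.flow`)

Per-event ratio is red/green; events with nonpositive green are excluded
and counted rather than pseudocounted. Well summaries are arithmetic
means over ratioable events; normalization divides by the event-weighted
pooled mean of designated reference wells, making the pooled reference
exactly 1 and the statistic invariant to global intensity rescaling. The
marker gate is a fixed threshold (≥ positive), not a mixture model.

## Numerical and reproducibility choices

- p-values are floored at 1e-300 so −log10 p is finite.
- The hypergeometric tail is evaluated through the log survival
  function; exactness to ~1e-14 relative against direct PMF summation
  is verified for all populations ≤ 30.
- All random draws flow through `numpy.random.default_rng` with
  explicit seeds; every CLI run writes a manifest (config echo, seed,
  package version, input SHA-256 checksums) and identical config + seed
  reproduces byte-identical outputs.
- Problem sizes in the test-suite (e.g. 50 screen replicates at the
  full study scale, 100 null replicates for the occupancy-shift
  calibration) were chosen so the whole suite completes in a few
  minutes on one core while keeping Monte-Carlo error well inside the
  asserted tolerances.

## Known limitations

- The counting stage has no quality trimming and no indel tolerance.
- The empirical-FDR machinery assumes enough NTCs (hundreds) that
  quasi-gene resampling explores a rich null; with very few NTCs the
  FDR curve becomes granular and the cutoff unstable.
- The occupancy-shift chi-squares treat cells as independent; they are
  not adjusted for overdispersion between GEM libraries.
- Flow summaries operate on CSV event tables; FCS binary parsing and
  spectral compensation are out of scope.
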