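# Methods

## Statistics

**SNP-index.** Per site and pool, `alt_depth / (alt_depth + ref_depth)`;
undefined (NaN) at zero depth. Indices are derived properties of the stored
depths, so records can never carry inconsistent values.

**Δ and |Δ|.** `delta = index_A − index_B` per site; `abs_delta = |delta|`.
Missing propagates. Pool orientation (which pool is A) is configuration and is
echoed into every report, because with a non-parental reference the sign of Δ
carries no parental-origin information: a reference that switches haplotype
state flips the sign of Δ at every site where the relevant parent is
heterozygous, segment-wise along the genome. Window means of Δ therefore cancel
toward zero over regions containing switch boundaries, while window means of
|Δ| are invariant to them. This is the entire case for |Δ| in heterozygous
material, and it is what the simulator's mosaic mode reproduces.

**Windows.** Fixed width (default 200 kb) advanced by a fixed step (default
20 kb), 1-based inclusive, truncated (never dropped) at scaffold ends. Each
window averages the per-site values of all variants inside its span; a variant
contributes to every overlapping window. `mean_delta` and `mean_abs_delta`
average over the same site set, so `mean_abs_delta ≥ |mean_delta|` is an
invariant (checked in tests). Windows with fewer than `min_snps` variants
(default 1) report all statistics missing. Means are computed as exact
per-window slice sums, not running differences, so they agree with a
brute-force rescan to machine precision.

**Thresholds.** Empirical quantiles of the non-missing window statistic with
linear interpolation (`numpy.quantile`): the top 0.5 % for |Δ|, and a symmetric
top/bottom 0.25 % pair for signed Δ. Quantiles are taken over windows, not raw
SNPs (a per-SNP variant can be had by windowing at `window_size == step == 1`).
Flagging is strict (`>` upper, `<` lower); a degenerate constant distribution
flags nothing. Realized threshold values are data-dependent outputs, never
constants.

**Intervals.** Flagged windows merge when overlapping or abutting, so interval
boundaries land on the window grid (…0001/…0000). The sparsity filter drops
intervals with fewer than `min_snps = 10` supporting SNPs or a median
inter-SNP gap above `max_median_gap = 20 kb`; these defaults are this package's
own (the practice of pruning thin intervals is standard, the numbers are not
canonical) and every report echoes them. Two length conventions coexist in
published interval tables and both are implemented with an explicit `mode`:
*inclusive* (`end − start + 1`) for grid regions, *difference* (`end − start`)
for marker-bounded spans. Lengths are returned unrounded; display formatting
uses one decimal for kb and two for Mb, matching how such tables are printed.

## Quality filters

Defaults: drop a site when (a) either pool's total depth is below 7, (b) the
SNP-index is below 0.3 in *both* pools (uninformative in both bulks), or (c) one
pool has no index at all. Published descriptions of these filters are ambiguous
about whether the index cutoff applies per pool or jointly and which pools the
depth cutoff covers, so both rules are configuration (`index_rule`:
both/either; `depth_rule`: either/both/combined). Exactly one reason is
recorded per dropped site (missing → depth → index precedence), and filtering
is idempotent.

## Simulator

The generator states a world and sticks to it; its defaults are the conditions
of a desk-scale heterozygous fruit-tree BSA experiment:

| parameter | default | why |
|---|---|---|
| genome | 5 scaffolds × 2 Mb | toy scale; each scaffold stands in for one linkage group |
| `snp_density` | 0.0045 /bp | ≈ 4.5 SNP/kb, the density implied by ~2.3 M SNPs on a ~512-Mb pome-fruit assembly |
| `parent_heterozygosity` | 0.5 | highly heterozygous outcrossing parents |
| `recombination_rate` | 45 cM/Mb | ~90 cM per 2-Mb scaffold: genetic length of a real linkage group (1500–2000 cM map over ~17–20 groups) preserved under physical down-scaling |
| `cross_type` | Rr × rr | single dominant trait allele, 1:1 segregation |
| `n_offspring`, pools | 120; (28, 27) | pools of 28 red + 27 green drawn from a larger F1 population |
| `mean_depth` | 20× | ~20× per pool |
| `sequencing_error` | 0.005 | post-QC Illumina per-base error |
| `reference_mode` | mosaic | the heterozygous-reference scenario |
| `mosaic_switch_rate` | 5 /Mb | reference switches haplotype state about once per window |
| `penetrance` | 1.0 | knob for phenotype misclassification / segregation distortion |

Mechanics: SNP positions are unique uniform draws (collisions at these
densities are negligible, so realized density is approximate); sites
monomorphic across all four parental haplotypes are discarded. Meiosis draws a
Poisson number of crossovers per gamete with mean equal to the scaffold's
genetic length in Morgans, uniformly placed — no interference, no obligate
chiasma. Pools take the first n red / n green offspring. Reads are
depth ~ Poisson(mean_depth) and alt ~ Binomial(depth, f(1−e) + (1−f)e); there
is no overdispersion term (a future config hook). In mosaic mode the reference
is parent 1's two haplotypes alternating at Poisson breakpoints; in parental
mode it is parent 1 haplotype 1 throughout. All randomness flows through one
`numpy.random.Generator`, so a seed fixes the dataset bit-for-bit.

**What the simulator does not emulate:** alignment artifacts and mapping bias,
indel/SV realism, LD structure beyond a single meiosis, overdispersed coverage,
GC effects, a reference carrying alleles absent from both parents, and
gene-level annotation. A green simulation test therefore establishes the
*statistical* behavior of the method under the stated genetic model, not
robustness to bioinformatic artifacts upstream of the variant table.

### Recombination scaling (a deliberate choice)

Using the genome-wide average cM/Mb of a real ~500-Mb genome (~3.5) on a 2-Mb
toy scaffold yields a 7-cM chromosome — effectively crossover-free meiosis in
which the trait signal saturates the entire scaffold and no window method can
localize anything. Scaled-down chromosomes must conserve *genetic* length, not
cM/Mb: the default 45 cM/Mb gives ~0.9 Morgans per scaffold, the genetic length
of a real linkage group, and restores the decay of pool allele-frequency
contrast with distance from the trait locus that windowed BSA relies on.

## Detection-power experiment

`power_experiment` reruns the full pipeline (filters → windows → thresholds →
intervals, including the sparsity filter) per replicate with per-replicate seeds
derived from the config seed, and scores a method as detecting when any called
interval covers the true locus position. Rates come with Clopper–Pearson
intervals; the paired signed-vs-absolute comparison is an exact McNemar sign
test on discordant replicates. At the default toy scale, 50 replicates of the
mosaic scenario give |Δ| ≈ 0.98 vs Δ ≈ 0.82 detection (one-sided p ≈ 0.01),
while under a parental reference the two are statistically indistinguishable.

### Known limitation: candidate width is not depth-limited here

Because the threshold is a quantile, the expected number of flagged windows is
fixed (0.5 % of ~500 windows ≈ 2–3), so total candidate width can shrink with
coverage only through flags concentrating and merging near the locus. That
concentration saturates by ~8× coverage; above it, flag placement is dominated
by pool-composition sampling noise (28 + 27 offspring), which read depth cannot
reduce. Measured mean candidate widths are flat (~250–260 kb) from 8× to 80×,
and below ~8× the depth filter removes the data wholesale. Expect depth to buy
*detectability* at low coverage, not interval resolution at these pool sizes;
narrower intervals require larger pools or denser recombination, not more reads.

## Numerical and degenerate-case choices

- Missing values are `float('nan')` everywhere; they never enter means,
  quantiles or flags.
- Multi-allelic VCF sites keep the alt allele with the most reads summed over
  both pools (logged); indels flow through the same index arithmetic.
- Unsorted variant input to window statistics is an error, not silently sorted;
  `read_variants` sorts its output by (scaffold, position).
- Tied/constant window statistics: strict flagging means "all equal" flags
  nothing rather than everything.
- Empty inputs raise `EmptyInputError` distinctly from malformed data
  (`DataError`) and misconfiguration (`ConfigurationError`).
- Pipeline reports are byte-identical across reruns of the same config; the
  run log (timestamped) is the only exception, and partial outputs are removed
  if a run fails.
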