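# bulkseg

Bulked-segregant (QTL-seq) trait mapping for crosses between **heterozygous**
parents, built around the sign-free **|Δ(SNP-index)|** window statistic, plus a
pooled-sequencing simulator that reproduces the reference-mosaic
"pseudoexchange" effect that motivates it.

## The problem

QTL-seq locates a trait locus by whole-genome sequencing of two DNA pools of
offspring with opposite phenotypes. At each SNP, the *SNP-index* of a pool is
the fraction of reads carrying the non-reference allele (0 = all reads match
the reference, 1 = all differ), and

    Δ(SNP-index) = index_A − index_B

is averaged in sliding windows (here 200 kb advanced by 20 kb). With inbred
parents the reference is one parental genome, the sign of Δ encodes parental
origin, and a trait locus appears as a window where Δ departs from 0.

With heterozygous parents (fruit trees, most outcrossing crops) the reference
genome is a third, itself-heterozygous cultivar: along a chromosome it switches
between haplotype states. Each switch flips which allele is "non-reference",
flipping the sign of Δ at random boundaries — the *pseudoexchange effect*.
Windowed signed Δ then cancels toward 0 and misses parts of the trait region.
Taking the absolute value per site,

    |Δ(SNP-index)|,

is invariant to these sign flips: windows of |Δ| keep their height over the
trait region and candidate intervals are recovered. Candidates are taken as
the top 0.5 % of |Δ| windows (for signed Δ, a symmetric top/bottom 0.25 % pair),
merged into grid-aligned intervals and pruned of intervals supported by few,
widely separated SNPs.

The simulator generates the whole experiment from a stated genetic model — a
biallelic SNP map, two phased heterozygous parents, a single dominant trait
allele (Rr × rr or Rr × Rr), Poisson-crossover meiosis, phenotype-based pooling,
and Poisson/binomial read sampling against a parental or haplotype-mosaic
reference — so every claim the package makes is testable offline.

## Worked example

`python examples/06_full_pipeline.py` simulates a default dataset
(5 × 2-Mb scaffolds, 28 + 27 offspring pooled, ~20× coverage per pool, mosaic
reference) and analyzes it end to end:

```
variants: 38,775 read, 31,532 kept
windows: 500 (3 flagged at |delta| > 0.371)
candidate intervals:
  scaffold01  [880,001 - 1,120,000]  240.0 kb  (789 SNPs)
total candidate length: 0.24 Mb
true locus scaffold01:1,000,000 covered: True
```

Reading: of 38,775 simulated SNPs, 31,532 survive the quality filters
(SNP-index ≥ 0.3 in at least one pool, depth ≥ 7 in both). The top-0.5 %
threshold on the 500 window values lands at |Δ| = 0.371; the three windows
above it merge into one 240-kb candidate interval that covers the true
simulated locus at scaffold01:1,000,000.

Other examples, one per capability: SNP-index and filters (`01`), window
statistics and thresholds (`02`), interval arithmetic in both length
conventions and cM distances (`03`), dataset bundles (`04`), and the
signed-vs-absolute detection-power comparison (`05`).

Everything is importable directly:

```python
from bulkseg import PipelineConfig, run_qtlseq, run_simulate
from bulkseg.simulate import CrossSimConfig, power_experiment
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline reference quantities — the SNP-index at a
locus where every read carries the non-reference allele and at a locus where
every read matches the reference — by calling the library at run time, and
writes them as JSON.

## Layout

- `src/bulkseg/variants.py` — pooled-variant records, VCF/table I/O, quality filters
- `src/bulkseg/windows.py` — window grid, Δ and |Δ| statistics, quantile thresholds
- `src/bulkseg/intervals.py` — interval calling, sparsity filter, length/cM arithmetic
- `src/bulkseg/simulate.py` — cross simulator and the detection-power experiment
- `src/bulkseg/pipeline.py` — end-to-end runs and report bundles
- `docs/methods.md` — model assumptions, parameter choices, known limitations
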