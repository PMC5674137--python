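"""Candidate-interval calling, sparsity filtering and length conventions.

Flagged windows merge into grid-aligned candidate intervals. Two length
conventions are used in interval reports: *inclusive* (end - start + 1, for
window-grid regions) and *difference* (end - start, for spans bounded by marker
coordinates). Genetic distances between mapped loci are plain |a - b| in cM.
"""

from bulkseg import (
    GenomicInterval,
    SparsityPolicy,
    Window,
    call_intervals,
    filter_sparse,
    format_length,
    interval_length,
    map_distance,
    total_length,
)
from bulkseg.variants import PooledVariant

# Three flagged 200-kb windows, two of them overlapping on the 20-kb grid
windows = [
    Window("sc1", 880_001, 1_080_000),
    Window("sc1", 900_001, 1_100_000),
    Window("sc2", 1, 200_000),
]
intervals = call_intervals(windows)
print("merged candidate intervals:")
for iv in intervals:
    print(f"  {iv.scaffold}  [{iv.start:,} - {iv.end:,}]  {format_length(iv, 'kb')}")
print(f"total candidate length: {format_length(total_length(intervals), 'Mb')}")

# Sparsity filter: the sc2 interval is supported by only three scattered SNPs
snps = [PooledVariant("sc1", 880_001 + 500 * i, "A", "G", 5, 5, 5, 5) for i in range(400)]
snps += [PooledVariant("sc2", p, "A", "G", 5, 5, 5, 5) for p in (10_000, 90_000, 180_000)]
result = filter_sparse(intervals, snps, SparsityPolicy())
print(f"\nafter sparsity filtering: {len(result.kept)} kept, "
      f"{len(result.dropped)} dropped ({', '.join(result.reasons)})")

# Length conventions on a marker-bounded span vs a grid region
marker_span = GenomicInterval("sc1", 3_639_340, 4_167_794)
grid_region = GenomicInterval("sc1", 3_800_001, 3_880_000)
print(f"\nmarker span  : {interval_length(marker_span, 'kb', 'difference'):.1f} kb (difference)")
print(f"grid region  : {interval_length(grid_region, 'kb', 'inclusive'):.1f} kb (inclusive)")
print(f"map distance between loci at 6.1 and 8.6 cM: {map_distance(6.1, 8.6):.1f} cM")
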