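"""Per-pool SNP-index and quality filtering on a handful of sites.

The SNP-index of a pool at a site is the fraction of its reads carrying the
non-reference allele: 0 = all reads match the reference, 1 = all differ.
Sites that are low-depth, uninformative in both pools, or covered in only one
pool are removed before any window statistic is computed.
"""

from bulkseg import FilterPolicy, PooledVariant, apply_filters, compute_snp_index

print("SNP-index examples:")
for alt, ref in [(20, 0), (0, 20), (3, 7), (0, 0)]:
    print(f"  alt={alt:>2} ref={ref:>2} -> index = {compute_snp_index(alt, ref)}")

variants = [
    PooledVariant("s1", 1_000, "A", "G", 0, 20, 10, 10),   # informative contrast
    PooledVariant("s1", 2_000, "A", "G", 18, 2, 16, 4),    # index < 0.3 in both pools
    PooledVariant("s1", 3_000, "A", "G", 10, 10, 2, 3),    # pool B depth 5 < 7
    PooledVariant("s1", 4_000, "A", "G", 10, 10, 0, 0),    # no index in pool B
]
result = apply_filters(variants, FilterPolicy())
print(f"\nFilters kept {len(result.kept)} of {len(variants)} sites; dropped:")
for v, reason in zip(result.dropped, result.reasons):
    print(f"  {v.scaffold}:{v.position}  {reason}")
print("\nA kept site is informative in at least one pool and well covered in both.")
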