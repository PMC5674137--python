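"""Simulate a pooled-sequencing dataset and write it as a reusable bundle.

The simulator models an F1 cross of two heterozygous parents with a single
dominant trait allele, pools offspring by phenotype, and sequences the pools
against either a parental reference or a haplotype-mosaic reference (the
"pseudoexchange" scenario). The bundle (VCF + truth + scaffold lengths) feeds
straight back into the analysis pipeline.
"""

import tempfile
from pathlib import Path

from bulkseg import run_simulate
from bulkseg.simulate import CrossSimConfig

config = CrossSimConfig(seed=5)  # defaults: 5 x 2-Mb scaffolds, 28+27 pools, 20x, mosaic
out_dir = Path(tempfile.mkdtemp()) / "simulated"
result = run_simulate(config, out_dir)

sim = result.sim
print(f"wrote dataset bundle to {out_dir}:")
for key, path in result.paths.items():
    print(f"  {key:<17} {path.name}")
print(f"\n{len(sim.variants):,} variant sites across {len(sim.scaffold_lengths)} scaffolds")
print(f"true locus: {sim.truth.qtl_scaffold}:{sim.truth.qtl_position:,}")
print(f"offspring phenotypes: {int(sim.truth.phenotype_red.sum())} red / "
      f"{int((~sim.truth.phenotype_red).sum())} green; "
      f"pools of {sim.truth.pool_a_members.size} + {sim.truth.pool_b_members.size}")
n_switch = sum(len(c) for c in sim.truth.reference_breakpoints.values())
print(f"mosaic reference switched haplotype state {n_switch} times genome-wide")
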