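"""End-to-end run: simulate a dataset, analyze it, inspect the report bundle.

`run_simulate` writes a VCF with two pool samples; `run_qtlseq` reads it back,
filters, computes 200-kb/20-kb windows, thresholds the top 0.5 % of |delta|
windows, and writes candidate intervals plus a JSON summary.
"""

import json
import tempfile
from pathlib import Path

from bulkseg import PipelineConfig, run_qtlseq, run_simulate
from bulkseg.simulate import CrossSimConfig

work = Path(tempfile.mkdtemp())
dataset = run_simulate(CrossSimConfig(seed=1), work / "data")

config = PipelineConfig(
    variants=dataset.paths["vcf"],
    scaffold_lengths=dataset.paths["scaffold_lengths"],
    out_dir=work / "analysis",
    pool_a="pool_red",
    pool_b="pool_green",
    statistic="abs_delta",
    upper_quantile=0.005,
    make_plots=True,
)
result = run_qtlseq(config)

summary = json.loads(result.paths["summary"].read_text())
print(f"variants: {summary['n_variants_input']:,} read, {summary['n_variants_kept']:,} kept")
print(f"windows: {summary['n_windows']} ({summary['n_windows_flagged']} flagged at "
      f"|delta| > {summary['thresholds']['upper_value']:.3f})")
print("candidate intervals:")
for iv in summary["intervals"]:
    print(f"  {iv['scaffold']}  [{iv['start']:,} - {iv['end']:,}]  "
          f"{iv['length_bp_inclusive'] / 1e3:.1f} kb  ({iv['n_snps']} SNPs)")
print(f"total candidate length: {summary['total_candidate_display']}")
truth = dataset.sim.truth
covered = any(
    iv["scaffold"] == truth.qtl_scaffold and iv["start"] <= truth.qtl_position <= iv["end"]
    for iv in summary["intervals"]
)
print(f"true locus {truth.qtl_scaffold}:{truth.qtl_position:,} covered: {covered}")
print(f"report bundle in {work / 'analysis'} (windows.tsv, intervals.bed/tsv, summary.json, plots/)")
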