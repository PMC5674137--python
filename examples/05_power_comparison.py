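"""Detection power: signed delta vs |delta| windows under a mosaic reference.

Replicates the full pipeline on simulated crosses and asks how often each
statistic's candidate intervals cover the true trait locus. Under a mosaic
(haplotype-switching) reference the signed statistic cancels within windows and
misses the locus more often; under a clean parental reference the two perform
alike. More replicates sharpen the contrast (the test suite uses 50).
"""

from dataclasses import replace

from bulkseg.simulate import CrossSimConfig, power_experiment

N_REPLICATES = 15  # keep the example quick; see tests for the full experiment

config = CrossSimConfig(seed=7)
for mode in ("mosaic", "parental"):
    result = power_experiment(replace(config, reference_mode=mode), N_REPLICATES)
    print(f"\n=== {mode} reference ===")
    print(result.summary().to_string(index=False))
    p = result.paired_pvalue("abs_delta", "delta", "greater")
    print(f"one-sided paired test (|delta| detects more): p = {p:.4f}")
print("\nDetection = a called candidate interval covers the true locus position.")
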