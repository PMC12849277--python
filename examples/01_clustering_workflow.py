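"""Cluster exposure instruments by their ratio effects on a disease outcome.

Simulates a study-shaped dataset (three variant clusters with distinct causal
effects on the outcome plus a null mass), runs the full clustering arm —
fixed-effect meta-analysis of two exposure GWAS, clumping, harmonisation,
Steiger filtering, EM mixture clustering, per-cluster IVW MR — and prints the
per-cluster results table.
"""

from mrclustmed import pipeline, synthetic_data as sd

config = sd.SimulationConfig(seed=7)
data = sd.simulate_summary_stats(config)

result = pipeline.run_part1(data.exposure, data.outcome, data.ld,
                            pipeline.RunConfig(seed=7))

print("Stage log (variants in/out at each filter):")
for line in result.stage_log:
    print(" ", line)

print("\nPer-cluster MR estimates (log-OR per exposure SD):")
print(result.cluster_table.round(3).to_string(index=False))

print(
    "\nEach substantive cluster groups variants sharing a causal ratio on the"
    "\noutcome; 'beta' is the fixed-effect IVW combination of the members'"
    "\nWald ratios, with its 95% CI. The generating means were 0.98, -0.61"
    "\nand -1.74, and the null cluster collects the no-effect variants."
)
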