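# mrclustmed

Clustered Mendelian randomisation and two-step mediation MR for heterogeneous
exposures.

## The problem

A polygenic exposure such as body mass index is not one thing: different
groups of variants raise it through different biological pathways, and those
pathways can have opposite effects on a disease. A single pooled MR estimate
then averages away real structure — one reason MR studies of adiposity and
breast cancer have disagreed for years. This package implements the two-part
analysis that resolves that heterogeneity:

1. **Clustered MR.** Each instrument j gives a Wald ratio
   θ̂_j = β̂_out,j / β̂_exp,j with SE σ_j. The ratios are modelled as a mixture
   of K substantive clusters N(μ_k, σ_j²), a null component N(0, σ_j²) and a
   heavy uniform junk component, fitted by EM with seeded restarts; K is
   chosen by BIC, and each cluster is summarised by the fixed-effect IVW
   estimate over its confident members, β̂ = Σw_jθ̂_j / Σw_j with
   w_j = σ_j⁻². Upstream, the package provides fixed-effect GWAS
   meta-analysis, greedy LD clumping, allele harmonisation (including
   palindromic resolution by allele frequency) and Steiger directionality
   filtering; downstream, cluster-specific polygenic scores give one-sample
   Wald-ratio MR in an individual-level cohort.

2. **Two-step mediation MR.** Step 1 estimates each cluster's effect on every
   protein in a molecular panel (cluster score as instrument, two disjoint
   sub-samples of one cohort); step 2 estimates each protein's effect on the
   outcome by IVW over its cis/trans instruments (p < 1.7×10⁻¹¹, ≥3
   independent variants, ≥1 cis), with MR-Egger and Cochran's Q diagnostics.
   After double FDR screening, the mediated effect is the product of
   coefficients β̂₁β̂₂ with delta-method SE √(β̂₁²σ₂² + β̂₂²σ₁²), a Monte Carlo
   CI from normal resamples of both factors, and the proportion mediated
   β̂₁β̂₂ / β̂_total. Between-cluster contrasts use
   β̂_diff = β̂_A→P − β̂_B→P, σ̂_diff = √(σ̂²_A→P + σ̂²_B→P) and
   σ̂ = √(β̂²_diff σ̂²_P→BC + β̂²_P→BC σ̂²_diff).

A first-class synthetic-data module generates GWAS summary statistics, pQTL
panels and an individual-level cohort with exactly this causal structure, so
the entire pipeline is testable without any restricted data.

## Worked example

```python
from mrclustmed import pipeline, synthetic_data as sd

config = sd.SimulationConfig(seed=7)          # 24/73/7 variant clusters at
data = sd.simulate_summary_stats(config)      # ratio means 0.98/-0.61/-1.74
result = pipeline.run_part1(data.exposure, data.outcome, data.ld,
                            pipeline.RunConfig(seed=7))
print(result.cluster_table.round(3).to_string(index=False))
```

prints

```
  cluster  n_snps  cluster_mean   beta    se     p  ci_lower  ci_upper
cluster_1       6        -1.708 -1.723 0.024 0.000    -1.770    -1.677
cluster_2      63        -0.601 -0.600 0.006 0.000    -0.612    -0.588
cluster_3      22         0.976  0.977 0.011 0.000     0.955     0.999
     null     332         0.007  0.007 0.003 0.005     0.002     0.013
```

Three substantive clusters are recovered with IVW estimates covering the
generating ratio means (−1.74, −0.61, 0.98); the null cluster collects the
no-effect variants. The `examples/` directory has one narrative script per
capability (clustering workflow, MR estimators, one-sample MR, mediation),
each printing the numbers it computes and what they mean. A thin CLI wraps
the same calls: `mrclustmed simulate`, `mrclustmed part1`,
`mrclustmed part2`.

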