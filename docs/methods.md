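# Methods

## Model and estimators

Throughout, per-variant summary associations are (β̂, se) pairs with
two-sided p-values from the normal distribution, the convention for GWAS
summary statistics. All combined estimates are fixed-effect: the
inverse-variance weighted (IVW) estimate of a set of Wald ratios is
β̂ = Σw_jθ̂_j / Σw_j with w_j = σ_j⁻² and se = (Σw_j)^{-1/2}; no
multiplicative random-effects rescaling is applied (a deliberate default —
the meta-analytic language of the analyses this package supports is
fixed-effect).

**Wald ratio SEs.** `mr_core.wald_ratio` defaults to the first-order delta
method, σ_j = |se_out/β̂_exp|. The pipeline (`RunConfig.wald_second_order`,
default on) uses the second-order form
σ_j² = se_out²/β̂_exp² + β̂_out² se_exp²/β̂_exp⁴. The exposure-side term is
negligible for small ratios but reaches ~15% of the total SE at ratios near
1.7 with the default study shape, and omitting it visibly under-covers the
per-cluster confidence intervals.

**Harmonisation.** Variants are aligned to the exposure's effect allele:
swapped allele labels flip the outcome beta and frequency; complementary
strand labels are complemented first. Palindromic variants (A/T, G/C) carry
no strand information in their labels, so after label alignment they are kept
only when both allele frequencies fall on the same side of 0.5 and both sit
outside the ambiguity band [0.42, 0.58] — the band follows common two-sample
MR practice, and is configurable.

**Steiger filtering** uses the observed-scale pseudo-r², r² = Z²/(Z² + n),
for both traits, and a one-sided Fisher-z test of the correlation difference
with variance 1/(n_exp−3) + 1/(n_out−3); a pair is kept when r²_exp > r²_out
and p < α (default 0.05). No liability-scale conversion is attempted; for a
binary outcome this is conservative for strong ratios (see Limitations).

**Clumping** is greedy: repeatedly keep the smallest-p variant below the
significance threshold (ties break by chromosome and position) and discard
remaining variants on the same chromosome within the window AND at or above
the r² threshold. Without an LD matrix the distance rule alone applies, and
a warning is emitted. Defaults: 500 kb, r² = 0.001, p < 5×10⁻⁸.

## The ratio mixture

Variant j's ratio θ̂_j has likelihood N(μ_k, σ_j²) under substantive cluster
k, N(0, σ_j²·λ) under the null (λ an optional overdispersion factor, default
1), and a uniform density over the observed ratio range widened by one range
on each side (total width 3× the range) under the junk component. The junk
support choice is isolated behind the model's junk-interval fields; any
location-free heavy alternative could be substituted.

Fitting is EM: responsibilities in the E-step; precision- and
responsibility-weighted means and mean responsibilities in the M-step;
convergence when the log-likelihood gains less than 1e-8 (cap 5,000
iterations). Each (K, seed) fit uses multi-restart initialisation — the
first restart starts the means at evenly spaced ratio quantiles, the rest
draw uniformly over the ratio range — with a short-run strategy: every
restart is capped at 100 iterations and only the best is polished to full
convergence. EM continues from the short run's state, so the reported
log-likelihood trace is monotone end to end. K is selected over 0..K_max by
BIC = −2logL + (2K+1)log n (each cluster contributes one mean and one free
mixing proportion; ties prefer fewer clusters). Cluster labels are
canonicalised with means ascending, making fits invariant to label
permutation and input order.

Assignment takes the posterior argmax; a variant is *confident* above a
probability threshold (default 0.8). Substantive clusters with fewer than
`min_cluster_size` (default 4) confident members are dissolved: their
probability mass is removed, rows renormalised, labels recomputed — members
fall to their next-best component, and responsibility vectors keep summing to
one. Per-cluster MR runs IVW over the confident members' Wald ratios (junk
excluded) and reports the unweighted member mean alongside.

## Mediation inference

Step-1 effects (cluster-scaled exposure → protein) come from a
two-sample-within-one-cohort design: the score→exposure association is
estimated in one sub-sample and the score→protein associations in a disjoint
sub-sample (disjointness is asserted, not assumed), then combined by the
Wald ratio. The exposure is rank-based inverse-normal transformed (Blom
offset 3/8, average ranks for ties) before regression. Step-2 effects
(protein → outcome) are IVW estimates over each protein's instruments,
eligible only with ≥3 independent genome-wide-significant variants
(p < 1.7×10⁻¹¹) of which ≥1 lies within ±1 Mb of the encoding gene.

Screening applies Benjamini–Hochberg FDR within each cluster across the
protein panel (step 1) and across proteins (step 2); candidates pass both at
α (default 0.05). A pooled step-1 family is available behind a flag.

The mediated effect is the product of the two estimates with first-order
delta SE; because the product of two normals is skewed near the significance
boundary, the reported CI is the empirical quantile interval of 10⁶ (default;
configurable) independent normal resamples of both factors. The Sobel-style
z uses the delta SE. The proportion mediated is the mediated effect over the
cluster's total MR effect, stored signed; for an odds-ratio outcome it is a
covariate-set-dependent approximation (non-collapsibility), and the package
treats it strictly as ratio arithmetic. Between-cluster contrasts exploit
that step 2 is shared across clusters for a protein: the difference of
mediated effects equals β̂_diff·β̂_P→BC exactly, with
σ̂ = √(β̂²_diff σ̂²_P→BC + β̂²_P→BC σ̂²_diff) and a Monte Carlo CI for the
product. Report tiers mark ** p<0.01, * p<0.05, ° only the Monte Carlo CI
excludes zero.

## The synthetic study

The generator emulates the study conditions the pipeline targets: three
substantive variant clusters of 24, 73 and 7 instruments at ratio means
0.98, −0.61 and −1.74, plus 360 null variants; exposure GWAS components of
266,130 and 322,154 samples meta-analysed; a binary-outcome GWAS of 247,173
with case fraction 0.54; an outcome prevalence of 0.085 in the cohort.
Observed effects add Normal(0, se²) noise with se² = 1/(2nf(1−f)) for
quantitative traits and se² = 1/(2nφ(1−φ)f(1−f)) for the binary outcome
(φ the case fraction) — the standard log-OR variance; without the φ(1−φ)
term the Steiger direction condition would fail in expectation for any
ratio above 1, which no coherent emulation of this design can allow.

Instruments are parameterised by strength: the per-variant exposure
correlation r = β√(2f(1−f)) is drawn uniformly from (0.05, 0.11) and β
derived from it and the allele frequency (f ~ U(0.2, 0.8)). This emulates
*post-selection* instruments — panels strong enough that the published-style
filtering flow (~90% retention through harmonisation and Steiger) leaves the
cluster architecture intact, with per-variant ratio SEs of 0.04–0.08 — and
deliberately not the effect-size spectrum of a full GWAS, where the
observed-scale Steiger test at p < 0.05 would selectively remove
strong-ratio variants. A direct |β| range can be supplied instead. The
outcome table is allele-scrambled (swaps and strand flips) so harmonisation
is genuinely exercised; allele pairs are drawn uniformly, so about one third
of variants are palindromic and ~6% drop in the ambiguity band, matching the
attrition a real harmonisation step produces.

The cohort draws genotypes Binomial(2, f), builds the exposure as the
genetic score plus residual noise to unit variance, proteins as linear
functions of the cluster-specific genetic components plus unit noise, and
the outcome from a logistic model whose intercept is solved by bisection to
hit the target prevalence. Cohort genetic effects are rescaled to a target
exposure heritability (default 0.25) since the strong-instrument panel
would otherwise exceed unit variance; the Wald ratio is invariant to this
common rescale. The cohort defaults are a deliberately desk-scaled
emulation: 20,000 individuals split evenly into the two disjoint
sub-samples, with mediator effects (0.4–0.9 SD of protein per SD of
cluster-specific exposure) sized to be detectable at that scale — the
emulated study's proteomics arm is an order of magnitude larger with
correspondingly smaller detectable effects. A separate summary-level
generator (`simulate_mediation_summary`) draws step-1/step-2 estimate tables
directly for screening studies over full-size (2,922-protein) panels, where
a per-replicate cohort would be wasteful.

What the generator does **not** emulate: realistic LD (variants are
independent by default; an LD matrix can be supplied to the clumping
exercises), population stratification, assortative mating, winner's curse in
instrument discovery, or a realistic GWAS effect-size spectrum (see above).
Passing tests therefore demonstrate the correctness and calibration of the
estimators and the pipeline's bookkeeping under the assumed causal
structure, not robustness to the confounding structures of real cohorts.

## Numerical choices and problem sizes

Simulation studies in the test suite use 50 replicates of the full
clustering pipeline (~460 variants each), 100 replicates of null-data model
selection (200 variants), 500 replicates of Monte Carlo CI coverage (10⁴
draws per CI; the 10⁶ default is for analyses, not calibration loops), and
20 replicates of the 2,922-protein screen. Degenerate inputs are handled
explicitly: exact regression fits report p-values of 0/1 rather than
dividing by zero; a zero exposure effect makes the Wald ratio a hard error;
all-identical values make the inverse-normal transform a hard error; an
all-ratios-identical mixture widens its junk support to a unit interval.

## Limitations

- Steiger filtering on the observed scale is conservative for binary
  outcomes with strong ratios; a liability-scale variant is out of scope.
- The per-cluster IVW over confident members inherits MR-Clust-style
  selection effects (members are chosen by the same data that is then
  combined); at the default signal-to-noise these are small but visible as
  mild extra dispersion.
- Proportions mediated through an odds-ratio outcome are approximations
  under non-collapsibility and depend on the covariate set of the underlying
  models.
- The stratified re-runs (e.g. by menopausal status) are supported as plain
  re-invocations on row subsets plus the coefficient Z-test; no interaction
  models are provided.
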