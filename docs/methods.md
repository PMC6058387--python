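# Methods

## Statistical models

**Cell-type contrast.** For each probe, neuron and glia control samples
are compared with a two-sample *t* test. Welch's unequal-variance form
is the default: per-probe array variances genuinely differ between
nuclei fractions, and with the effect sizes of interest (Δβ ≥ 0.20) the
choice is immaterial; a pooled-variance flag exists for exact
equivalence with the classical Student test. A ct-DMCG call requires
(i) an autosomal probe, (ii) Bonferroni-adjusted p < α (default 0.05,
m = probes tested), and (iii) |mean difference| ≥ `delta_min` (default
0.20 on the beta scale, read as an absolute difference in methylation
fraction, not percent-of-baseline). Probes with zero variance in both
groups get p = 1 rather than being dropped, so m is preserved.

**Association regressions.** Per CpG and per cell fraction, ordinary
least squares of beta on the predictor (age in years, or Braak stage as
a numeric 0–6 score — a single-slope ordinal reading, which is why one
p-value per probe is reported) with covariates from {age, braak, sex,
pc1}; sex is female = 0 / male = 1. Working on beta values keeps
coefficients directly interpretable as beta units per year / per stage.
All probes share one design matrix, so the fits reduce to one set of
matrix products (normal equations); the per-probe path
(`fit_cpg_regression`) is retained and tested equal to the vectorised
path. Two-sided p-values use the t distribution with n − k df.
Rank-deficient designs are rejected; zero-variance probes get p = 1.
The aging analysis defaults to controls only; a switch includes AD
samples with Braak as an extra covariate.

**Meta-analysis.** Fisher's method over the k = 2 cell fractions:
χ² = −2 Σ ln p, combined p = upper tail of χ²(2k = 4 df), computed via
the log survival function so that component p-values near 1e−300 do not
underflow; component p ≤ 0 is clamped to a configurable floor (1e−300)
with a warning. BH q-values are computed by the step-up rule over all
probes entering the meta-analysis (probes tested in only one fraction
are excluded, not imputed, since Fisher's method assumes valid
component tests). `bh_fdr(p, m=...)` supports an external family size,
and `bh_from_ranked` adjusts excerpted rows of a larger ranked family —
this reproduces a published FDR column of the form p·m/rank at the top
ranks with m = 478,416. Ranking is ascending p with ties broken by
probe id for determinism.

**Deconvolution.** The reference panel holds per-cell-type mean betas
at the k most discriminative probes (smallest t-test p, default
k = 600; a `balanced` option takes k/2 per direction). Weights solve
min‖b − Rw‖² s.t. w ≥ 0, Σw ≤ 1 — the constraint set of the standard
constrained-projection estimator; the residual 1 − Σw is unexplained
signal. The quadratic program is solved by SLSQP with analytic
gradient, x₀ = 0 and ftol 1e−14; tests pin the solution against a
0.001-step grid search (±0.002) and against identity recovery of the
panel's own profiles. Markers missing in a bulk sample are dropped per
sample; estimates are marker-order invariant.

## Synthetic cohorts

The generator emulates a sorted neuron/glia 450k study with full
per-probe ground truth. Defaults (all exposed as parameters):

| parameter | default | meaning |
|---|---|---|
| baseline μ | bimodal (40% in 0.03–0.20, 40% in 0.80–0.97, 20% mid) | array-typical methylation landscape |
| ct-different fraction | 0.12 | probes with \|μ_n − μ_g\| ≥ 0.20 (Δ ~ U(0.20, 0.45)), 54% neuron-hyper |
| age-slope fraction | 0.01 per fraction (disjoint) | slopes ±0.002 β/yr, 60% negative; 25% get an opposite-sign slope in the other fraction |
| age-dynamic ct probes | 0.25 of ct probes | opposing ±0.002 β/yr slope pairs; 70% converging (the high fraction drifts toward the low one), matching the predominance of shrinking neuron–glia differences in aged donors |
| Braak effects | 0.005 per fraction (disjoint) | ±0.02 β/stage, 60% negative |
| sex / batch effects | 1% of probes ±0.01 / 5% of probes ±0.01 (batch b2) | nuisance structure |
| noise | Beta(mφ, (1−m)φ), φ = 200 | sd ≈ 0.03 at μ = 0.5, typical array replicate noise; φ ≥ 1e6 is the exact noise-free limit |
| ages | U(30, 95), effects centred at 62.5 | centring makes μ the cohort-centre mean, so planted ct labels stay exact and regression slopes are unchanged |
| Braak staging | rank-thresholded latent score, corr(age) ≈ 0.5; stage frequencies (.20,.15,.15,.12,.10,.14,.14); diagnosis = AD iff stage ≥ III | age–pathology confounding of autopsy cohorts |
| bulk mixing | w = clip(0.55 − 0.002·age − 0.01·braak + N(0, 0.05), 0, 1) | neuronal weight declining with age and disease; mixing is linear in beta, the physically correct rule for pooled nuclei |

Per-sample means are m = clip(μ + slope·(age − 62.5) + braak·effect +
sex/batch offsets, 0.01, 0.99); effects are additive on the beta scale
(matching the fitted model, so recovery is directly interpretable),
with clipping in place of a logit link. Each donor contributes one
neuron and one glia sample with shared covariates. Annotation assigns
probes round-robin to chromosomes 1–22 with region classes drawn at
450k design proportions (TSS1500 .13, TSS200 .10, 5'UTR .12, 1stExon
.07, Body .31, 3'UTR .03, intergenic .24). All randomness flows from a
single seed; cohorts are reproducible byte-for-byte.

Not emulated: Infinium I/II probe chemistry, background/dye effects,
detection-p structure (an optional pass-through filter only), spatial
correlation along the genome, and non-CpG probes beyond allowing "ch."
ids. Passing tests therefore demonstrate correctness of the statistics
under the stated generative model, not robustness to those artifacts.

## Preprocessing

Detection filtering keeps probes with detection p ≤ 0.01 in every
sample (pass-through when no detection matrix exists, as for synthetic
data). Quantile normalization maps every sample onto the mean empirical
distribution, ties receiving the value at their average rank; it is
idempotent to 1e−12. PCA runs on the probe-centred combined sorted
matrix; component signs are fixed by forcing each component's largest
loading positive. PC–covariate association uses Pearson tests for
continuous covariates and one-way ANOVA for categorical ones.

A property of the synthetic conditions worth knowing: PC1 of the
combined sorted matrix is the cell-type axis, and because age-dynamic
ct probes converge with age, within-fraction PC1 scores are nearly
collinear with age. Including pc1 in a per-fraction aging regression
then absorbs most planted signal. The pipeline keeps pc1 by default
(mirroring its role as a technical covariate when, as in real sorted
datasets, the leading component tracks array batch) and exposes
`include_pc1: false`; ground-truth recovery tests use explicit specs
without pc1.

## Experiments

**Sorted vs bulk power.** For matched donor numbers (n samples per
sorted fraction, n bulk samples), power is scored per planted effect
instance — a (probe, fraction) pair with a nonzero Braak effect — as
the fraction of instances reaching Bonferroni significance in the EWAS
of the carrying fraction (sorted) or in the bulk regression (bulk).
Under the default confounded design, bulk attenuates cell-type-specific
effects by the mixing weight and sorted power exceeds bulk power; with
proportion drift disabled and equal effects in both fractions the gap
collapses, confirming the gain comes from composition confounding, not
from the scoring.

**Reference-age bias.** Two reference panels are built from sorted
cohorts drawn in a young (30–45 y) and an old (75–95 y) age window
(all diagnoses — the old window is depleted of low-Braak donors), each
selecting its own top-k markers; one bulk cohort is deconvolved with
both, and the per-sample difference of neuronal-proportion estimates is
reported. With age-dynamic markers the difference is systematic and
sign-stable and vanishes monotonically as the slopes are scaled to
zero. Its magnitude under the default design is of order 0.01 and
scales with the distance of the true proportions from 0.5, the
fraction of markers carrying slopes, and the converging/diverging
asymmetry; designs with more extreme proportions or stronger marker
dynamics show proportionally larger bias.

## Problem sizes

The test suite runs at desk scale, chosen so that every recovery check
has adequate statistical resolution: 10,000 probes with 40 donors per
fraction for ct-DMCG recovery and deconvolution (600 markers, 100 bulk
samples), 50 donors for aging-slope recovery, 20 seeds × 1,500 probes
for null calibration, 10 seeds × 4,000 probes for the power study, and
10 seeds at 10,000 probes for the reference-age experiment.

## Known limitations

- No IDAT parsing, background subtraction or probe-type normalization;
  input is an already-normalized (or raw simulated) beta matrix.
- Empirical-Bayes batch adjustment (ComBat-style) is not implemented;
  the PC covariate is the supported batch correction, and whether it
  fully substitutes for explicit batch modelling on real data is not
  established here.
- Braak enters as a linear ordinal; threshold or saturating stage
  effects are not modelled.
- Deconvolution is two-component (neuron/glia); glial subtypes are out
  of scope.
- Effects near the beta boundaries are clipped, so very hypo-/hyper-
  methylated probes carry attenuated planted effects — visible as a
  sensitivity cost exactly at the Δ ≥ 0.20 calling boundary.
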