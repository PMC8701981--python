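# Methods

## Model

All evaluations use the single-trait animal model

    y = Xb + Zu + e,   u ~ N(0, K σ²ₐ),   e ~ N(0, I σ²ₑ)

where `y` are trait records in kg, the fixed part holds a slaughter-date
contemporary group (a categorical factor, cell-means coded with no explicit
intercept so the factor absorbs the mean) and a slaughter-age covariate in
days (centred before assembly; centring affects conditioning only, not the
breeding-value solutions), and `u` are additive breeding values for every
pedigree animal. `K = A` gives PBLUP; `K = H` gives single-step GBLUP.

The slaughter-date/age structure follows the convention of carcass
evaluations, where animals slaughtered on the same day share management and
measurement conditions (of the order of 180 date levels in a production
dataset; 40 in the desk-scale simulations).

## Relationship matrices

* **A** is built by the recursive tabular method (exact with inbreeding);
  its inverse is assembled directly from per-animal contributions `1/dᵢ`
  with Mendelian-sampling variances `dᵢ = 0.5 − 0.25(F_s + F_d)` (both
  parents known), `0.75 − 0.25 F_p` (one), `1` (none). A⁻¹ is held sparse;
  A22 (the genotyped block) is extracted dense through the triangular
  factorisation `A = L⁻¹ D L⁻ᵀ`, so the full dense A is never materialised
  for large pedigrees.
* **G** is VanRaden's first method, `Z Z' / (2 Σ pⱼ(1−pⱼ))`, with `Z` the
  genotype matrix centred by twice the observed allele frequency of the
  post-QC genotyped set. The base-population frequencies are unknowable
  without a pedigree-founder reconstruction, so observed frequencies are
  the default; an optional moment-matching step (`tune_G_to_A22`) rescales
  G so its mean diagonal and off-diagonal equal those of A22, for users
  whose pipelines expect that convention. Blending `w_G G + w_A A22`
  (default 0.95/0.05) guarantees invertibility.
* **H⁻¹** adds `(G_blend)⁻¹ − A22⁻¹` to the genotyped block of A⁻¹.
  Both inverses are computed by Cholesky factorisation and fail loudly,
  naming the offending matrix, if it is not positive definite.

## Genotype quality control

Stages run in a fixed, documented order — animal call rate, SNP call rate,
minor allele frequency, heterozygosity deviation — each on the matrix
surviving the previous stage, because the per-stage counts depend on the
order. Defaults: call rate ≥ 0.90, MAF ≥ 0.01, |Hobs − 2p(1−p)| ≤ 0.15.
Remaining missing genotypes are imputed with the rounded per-SNP mean
(2p rounded to 0/1/2); pedigree-aware imputation is deliberately out of
scope since imputation quality is not what the estimators under test are
sensitive to at simulated missingness of ~1%.

## Gibbs sampler

A single-site sampler: each fixed-effect level, the covariate slope and
each breeding value are drawn from their Gaussian full conditionals (the
hot loop is compiled with numba; K⁻¹ is accessed by sparse rows), then

    σ²ₐ | u  ~ (u' K⁻¹ u) / χ²(q − 2),   σ²ₑ | e ~ (e'e) / χ²(n − 2)

under flat priors on fixed effects and variances (scaled inverse
chi-square with ν = −2, S = 0), chosen so posterior means are comparable
to REML. The heritability is summarised as the posterior mean of the
per-draw ratio σ²ₐ/(σ²ₐ+σ²ₑ) — not the ratio of posterior means, which can
differ in the second decimal. Convergence is checked by a split-chain
potential-scale-reduction factor on both variances (warning above 1.05)
rather than visual inspection.

Chain profiles: desk-scale default 50,000 cycles / 5,000 burn-in /
thinning 10 (used throughout the tests; about 10 s at 2,500 pedigree
animals), with the production profile 550,000 / 50,000 / 50 available via
configuration.

**Equilibrium genetic variance.** For each retained draw, the empirical
variance of the sampled breeding values across the focal cohort is
computed; σ²ᵤ,∞ is the posterior mean of that quantity (Monte-Carlo SE
from the per-draw spread). Conditional on the pedigree this equals
(1 + F̄ − 2f̄)σ²ₐ in an unselected population and is automatically reduced
by selection-induced covariances among cohort members — which is exactly
the denominator the LR accuracy needs. Which cohort defines "equilibrium"
is an open convention; here it is the focal (validation) cohort itself.

## LR validation

The partial dataset removes only the focal cohort's phenotype records;
pedigree and genotypes are untouched. Estimators, for focal EBV vectors
û_p (partial) and û_w (whole):

* accuracy² of the partial evaluation: `cov(û_w, û_p) / ((1 + F̄ − 2f̄) σ²ᵤ,∞)`;
  the reported accuracy is its square root by default, since the ratio
  estimates a squared correlation while published accuracy scales
  (roughly 0.2–0.8) correspond to ρ itself. The whole-data accuracy uses
  the same estimator with û_w in both slots (cov → var).
* bias `mean(û_p) − mean(û_w)` (expected 0) and dispersion, the slope of
  û_w on û_p (expected 1).
* ratio estimators: the Pearson correlation between two EBV vectors
  estimates the ratio of their accuracies, and `1/ρ − 1` the relative
  gain — between methods on a fixed dataset, or between partial and whole
  data for a fixed method.

Two printed conventions for the denominator exist in the literature,
`1 + F̄ − 2f̄` and `1 + F̄ + 2f̄`. The minus sign is the default here (it is
the form consistent with the variance of EBV differences within a cohort);
both are selectable and the choice is recorded in every report. f̄ averages
coancestry A_ij/2 over distinct pairs only — self-pairs belong to F̄.
Negative covariance estimates clamp the accuracy to 0 with a warning
rather than crashing a pipeline on small-sample noise.

## Synthetic data

The generator emulates a steer-evaluation design: discrete generations
(default 500 founders plus four cohorts of 500, giving 2,000 phenotyped
non-founders), gene dropping over 5,000 unlinked SNPs, 200 of them QTL
with normal effects rescaled so the founder breeding-value variance equals
`h² σ²_p` (defaults h² = 0.4, σ²_p = 10 kg², trait mean 30 kg — mid-range
for a primal cut), 40 slaughter-date levels (SD 1.5 kg), an age effect of
0.05 kg/day over ages 690–780 days, and a focal cohort defined by the last
birth year (the youngest generation). 85% of non-focal animals and all
focal animals are genotyped — mirroring production datasets in which
nearly every phenotyped animal is genotyped — leaving all four
genotyped-by-phenotyped classes populated. Missingness is 1% at random.
Truncation selection, when enabled, selects the top half of each
generation on the simulated phenotype itself, so the pedigree accumulates
genuine selection pressure on the analysed trait.

What the generator does **not** emulate: linkage and LD structure (loci
are unlinked, so marker-QTL association comes from cosegregation within
the recorded pedigree only), dominance/epistasis, genotyping error,
heterogeneous variances, and overlapping generations. Passing tests
therefore demonstrate correctness of the estimators under the model's own
assumptions, not robustness to the violations real data exhibit.

## Numerical choices

* MME solved by sparse LU with one iterative-refinement step; relative
  residual above 1e-10 is a hard error.
* Rank deficiency between intercept and contemporary groups is avoided by
  cell-means coding; a constant covariate is dropped with a warning.
* Pedigree files are topologically sorted on read (depth-first), with
  cycles, self-parenting and duplicates rejected; animals appearing only
  as parents become founders.
* All simulation randomness flows from a single integer seed through
  numpy Generators; Gibbs chains seed numba's RNG explicitly, so equal
  seeds give bit-identical chains.

## Problem sizes used in the checks

Worked-example checks are closed-form. Oracle-equivalence checks use
pedigrees up to 500 animals (dense inverses as the oracle) and an
80-animal / 30-genotyped single-step instance. Parameter recovery runs
the desk-scale chain on 2,000 phenotyped animals at true h² of 0.2 and
0.5. Calibration and ordering checks average ten replicate studies of
1,000 pedigree animals (800 phenotyped, 200 focal, 1,000 SNPs), sizes at
which the full suite completes in a few minutes while leaving the
estimators' sampling error small relative to the tolerances.

## Known limitations

Single trait only (no multi-trait MME or samplers), no genetic groups or
metafounders, no reliabilities from the MME inverse, dense A22/G
(genotyped sets of a few thousand), and the equilibrium-variance estimand
is tied to the focal cohort as described above.
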