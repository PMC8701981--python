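# ssgblup

Pedigree-based and single-step genomic evaluation of quantitative traits,
with Bayesian variance-component estimation and LR-method validation.

The package targets the standard workflow of a livestock genetic
evaluation — here modelled on carcass primal-cut weights in beef cattle
(Hanwoo), where breeders want to rank young animals on traits that can only
be measured at slaughter:

1. **PBLUP** — Henderson's mixed model equations for the animal model
   `y = Xb + Zu + e`, `u ~ N(0, A σ²ₐ)`, with the numerator relationship
   matrix **A** built from the pedigree (tabular method) and its sparse
   inverse built directly with inbreeding-corrected Mendelian-sampling
   variances.
2. **ssGBLUP** — the same equations with `A⁻¹` replaced by the single-step
   inverse

   `H⁻¹ = A⁻¹ + [0 0; 0 (w_G G + w_A A₂₂)⁻¹ − A₂₂⁻¹]`,

   where **G** is VanRaden's genomic relationship matrix `ZZ'/2Σpⱼ(1−pⱼ)`
   from quality-controlled SNP genotypes and **A₂₂** the pedigree block of
   the genotyped animals (default blend 0.95 G + 0.05 A₂₂).
3. **Gibbs sampling** — a single-site sampler for σ²ₐ and σ²ₑ under flat
   priors, yielding h², the coefficient of genetic variation
   `CV_g = 100·σₐ/mean`, and the focal cohort's equilibrium genetic
   variance σ²ᵤ,∞ under selection.
4. **LR-method validation** — breeding values predicted with the focal
   cohort's phenotypes removed ("partial") are compared with those using
   all data ("whole"): accuracy `ρ = √( cov(û_w, û_p) / ((1+F̄−2f̄) σ²ᵤ,∞) )`,
   bias `mean(û_p) − mean(û_w)`, dispersion `slope of û_w on û_p`, and the
   relative accuracy gain `1/ρ − 1` between methods or datasets.

A forward simulator (discrete generations, gene dropping over unlinked
SNPs, additive QTL inside the panel, contemporary-group and slaughter-age
fixed effects, optional truncation selection) generates datasets with the
statistical structure the analysis assumes, so every estimator can be
checked against simulation truth.

## Worked example

```python
from ssgblup import (SimulationConfig, simulate_dataset, run_lr_study,
                     RunConfig, GibbsConfig)

cfg = SimulationConfig(n_founders=200, n_generations=5,
                       offspring_per_mating=2, n_snps=1000, n_qtl=100,
                       h2_true=0.4, seed=11)
data = simulate_dataset(cfg)
result = run_lr_study(data, RunConfig(seed=11),
                      GibbsConfig(chain_length=6_000, burn_in=1_000,
                                  thin=5, seed=12))
print(result.report.table)
```

prints (abridged):

```
pedigree: 1000 animals; 800 phenotyped; 880 genotyped; 200 focal
h2 = 0.29 (SD 0.06); sigma2_a = 2.51; sigma2_e = 6.09; CV_g = 5.34%
sigma2_u_inf = 2.52; F_bar = 0.0011; f_bar = 0.0050
 method  acc_partial  acc_whole   bias  dispersion  gain_methods_partial  gain_methods_whole
  PBLUP        0.442      0.649 -0.035       1.028                 0.178               0.061
ssGBLUP        0.532      0.702 -0.021       1.021                 0.178               0.061
```

Reading the numbers: with the focal cohort's phenotypes masked, adding
genomic information lifts the LR accuracy from 0.44 (PBLUP) to 0.53
(ssGBLUP), a relative gain of 18%; with all phenotypes the two methods
nearly coincide (gain 6%). Bias is near zero and dispersion near one for
both methods, i.e. neither evaluation systematically over- or
under-predicts the focal animals' breeding values.

## Command-line pipeline

```bash
ssgblup simulate --out data/ --seed 1
ssgblup run-all --data data/ --work work/ --config config.yaml
```

`run-all` chains simulate → QC → relationship matrices → Gibbs → MME
solves → LR report, caching each stage's artifacts: deleting only
`work/lr_report.tsv` and re-running regenerates the report without
repeating the Gibbs chain. Stages are also exposed individually
(`qc`, `relmat`, `gibbs`, `solve`, `validate`).

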