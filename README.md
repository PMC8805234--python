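# ntmr — Mendelian randomisation with maternal non-transmitted-allele polygenic instruments

Observational studies consistently find that mothers with higher
pre-pregnancy BMI have children with higher adiposity, but whether this
reflects a causal intrauterine/periconceptional effect or familial
confounding is hard to settle. A one-sample Mendelian-randomisation
design resolves it by instrumenting the maternal exposure with a
polygenic risk score built **only from the maternal alleles the child
did not inherit**: the non-transmitted (NT) score predicts the mother's
BMI but is independent of the offspring's genotype under random mating,
so it cannot act on the child through inherited variants — and no
adjustment for offspring or paternal genotype (with its collider-bias
risk) is needed.

`ntmr` is a library for building, validating and stress-testing that
design end to end, aimed at genetic epidemiologists and methodologists:

- **simdata** — simulate mother–father–offspring cohorts with exact
  transmission truth: exposure `X = √α·Z_m + λ_x C + ε`, outcomes
  `Y = β_m X + γ_c Z_c + γ_p Z_p + λ_y C + ε` (all SD units; `Z` are
  standardised polygenic scores, `C` a latent familial confounder),
  optional assortative mating, block LD, per-SNP pleiotropy, MCAR
  missingness.
- **haplotypes** — recover maternal transmitted/non-transmitted
  dosages from duo (optionally trio) hard-call genotypes with explicit
  handling of the ambiguous het/het sites and Mendelian-error QC.
- **prs** — harmonise external weight tables (allele flips, strand,
  palindromes), LD clumping + p-value thresholding, weighted scoring,
  within-stratum standardisation.
- **estimators** — nested multivariable models one–three on an
  identical complete-case sample, one-sample TSLS with first-stage
  R²/F diagnostics, the Wald/ratio estimator with Taylor-series SEs
  (`SE² = se_zy²/β_zx² + β_zy² se_zx²/β_zx⁴`), per-SNP Wald ratios.
- **inference** — fixed-effects (and DerSimonian–Laird) meta-analysis
  with Q/I², the pooled ratio estimator, the MV-vs-MR z-test with a
  family-bootstrap covariance, between-SNP Cochran's Q, MR-Egger,
  instrument-validity screening, effect-size-stratified MR, sex
  interaction and parental-PRS correlation checks.
- **pipeline / CLI** — a configured `simulate → estimate → report`
  workflow over VCF/TSV files (`ntmr` console command).

## Worked example

```python
import pandas as pd
from ntmr import SimConfig, simulate_cohort, score, mv_regress, tsls

cfg = SimConfig(n_trios=5000, n_snps=100, alpha=0.1,
                beta_m={"y": 0.1},      # true causal effect, SD per SD
                gamma_p=0.0, seed=3)    # familial confounding defaults on
cohort, pheno = simulate_cohort(cfg)

weights = cohort.snp_meta[["id", "chrom", "pos", "ea", "oa", "weight"]].copy()
weights["flip"] = False
nt = pd.DataFrame(cohort.maternal_nontransmitted,
                  index=cohort.family_ids, columns=cohort.snp_meta["id"])
instrument = score(nt, weights).score

print(mv_regress(pheno, "y_y", model="three").beta)
print(tsls(pheno, "y_y", instrument, covariates=["pc1", "pc2"]).beta)
```

Running `examples/03_mr_versus_mv.py` (this scenario plus the
difference test) prints:

```
MV model   one: beta = 0.392 (SE 0.013), N = 5000
MV model   two: beta = 0.219 (SE 0.014), N = 5000
MV model three: beta = 0.214 (SE 0.014), N = 5000
TSLS (NT-PRS):  beta = 0.127 (SE 0.063), first-stage R2 = 0.046, F = 241
MV-vs-MR difference: z = 1.44, p = 0.15 (bootstrap covariance 0.00021)
```

The crude association (0.39) is inflated by familial confounding; the
covariate-adjusted models remove only the part captured by the noisy
confounder proxies (0.21); the NT-PRS instrument recovers the true
causal effect 0.1 within its standard error. The other scripts under
`examples/` walk through duo resolution and scoring, transmission
structure, and the pleiotropy/heterogeneity diagnostics.

A shell workflow over files is available too:

```bash
ntmr simulate --config run.yaml   # writes trio VCF + phenotype/weight TSVs
ntmr estimate --config run.yaml   # resolution -> scoring -> MV/MR -> report
ntmr report   --out out_dir
```

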