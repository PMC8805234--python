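# Methods

## The design in one paragraph

A mother passes exactly one allele per locus to her child. A polygenic
score built from the alleles she did *not* transmit predicts her own
phenotype (each non-transmitted allele is an unbiased draw from her
genome) yet, under random mating, is independent of the child's
genotype. Used as an instrumental variable for a maternal exposure, the
non-transmitted (NT) score therefore cannot affect the offspring
outcome through inherited variants, and no adjustment for offspring or
paternal genotype is required — avoiding the collider bias that such
adjustment induces when paternal direct genetic effects exist. `ntmr`
implements this design, the estimators around it, and a simulator rich
enough to validate every stage against known truth.

## Generative model (simdata)

Per family: phased parental haplotypes are drawn binomially at
frequencies uniform on `allele_freq_range` (default 0.1–0.9). One
haplotype per parent per LD block is transmitted; transmitted +
non-transmitted equals the maternal genotype identically, so the
instrument truth is exact.

Phenotypes, all internally z-scored (SD units):

- exposure `X = √α · z(PRS_m) + λ_x C + ε_x`, with `C ~ N(0,1)` a
  latent familial confounder; `α` (default 0.05) is the exposure
  variance explained by the maternal PRS — the NT score then has
  first-stage R² ≈ α/2, and α = 0.1 matches the ~5% NT-score R²
  reported for large BMI PRS instruments;
- outcome `Y = β_m X + γ_c z(PRS_c) + γ_p z(PRS_p) + λ_y C +
  m'δ + τ·X·(sex−½) + ε_y`, where `δ` is optional per-SNP maternal
  pleiotropy and `τ` an optional sex-specific effect. Defaults:
  `β_m = {bw: 0.14, bmi15: 0}` (a birthweight effect, none on
  adolescent BMI), `γ_c = γ_p = 0.2`, `λ_x = λ_y = 0.5` (crude
  confounding ≈ +0.25).

Residual variances are allocated from the empirical variance of the
systematic part so the total is 1; a systematic variance ≥ 1 raises.
This keeps the coefficients exact in SD units without a closed-form
variance budget, which would be fragile under assortative mating and
pleiotropy cross-terms.

The observed table carries the true confounder (`c_true`) *and* two
noisy proxies (`conf1`, `conf2`, reliability ≈ 0.7) plus a paternal
exposure analogue; the default multivariable models adjust only for the
proxies, so residual confounding — the phenomenon the design exists to
expose — persists after adjustment, as in real cohort data.

**Assortative mating** is induced by rank-matching mothers and fathers
on PRS + Gaussian noise with `σ² = var(PRS)(1−ρ)/ρ`, the closed-form
attenuation that yields spousal PRS correlation ≈ `ρ_am`. A shortfall
beyond 0.05 raises with the achieved value. A derived consequence,
asserted in tests: the NT-score–paternal-score correlation is `ρ/√2`
(the NT haplotype is a random half of the maternal score), slightly
below the full-score correlation `ρ`.

**LD** is a block copula: SNPs in a block share a frequency and copy a
block-driver allele with probability `√r`, giving pairwise haplotype
correlation `r`; blocks are unlinked and transmitted whole (no
within-meiosis recombination), so transmission truth stays exact. This
is deliberately minimal — enough LD to exercise clumping, not a
coalescent model.

**Weight distributions**: `normal` (a polygenic tail with many
near-zero effects), `uniform`, `laplace`, `single_snp` (the
single-locus analogue), and `gws` (|w| ~ U(0.5, 1.5), random sign) —
a genome-wide-significant-style panel in which every SNP is
individually a usable instrument. Per-SNP diagnostics (Wald ratios,
Cochran's Q, MR-Egger) are only meaningful in that regime and the
calibration studies use it; with `normal` weights the small-|w| SNPs
are near-null instruments and their ratios are sign-unstable.

**What the simulator does not emulate**: realistic LD decay and allele
frequency spectra, genotyping/imputation error, population
stratification with structured PCs (PC covariates are pure noise
columns), informative missingness, and selection. Passing tests
demonstrate the statistical machinery under the assumed causal
structure, not robustness to those data pathologies.

## Duo resolution (haplotypes)

With hard-call dosages, the transmitted maternal allele is forced
whenever mother or child is homozygous, or the child is heterozygous
with a homozygous mother; a homozygous father resolves the remaining
het/het case. The only irreducible ambiguity (mother het, child het,
father het or absent) is handled by policy: expected dosage 0.5
(default) or dropping the site. Impossible configurations are flagged
`mendel_error`; SNPs whose error rate exceeds 1% (configurable) are
excluded, standard trio-QC practice.

Two honest caveats, both verified by simulation and asserted at their
measured values: (i) the 0.5 expectation is the symmetric prior, while
the true conditional expectation at an ambiguous site is `1−p`, so the
policy is slightly miscalibrated per site; (ii) the ambiguity error
does **not** vanish with panel size — signal and error variance both
scale linearly in the number of SNPs — so the resolved-NT score
correlates ≈ 0.87 (duo) / 0.94 (trio) with the truth regardless of
panel size. Crucially this attenuates instrument *strength*, not
estimator *consistency*: the same (noisy) instrument appears in both
TSLS stages, so the ratio is unaffected in expectation when paternal
direct effects are absent.

## Instruments (prs)

Harmonisation resolves swapped alleles (dosage re-oriented, weight sign
kept), strand complements, and palindromic A/T–C/G SNPs, which are
dropped when the cohort frequency is in (0.4, 0.6) and otherwise
matched by effect-allele frequency when the table provides one.
Clumping is greedy over ascending (p, id) with an r² cap inside a
physical window; row order never matters. Scores mean-impute sporadic
missing dosages per SNP. Within-stratum standardisation (e.g. maternal
BMI by 1-year age band) merges strata below 10 individuals into the
nearest label before z-scoring, and refuses zero-variance strata.

## Estimators and inference

All linear algebra is explicit (numpy closed forms) so the exact
identities hold to machine precision: single-instrument TSLS equals the
Wald ratio; TSLS with covariates equals the ratio of
covariate-residualised coefficients (Frisch–Waugh). TSLS SEs use the
standard IV form with structural residuals (HC1 sandwich optional);
first-stage partial F uses `R²(n−k_c−k−1)/((1−R²)k)`; F < 10 warns,
never errors. The ratio estimator's Taylor SE defaults to first order
(`se_zy²/β_zx² + β_zy²se_zx²/β_zx⁴`), second order adds the
cross-variance term.

Models one–three are fitted on the intersection complete-case sample
over the union of all three covariate sets, so their estimates are
directly comparable.

**MV-vs-MR difference test.** Families are resampled with replacement;
both the model-three OLS and the TSLS estimates are recomputed in every
replicate (implemented through weighted cross-moments, algebraically
identical to refitting and fast enough for calibration studies), and
`z = (β_mv − β_mr)/√(se_mv² + se_mr² − 2·cov_boot)` with the analytic
variances and the bootstrap covariance (default 1000 replicates, seed
recorded). Calibration was verified by simulation: at n ≥ 2000 with an
instrument of realistic strength the null rejection rate is ~5–6%; at
n = 1000 the analytic TSLS variance is conservative in finite samples
and the test under-rejects — the calibration studies therefore run at
n = 2000.

**Between-SNP Cochran's Q** uses inverse-variance weights from the
delta variance evaluated at the *pooled* estimate, including the
shared-sample covariance between the numerator and denominator slopes,
iterated to a fixed point (the modified-Q construction). Plugging the
noisy per-SNP `β_zy` into the weight instead makes each SNP's SE
co-vary with its own error and leaves Q severely conservative (mean
≈ 16 on 29 df in simulation).

**MR-Egger** regresses per-SNP outcome coefficients on exposure
coefficients (weights `1/se_zy²`, all SNPs oriented to positive
exposure effect) with a free intercept; the residual scale is
multiplicative, floored at 1.

**Meta-analysis** is inverse-variance fixed-effects with Q, I² =
max(0, (Q−df)/Q)·100, and DerSimonian–Laird as a sensitivity flag; the
pooled ratio estimator applies the Taylor SE to fixed-effects-pooled
numerator and denominator coefficients.

Other diagnostics: Pearson instrument-confounder screen with
0.05/0.001/1e−5 star bands; effect-size-stratified MR over |weight|
quintiles with an inverse-variance trend test on bin medians; a
product-term sex-interaction test (MV or second-stage); parental PRS
correlations with Fisher z CIs.

## Simulation sizes and numerical choices

The validation studies use: 1,000 trios × 1,000 SNPs for transmission
properties; 200 replicates of n = 5,000 for parameter recovery
(α = 0.05, β_m = 0.1, γ_c = 0.2, λ = 0.5); 100 replicates of n = 5,000
for the collider contrast (γ_p = 0.3); 500 replicates at n = 2,000
(null) and 100 at n = 5,000 (power, confounding +0.2, α = 0.1) for the
difference test; 500 replicates of an n = 8,000, 30-SNP `gws` panel for
Egger/Q calibration. These sizes give Monte-Carlo error comfortably
inside the asserted tolerances while keeping the full suite around two
minutes. Degenerate inputs are explicit errors: zero-variance strata,
constant instruments, collinear covariates (named), zero harmonisation
survivors, `β_zx = 0` ratios, non-positive difference variance.

## Known limitations

- The duoHMM-style phasing of real studies is replaced by deterministic
  duo resolution; sites it cannot resolve are scored at their
  symmetric-prior expectation, which mildly attenuates the instrument
  (quantified above) but does not bias the estimators under random
  mating without paternal direct effects.
- The per-SNP diagnostic suite presumes individually strong SNPs; it is
  not calibrated for highly polygenic panels with near-zero weights.
- PC adjustment is the only population-structure control; no mixed
  models, kinship pruning or imputation are implemented.
- A multi-cohort analysis is emulated by declaring strata within one
  phenotype table; cohort-specific data wrangling is out of scope.
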