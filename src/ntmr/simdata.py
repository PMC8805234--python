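"""Synthetic mother–father–offspring cohorts with known causal structure.

The generator emulates the statistical structure of a mother–offspring
Mendelian-randomisation study of maternal adiposity: a maternal exposure
(BMI analogue) driven by a polygenic score plus a familial confounder,
offspring outcomes with a maternal causal effect, direct offspring and
paternal genetic effects, optional assortative mating and optional block
LD.  Transmission truth (which maternal allele each child inherited) is
recorded exactly, so the haplotype-resolution and instrument-building
stages can be validated against it.

All phenotypes are emitted in standard-deviation units (internally
z-scored after generation), matching how such cohorts report effect
sizes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "TrioCohort",
    "draw_snp_panel",
    "simulate_parents",
    "transmit",
    "generate_phenotypes",
    "simulate_cohort",
    "small_weight_pleiotropy",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of one simulated cohort.

    Variance-scale parameters are on the standardised (SD-unit) scale:
    ``alpha`` is the proportion of exposure variance explained by the
    standardised maternal PRS, ``beta_m`` the maternal causal effect on
    each outcome in SD per SD, ``gamma_c``/``gamma_p`` the offspring and
    paternal direct genetic effects per PRS SD, and ``lambda_x`` /
    ``lambda_y`` the effect of the latent familial confounder on
    exposure and outcome.  ``rho_am`` is the target spousal PRS
    correlation induced by assortative mating.
    """

    n_trios: int = 5000
    n_snps: int = 100
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    weight_dist: str = "normal"  # normal | uniform | laplace | single_snp
    alpha: float = 0.05
    beta_m: Mapping[str, float] | float = field(
        default_factory=lambda: {"bw": 0.14, "bmi15": 0.0}
    )
    gamma_c: float = 0.2
    gamma_p: float = 0.2
    lambda_x: float = 0.5
    lambda_y: float = 0.5
    rho_am: float = 0.0
    ld_block_size: int = 1
    ld_within_r: float = 0.8
    missing_rate: float = 0.0
    n_pcs: int = 4
    sex_beta_diff: float = 0.0
    pleiotropy: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"allele_freq_range must lie within (0,1): {(lo, hi)}")
        if self.n_trios < 1:
            raise ValueError("n_trios must be >= 1")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not (0.0 <= self.rho_am < 1.0):
            raise ValueError("rho_am must be in [0, 1)")
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError("alpha must be in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_within_r <= 1.0):
            raise ValueError("ld_within_r must be in [0, 1]")
        if self.alpha + self.lambda_x**2 >= 1.0:
            raise ValueError("alpha + lambda_x^2 must be < 1 (residual exposure variance)")
        if self.pleiotropy is not None and len(self.pleiotropy) != self.n_snps:
            raise ValueError("pleiotropy vector length must equal n_snps")

    @property
    def outcome_effects(self) -> dict[str, float]:
        if isinstance(self.beta_m, Mapping):
            return dict(self.beta_m)
        return {"y": float(self.beta_m)}


@dataclass
class TrioCohort:
    """One simulated cohort with exact transmission truth.

    Haplotype arrays have shape ``(n, 2, m)`` (individual, haplotype,
    SNP); dosage arrays have shape ``(n, m)``.  ``truth`` holds the
    realised polygenic scores and the latent confounder per family.
    """

    snp_meta: pd.DataFrame
    maternal_haplotypes: np.ndarray
    paternal_haplotypes: np.ndarray
    offspring_genotype: np.ndarray
    maternal_transmitted: np.ndarray
    maternal_nontransmitted: np.ndarray
    paternal_transmitted: np.ndarray
    truth: pd.DataFrame

    @property
    def n_trios(self) -> int:
        return self.maternal_haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.maternal_haplotypes.shape[2]

    @property
    def maternal_genotype(self) -> np.ndarray:
        return self.maternal_haplotypes.sum(axis=1)

    @property
    def paternal_genotype(self) -> np.ndarray:
        return self.paternal_haplotypes.sum(axis=1)

    @property
    def family_ids(self) -> pd.Index:
        return self.truth.index


def _block_layout(n_snps: int, block_size: int) -> np.ndarray:
    """Assign each SNP to an LD block (block index per SNP)."""
    return np.arange(n_snps) // block_size


def _genotype_covariance(freq: np.ndarray, block: np.ndarray, ld_r: float,
                         block_size: int) -> "np.ndarray":
    """Theoretical covariance matrix of genotype dosages under the block model."""
    var = 2.0 * freq * (1.0 - freq)
    if block_size == 1:
        return np.diag(var)
    cov = np.zeros((len(freq), len(freq)))
    same = block[:, None] == block[None, :]
    sd = np.sqrt(var)
    cov[same] = (ld_r * np.outer(sd, sd))[same]
    np.fill_diagonal(cov, var)
    return cov


def draw_snp_panel(config: SimConfig, rng: np.random.Generator | None = None
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw a SNP panel and true per-allele effect weights.

    Frequencies are uniform on ``allele_freq_range`` (shared within an
    LD block so the block-copula preserves marginals).  Weights come
    from ``weight_dist`` and are rescaled so the population variance of
    the raw maternal PRS is 1; the standardised PRS then explains
    exactly ``alpha`` of exposure variance by construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.n_snps
    block = _block_layout(m, config.ld_block_size)
    n_blocks = block.max() + 1
    lo, hi = config.allele_freq_range
    block_freq = rng.uniform(lo, hi, size=n_blocks)
    freq = block_freq[block]

    if config.weight_dist == "normal":
        w = rng.normal(size=m)
    elif config.weight_dist == "uniform":
        w = rng.uniform(-1.0, 1.0, size=m)
    elif config.weight_dist == "laplace":
        w = rng.laplace(size=m)
    elif config.weight_dist == "single_snp":
        w = np.zeros(m)
        w[rng.integers(m)] = 1.0
    elif config.weight_dist == "gws":
        # genome-wide-significant-style panel: effects clearly nonzero
        # (|w| uniform in [0.5, 1.5]) with random sign, so every SNP is
        # individually a usable instrument
        w = rng.uniform(0.5, 1.5, size=m) * rng.choice([-1.0, 1.0], size=m)
    else:
        raise ValueError(f"unknown weight_dist: {config.weight_dist!r}")

    cov = _genotype_covariance(freq, block, config.ld_within_r, config.ld_block_size)
    prs_var = float(w @ cov @ w)
    if prs_var > 0:
        w = w / np.sqrt(prs_var)

    # effect / other alleles: distinct bases per SNP
    ea_idx = rng.integers(0, 4, size=m)
    oa_idx = (ea_idx + rng.integers(1, 4, size=m)) % 4
    chrom = (block % 22) + 1
    # positions: 10 kb spacing, restarting per chromosome
    pos = np.zeros(m, dtype=int)
    for c in np.unique(chrom):
        sel = chrom == c
        pos[sel] = 10_000 * (1 + np.arange(sel.sum()))
    snp_meta = pd.DataFrame(
        {
            "id": [f"rs{i:06d}" for i in range(m)],
            "chrom": chrom,
            "pos": pos,
            "ea": _BASES[ea_idx],
            "oa": _BASES[oa_idx],
            "freq": freq,
            "block": block,
            "weight": w,
        }
    )
    return snp_meta, w


def _draw_haplotypes(rng: np.random.Generator, n: int, snp_meta: pd.DataFrame,
                     config: SimConfig) -> np.ndarray:
    """Draw (n, 2, m) phased haplotypes under the block-copula LD model."""
    freq = snp_meta["freq"].to_numpy()
    m = len(freq)
    if config.ld_block_size == 1:
        return (rng.random((n, 2, m)) < freq).astype(np.int8)
    block = snp_meta["block"].to_numpy()
    n_blocks = block.max() + 1
    block_freq = np.array([freq[block == b][0] for b in range(n_blocks)])
    # driver allele per (individual, haplotype, block); each SNP copies
    # its block driver with probability sqrt(r) else draws fresh, giving
    # pairwise haplotype correlation r within a block.
    driver = (rng.random((n, 2, n_blocks)) < block_freq).astype(np.int8)
    copy_p = np.sqrt(config.ld_within_r)
    fresh = (rng.random((n, 2, m)) < freq).astype(np.int8)
    take_driver = rng.random((n, 2, m)) < copy_p
    return np.where(take_driver, driver[:, :, block], fresh).astype(np.int8)


def simulate_parents(config: SimConfig, snp_meta: pd.DataFrame,
                     rng: np.random.Generator | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Draw phased parental haplotypes, with optional assortative mating.

    Couples are formed by rank-matching maternal and paternal PRS each
    perturbed with Gaussian noise whose variance is chosen by the
    closed-form attenuation ``sigma^2 = var(PRS) * (1 - rho) / rho`` so
    the realised spousal PRS correlation approximates ``rho_am``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_trios
    mat = _draw_haplotypes(rng, n, snp_meta, config)
    pat = _draw_haplotypes(rng, n, snp_meta, config)
    rho = config.rho_am
    if rho > 0:
        w = snp_meta["weight"].to_numpy()
        prs_m = mat.sum(axis=1) @ w
        prs_p = pat.sum(axis=1) @ w
        s2 = np.var(prs_m)
        if s2 == 0:
            raise ValueError("assortative mating requested but PRS has zero variance")
        sigma = np.sqrt(s2 * (1.0 - rho) / rho)
        u = prs_m + rng.normal(scale=sigma, size=n)
        v = prs_p + rng.normal(scale=sigma, size=n)
        rank_u = np.argsort(np.argsort(u))
        pat = pat[np.argsort(v)[rank_u]]
        achieved = float(np.corrcoef(prs_m, pat.sum(axis=1) @ w)[0, 1])
        if achieved < rho - 0.05:
            raise ValueError(
                f"assortative mating target rho_am={rho} unattainable; "
                f"achieved spousal PRS correlation {achieved:.3f}"
            )
    return mat, pat


def transmit(maternal_haplotypes: np.ndarray, paternal_haplotypes: np.ndarray,
             snp_meta: pd.DataFrame, rng: np.random.Generator
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mendelian transmission: one haplotype per parent per LD block.

    Whole blocks are transmitted without recombination, so transmission
    truth within a block is exact.  Returns (offspring genotype,
    maternal transmitted, paternal transmitted) dosage arrays.
    """
    n, _, m = maternal_haplotypes.shape
    block = snp_meta["block"].to_numpy()
    n_blocks = block.max() + 1
    pick_m = rng.integers(0, 2, size=(n, n_blocks))[:, block]
    pick_p = rng.integers(0, 2, size=(n, n_blocks))[:, block]
    idx = np.arange(n)[:, None]
    snp = np.arange(m)[None, :]
    t_m = maternal_haplotypes[idx, pick_m, snp]
    t_p = paternal_haplotypes[idx, pick_p, snp]
    return (t_m + t_p).astype(np.int8), t_m.astype(np.int8), t_p.astype(np.int8)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardise a zero-variance vector")
    return (x - x.mean()) / sd


def small_weight_pleiotropy(weights: np.ndarray, fraction: float = 0.5,
                            effect_sd: float = 0.02, seed: int = 0,
                            directional: bool = True) -> np.ndarray:
    """Per-SNP direct maternal effects concentrated in small-|weight| SNPs.

    Returns a vector of per-allele outcome effects that is nonzero only
    for the ``fraction`` of SNPs with the smallest absolute instrument
    weight — the scenario in which weakly associated variants carry
    horizontal pleiotropy.  With ``directional=True`` (default) the
    effects are half-normal and aligned with the exposure-increasing
    allele, so small-effect instruments are biased away from zero — the
    pattern an effect-size-stratified analysis is designed to reveal;
    ``directional=False`` gives balanced (mean-zero) pleiotropy.
    """
    rng = np.random.default_rng(seed)
    m = len(weights)
    k = max(1, int(round(fraction * m)))
    order = np.argsort(np.abs(weights), kind="stable")
    delta = np.zeros(m)
    raw = rng.normal(scale=effect_sd, size=k)
    if directional:
        raw = np.abs(raw) * np.sign(weights[order[:k]])
    delta[order[:k]] = raw
    return delta


def generate_phenotypes(config: SimConfig, cohort: TrioCohort,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the phenotype/covariate table for a cohort.

    Exposure: ``x = sqrt(alpha) * z(PRS_mat) + lambda_x * C + noise``,
    standardised.  Each outcome ``y_<label>``: maternal causal effect on
    the exposure plus offspring/paternal direct genetic effects,
    confounding, optional per-SNP maternal pleiotropy and optional
    sex-specific causal effect, standardised.  Residual variances are
    allocated so total variance is 1; a negative allocation raises.

    Observed confounder columns are the latent confounder ``c_true``
    plus two noisy proxies (``conf1``, ``conf2``, reliability ~0.7) and
    a paternal exposure analogue (``paternal_bmi``) sharing the same
    familial confounder.  Missingness is completely at random at
    ``missing_rate`` on exposure, outcomes and confounders.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = cohort.n_trios
    w = cohort.snp_meta["weight"].to_numpy()

    z_mat = _zscore(cohort.maternal_genotype @ w)
    z_pat = _zscore(cohort.paternal_genotype @ w)
    z_child = _zscore(cohort.offspring_genotype.astype(float) @ w)

    c = rng.normal(size=n)
    a = np.sqrt(config.alpha)
    resid_x = 1.0 - config.alpha - config.lambda_x**2
    if resid_x <= 0:
        raise ValueError("negative residual exposure variance")
    x_raw = a * z_mat + config.lambda_x * c + np.sqrt(resid_x) * rng.normal(size=n)
    x = _zscore(x_raw)

    # paternal exposure analogue (model-three covariate)
    xp_raw = a * z_pat + config.lambda_x * c + np.sqrt(resid_x) * rng.normal(size=n)
    paternal_bmi = _zscore(xp_raw)

    sex = rng.integers(0, 2, size=n)  # 1 = female
    maternal_age = rng.normal(29.0, 4.5, size=n)
    child_age = rng.normal(size=n)
    pcs = rng.normal(size=(n, config.n_pcs))

    pleio = np.zeros(n)
    if config.pleiotropy is not None:
        m_geno = cohort.maternal_genotype.astype(float)
        pleio = (m_geno - m_geno.mean(axis=0)) @ np.asarray(config.pleiotropy)

    data: dict[str, np.ndarray] = {
        "maternal_bmi": x,
        "paternal_bmi": paternal_bmi,
        "maternal_age": maternal_age,
        "child_sex": sex.astype(float),
        "child_age": child_age,
        "c_true": c,
        "conf1": _zscore(c + rng.normal(scale=0.7, size=n)),
        "conf2": _zscore(c + rng.normal(scale=0.7, size=n)),
    }
    for j in range(config.n_pcs):
        data[f"pc{j + 1}"] = pcs[:, j]

    for label, beta in config.outcome_effects.items():
        sys = (
            beta * x
            + config.gamma_c * z_child
            + config.gamma_p * z_pat
            + config.lambda_y * c
            + pleio
            + config.sex_beta_diff * x * (sex - 0.5)
        )
        var_sys = float(np.var(sys))
        resid = 1.0 - var_sys
        if resid <= 0:
            raise ValueError(
                f"negative residual outcome variance for {label!r} (systematic "
                f"variance {var_sys:.3f} >= 1)"
            )
        y = sys + np.sqrt(resid) * rng.normal(size=n)
        data[f"y_{label}"] = _zscore(y)

    pheno = pd.DataFrame(data, index=cohort.family_ids)

    if config.missing_rate > 0:
        missable = ["maternal_bmi", "paternal_bmi", "conf1", "conf2"] + [
            f"y_{lbl}" for lbl in config.outcome_effects
        ]
        for col in missable:
            mask = rng.random(n) < config.missing_rate
            pheno.loc[mask, col] = np.nan
    return pheno


def simulate_cohort(config: SimConfig
                    ) -> tuple[TrioCohort, pd.DataFrame]:
    """Simulate a full cohort and its phenotype table, deterministic in seed."""
    rng = np.random.default_rng(config.seed)
    snp_meta, w = draw_snp_panel(config, rng)
    mat, pat = simulate_parents(config, snp_meta, rng)
    child, t_m, t_p = transmit(mat, pat, snp_meta, rng)
    nt = mat.sum(axis=1).astype(np.int8) - t_m
    fam = pd.Index([f"fam{i:06d}" for i in range(config.n_trios)], name="family_id")
    truth = pd.DataFrame(
        {
            "prs_mat": mat.sum(axis=1) @ w,
            "prs_pat": pat.sum(axis=1) @ w,
            "prs_child": child.astype(float) @ w,
            "prs_transmitted": t_m.astype(float) @ w,
            "prs_nontransmitted": nt.astype(float) @ w,
        },
        index=fam,
    )
    cohort = TrioCohort(
        snp_meta=snp_meta,
        maternal_haplotypes=mat,
        paternal_haplotypes=pat,
        offspring_genotype=child,
        maternal_transmitted=t_m,
        maternal_nontransmitted=nt,
        paternal_transmitted=t_p,
        truth=truth,
    )
    pheno = generate_phenotypes(config, cohort, rng)
    cohort.truth["c_true"] = pheno["c_true"]
    return cohort, pheno


def config_to_dict(config: SimConfig) -> dict:
    """JSON-serialisable view of a SimConfig (for run manifests)."""
    d = dataclasses.asdict(config)
    if d.get("pleiotropy") is not None:
        d["pleiotropy"] = list(np.asarray(d["pleiotropy"], dtype=float))
    if isinstance(d["beta_m"], Mapping):
        d["beta_m"] = dict(d["beta_m"])
    d["allele_freq_range"] = list(d["allele_freq_range"])
    return d
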