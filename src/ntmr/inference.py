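"""Combining and interrogating estimates: fixed-effects meta-analysis,
the pooled ratio estimator, the MV-vs-MR bootstrap-covariance z-test,
between-SNP heterogeneity and MR-Egger pleiotropy diagnostics, the
instrument-validity screen, effect-size-stratified MR, the offspring-sex
interaction test, and the parental PRS correlation check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import (
    DEFAULT_MODELS,
    EstimateRecord,
    RatioInput,
    _design,
    mv_regress,
    ratio_estimate,
    tsls,
)
from . import prs as _prs

__all__ = [
    "MetaResult",
    "DifferenceTest",
    "EggerResult",
    "meta_fixed",
    "ratio_meta",
    "difference_z",
    "mv_mr_difference_test",
    "cochran_q_snps",
    "mr_egger",
    "instrument_validity_screen",
    "effect_size_stratified_mr",
    "sex_interaction",
    "parental_prs_correlation",
]


@dataclass
class MetaResult:
    """Pooled estimate with heterogeneity summary."""

    pooled_beta: float
    pooled_se: float
    q: float
    df: int
    p_q: float
    i2: float
    members: list[EstimateRecord] = field(default_factory=list)

    @property
    def p(self) -> float:
        return float(2.0 * sps.norm.sf(abs(self.pooled_beta / self.pooled_se)))


def meta_fixed(records: list[EstimateRecord], method: str = "fixed") -> MetaResult:
    """Inverse-variance-weighted meta-analysis across strata.

    ``method='fixed'`` (default) assumes a common effect;
    ``method='dersimonian_laird'`` is the random-effects sensitivity
    variant.  Heterogeneity is summarised by Cochran's Q (df = k − 1)
    and I² = max(0, (Q − df)/Q) · 100.
    """
    if not records:
        raise ValueError("no records to pool")
    b = np.array([r.beta for r in records], dtype=float)
    se = np.array([r.se for r in records], dtype=float)
    if (se <= 0).any():
        raise ValueError("non-positive standard error in meta-analysis input")
    w = 1.0 / se**2
    pooled = float((w * b).sum() / w.sum())
    q = float((w * (b - pooled) ** 2).sum())
    df = len(b) - 1
    p_q = float(sps.chi2.sf(q, df)) if df > 0 else 1.0
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0
    if method == "dersimonian_laird":
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
        w_star = 1.0 / (se**2 + tau2)
        pooled = float((w_star * b).sum() / w_star.sum())
        pooled_se = float(np.sqrt(1.0 / w_star.sum()))
    elif method == "fixed":
        pooled_se = float(np.sqrt(1.0 / w.sum()))
    else:
        raise ValueError(f"unknown meta-analysis method {method!r}")
    return MetaResult(pooled, pooled_se, q, df, p_q, i2, list(records))


def ratio_meta(inputs: list[RatioInput], order: str = "first",
               outcome: str = "") -> EstimateRecord:
    """Pooled ratio estimator across samples.

    The instrument→outcome and instrument→exposure coefficients are each
    pooled by fixed-effects meta-analysis; the ratio and its
    Taylor-series SE are then applied to the pooled coefficients.
    """
    if not inputs:
        raise ValueError("no samples to pool")

    def pool(vals, ses):
        w = 1.0 / np.asarray(ses, dtype=float) ** 2
        return float((w * np.asarray(vals)).sum() / w.sum()), float(np.sqrt(1.0 / w.sum()))

    zy, se_zy = pool([i.beta_zy for i in inputs], [i.se_zy for i in inputs])
    zx, se_zx = pool([i.beta_zx for i in inputs], [i.se_zx for i in inputs])
    if zx == 0:
        raise ZeroDivisionError("pooled denominator beta_zx = 0")
    n = int(sum(i.n for i in inputs))
    rec = ratio_estimate(RatioInput(zy, se_zy, zx, se_zx, n), order=order, outcome=outcome)
    rec.method = "ratio_meta"
    return rec


@dataclass
class DifferenceTest:
    """z-test for a difference between MV and MR estimates of one outcome."""

    beta_mv: float
    beta_mr: float
    se_mv: float
    se_mr: float
    cov_boot: float
    z: float
    p: float
    n_boot: int
    seed: int


def difference_z(beta_mv: float, var_mv: float, beta_mr: float, var_mr: float,
                 cov: float) -> tuple[float, float]:
    """z statistic and two-sided p for the MV − MR difference given the
    estimator variances and their covariance."""
    var_diff = var_mv + var_mr - 2.0 * cov
    if var_diff <= 0:
        raise ValueError(
            f"non-positive variance of the MV−MR difference "
            f"(var_mv={var_mv:.3g}, var_mr={var_mr:.3g}, cov={cov:.3g})"
        )
    z = (beta_mv - beta_mr) / np.sqrt(var_diff)
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def _batched_solve(M: np.ndarray, r: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(M, r[..., None])[..., 0]
    except np.linalg.LinAlgError:
        return np.einsum("bij,bj->bi", np.linalg.pinv(M), r)


def mv_mr_difference_test(pheno: pd.DataFrame, outcome: str,
                          instrument: pd.Series, mv_model: str = "three",
                          mr_covariates: list[str] | None = None,
                          exposure: str = "maternal_bmi",
                          models: dict[str, list[str]] | None = None,
                          n_boot: int = 1000, seed: int = 0) -> DifferenceTest:
    """Test whether the confounder-adjusted MV estimate differs from MR.

    Families are resampled with replacement; in every replicate both the
    MV (model three by default) and TSLS estimates are recomputed on the
    resampled data, and the empirical covariance of the replicate pairs
    enters ``z = (b_mv − b_mr) / sqrt(var_mv + var_mr − 2 cov)`` with the
    analytic estimator variances.  Replicate estimates are evaluated
    through weighted cross-moments, which is algebraically identical to
    refitting on the resampled rows.
    """
    if n_boot < 500:
        raise ValueError("n_boot must be >= 500")
    models = models or DEFAULT_MODELS
    mr_covariates = mr_covariates or []
    rec_mv = mv_regress(pheno, outcome, model=mv_model, exposure=exposure, models=models)
    rec_mr = tsls(pheno, outcome, instrument, covariates=mr_covariates, exposure=exposure)

    rng = np.random.default_rng(seed)
    fams = pheno.index
    n = len(fams)
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).astype(float)

    # --- MV replicates from weighted cross-moments -----------------------
    all_cols = sorted({c for spec in models.values() for c in spec})
    cc_mv = pheno[[outcome, exposure] + all_cols].dropna()
    covs_mv = models[mv_model]
    A = np.column_stack(
        [cc_mv[outcome].to_numpy(float), cc_mv[exposure].to_numpy(float)]
        + [cc_mv[c].to_numpy(float) for c in covs_mv]
        + [np.ones(len(cc_mv))]
    )
    pos = fams.get_indexer(cc_mv.index)
    W = counts[:, pos]
    p_mv = A.shape[1]
    P = (A[:, :, None] * A[:, None, :]).reshape(len(A), -1)
    M = (W @ P).reshape(n_boot, p_mv, p_mv)
    design_ix = np.arange(1, p_mv)  # exposure, covariates, intercept
    S = M[:, design_ix[:, None], design_ix[None, :]]
    r = M[:, design_ix, 0]
    beta_mv_b = _batched_solve(S, r)[:, 0]

    # --- MR (TSLS) replicates --------------------------------------------
    df = pheno[[outcome, exposure] + mr_covariates].copy()
    df["_z"] = pd.Series(instrument).reindex(df.index)
    df = df.dropna()
    B = np.column_stack(
        [df[outcome].to_numpy(float), df[exposure].to_numpy(float),
         df["_z"].to_numpy(float)]
        + [df[c].to_numpy(float) for c in mr_covariates]
        + [np.ones(len(df))]
    )
    pos_mr = fams.get_indexer(df.index)
    W_mr = counts[:, pos_mr]
    p_mr = B.shape[1]
    Pm = (B[:, :, None] * B[:, None, :]).reshape(len(B), -1)
    Mm = (W_mr @ Pm).reshape(n_boot, p_mr, p_mr)
    c_ix = np.arange(3, p_mr)  # covariates + intercept
    # residualise instrument moments on covariates within each replicate:
    # beta_iv = (z~'y) / (z~'x) with z~ = z - C (C'C)^-1 C'z (weighted)
    Scc = Mm[:, c_ix[:, None], c_ix[None, :]]
    gz = _batched_solve(Scc, Mm[:, c_ix, 2])
    zy = Mm[:, 2, 0] - np.einsum("bi,bi->b", gz, Mm[:, c_ix, 0])
    zx = Mm[:, 2, 1] - np.einsum("bi,bi->b", gz, Mm[:, c_ix, 1])
    beta_mr_b = zy / zx

    ok = np.isfinite(beta_mv_b) & np.isfinite(beta_mr_b)
    cov_boot = float(np.cov(beta_mv_b[ok], beta_mr_b[ok])[0, 1])
    z, p = difference_z(rec_mv.beta, rec_mv.se**2, rec_mr.beta, rec_mr.se**2, cov_boot)
    return DifferenceTest(
        beta_mv=rec_mv.beta, beta_mr=rec_mr.beta, se_mv=rec_mv.se,
        se_mr=rec_mr.se, cov_boot=cov_boot, z=z, p=p,
        n_boot=int(ok.sum()), seed=seed,
    )


def cochran_q_snps(wald_table: pd.DataFrame, iterations: int = 3
                   ) -> tuple[float, int, float]:
    """Between-SNP heterogeneity of Wald ratios: Q, df, chi-square p.

    Q = sum w_j (b_j − b_ivw)² with inverse-variance weights.  When the
    per-SNP table carries the shared-sample slope-error covariance
    (``cov_zxzy``), the weights use the modified delta variance with the
    second-order term evaluated at the pooled estimate,
    ``(se_zy² − 2 b̂ cov + b̂² se_zx²) / beta_zx²``, iterated to a fixed
    point — evaluating it at the noisy per-SNP ratio instead makes each
    SNP's SE inflate exactly when its error is large and leaves Q
    conservative.
    """
    if len(wald_table) < 2:
        raise ValueError("need >= 2 SNPs for Cochran's Q")
    b = wald_table["wald"].to_numpy(float)
    w = 1.0 / wald_table["se"].to_numpy(float) ** 2
    df = len(b) - 1
    if "cov_zxzy" in wald_table.columns:
        bzx = wald_table["beta_zx"].to_numpy(float)
        se_zy = wald_table["se_zy"].to_numpy(float)
        se_zx = wald_table["se_zx"].to_numpy(float)
        cov = wald_table["cov_zxzy"].to_numpy(float)
        for _ in range(iterations):
            b0 = (w * b).sum() / w.sum()
            var = (se_zy**2 - 2 * b0 * cov + b0**2 * se_zx**2) / bzx**2
            w = 1.0 / np.maximum(var, np.finfo(float).tiny)
    b_ivw = (w * b).sum() / w.sum()
    q = float((w * (b - b_ivw) ** 2).sum())
    return q, df, float(sps.chi2.sf(q, df))


@dataclass
class EggerResult:
    intercept: float
    intercept_se: float
    slope: float
    slope_se: float

    @property
    def p_intercept(self) -> float:
        return float(2.0 * sps.norm.sf(abs(self.intercept / self.intercept_se)))

    @property
    def p_slope(self) -> float:
        return float(2.0 * sps.norm.sf(abs(self.slope / self.slope_se)))


def mr_egger(wald_table: pd.DataFrame) -> EggerResult:
    """MR-Egger regression for directional pleiotropy.

    Inverse-variance-weighted (1/se_zy²) regression of per-SNP outcome
    coefficients on exposure coefficients with a free intercept, after
    orienting every SNP so its exposure coefficient is positive.  A
    nonzero intercept indicates directional pleiotropy.
    """
    if len(wald_table) < 3:
        raise ValueError("MR-Egger needs >= 3 SNPs")
    bx = wald_table["beta_zx"].to_numpy(float).copy()
    by = wald_table["beta_zy"].to_numpy(float).copy()
    se = wald_table["se_zy"].to_numpy(float)
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1
    if np.allclose(bx, bx[0]):
        raise ValueError("exposure coefficients all equal: Egger slope not identified")
    w = 1.0 / se**2
    X = np.column_stack([np.ones(len(bx)), bx])
    WX = X * w[:, None]
    XtWX_inv = np.linalg.inv(X.T @ WX)
    beta = XtWX_inv @ (WX.T @ by)
    resid = by - X @ beta
    dof = max(len(bx) - 2, 1)
    scale = float((w * resid**2).sum()) / dof
    # multiplicative random-effects scale, floored at 1 as is conventional
    cov = XtWX_inv * max(scale, 1.0)
    return EggerResult(
        intercept=float(beta[0]), intercept_se=float(np.sqrt(cov[0, 0])),
        slope=float(beta[1]), slope_se=float(np.sqrt(cov[1, 1])),
    )


def instrument_validity_screen(score: pd.Series,
                               risk_factors: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of the instrument with candidate risk factors.

    Mirrors the convention of starring p < 0.05 (*), < 0.001 (**) and
    < 1e-5 (***).  Constant columns are skipped with a note.
    """
    rows = []
    for col in risk_factors.columns:
        both = pd.concat([score.rename("s"), risk_factors[col].rename("f")], axis=1).dropna()
        if both["f"].nunique() <= 1:
            rows.append(dict(factor=col, n=len(both), r=np.nan, p=np.nan,
                             stars="", note="constant column skipped"))
            continue
        r, p = sps.pearsonr(both["s"], both["f"])
        stars = "***" if p < 1e-5 else "**" if p < 1e-3 else "*" if p < 0.05 else ""
        rows.append(dict(factor=col, n=len(both), r=float(r), p=float(p),
                         stars=stars, note=""))
    return pd.DataFrame(rows)


def effect_size_stratified_mr(weights: pd.DataFrame, dosages: pd.DataFrame,
                              pheno: pd.DataFrame, outcome: str,
                              n_bins: int = 5,
                              covariates: list[str] | None = None,
                              exposure: str = "maternal_bmi"
                              ) -> tuple[list[EstimateRecord], dict]:
    """MR within quantile bins of |weight|, plus a weighted trend test.

    SNPs are partitioned into ``n_bins`` quantile bins of absolute
    weight; a sub-score instruments each bin's MR.  The trend is an
    inverse-variance-weighted regression of the per-bin estimate on the
    bin median |weight|.  Larger estimates in smaller-weight bins (a
    negative trend) suggest pleiotropy concentrated in weakly
    associated SNPs.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    absw = weights["weight"].abs()
    try:
        bins = pd.qcut(absw.rank(method="first"), n_bins, labels=False)
    except ValueError as err:
        raise ValueError(f"cannot form {n_bins} non-empty weight bins") from err
    records = []
    medians = []
    for b in range(n_bins):
        sub = weights[bins.to_numpy() == b]
        if sub.empty:
            raise ValueError(f"empty weight bin {b}")
        sv = _prs.score(dosages, sub)
        rec = tsls(pheno, outcome, sv.score, covariates=covariates, exposure=exposure,
                   stratum=f"bin{b}")
        rec.method = "tsls_bin"
        rec.extra["bin"] = b
        rec.extra["median_abs_weight"] = float(sub["weight"].abs().median())
        records.append(rec)
        medians.append(rec.extra["median_abs_weight"])
    b_est = np.array([r.beta for r in records])
    w = 1.0 / np.array([r.se for r in records]) ** 2
    if np.unique(medians).size < 2:
        # identical bin weights: no gradient to regress on
        trend = dict(slope=np.nan, se=np.nan, p=np.nan)
        return records, trend
    X = np.column_stack([np.ones(n_bins), np.asarray(medians)])
    WX = X * w[:, None]
    XtWX_inv = np.linalg.inv(X.T @ WX)
    coef = XtWX_inv @ (WX.T @ b_est)
    slope, slope_se = float(coef[1]), float(np.sqrt(XtWX_inv[1, 1]))
    trend = dict(slope=slope, se=slope_se,
                 p=float(2.0 * sps.norm.sf(abs(slope / slope_se))))
    return records, trend


def sex_interaction(pheno: pd.DataFrame, outcome: str,
                    exposure: str = "maternal_bmi",
                    instrument: pd.Series | None = None,
                    covariates: list[str] | None = None,
                    sex_col: str = "child_sex") -> tuple[float, float, float]:
    """Offspring-sex interaction: product-term coefficient, SE and p.

    With ``instrument=None`` the product term enters the multivariable
    model; otherwise it enters the second stage of the MR model (the
    exposure replaced by its first-stage fitted value).
    """
    covariates = covariates or []
    cols = [outcome, exposure, sex_col] + covariates
    df = pheno[cols].copy()
    if instrument is not None:
        df["_z"] = pd.Series(instrument).reindex(df.index)
    df = df.dropna()
    if df[sex_col].nunique() < 2:
        raise ValueError("both sexes must be present for the interaction test")
    y = df[outcome].to_numpy(float)
    sex = df[sex_col].to_numpy(float)
    if instrument is None:
        xx = df[exposure].to_numpy(float)
    else:
        Z1 = _design(df, ["_z"] + covariates)
        g, _ = np.linalg.lstsq(Z1, df[exposure].to_numpy(float), rcond=None)[:2]
        xx = Z1 @ g
    X = np.column_stack([np.ones(len(df)), xx, sex, xx * sex]
                        + [df[c].to_numpy(float) for c in covariates])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / max(len(df) - X.shape[1], 1)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    b, se = float(beta[3]), float(np.sqrt(cov[3, 3]))
    return b, se, float(2.0 * sps.norm.sf(abs(b / se)))


def _pearson_ci(r: float, n: int) -> tuple[float, float]:
    z = np.arctanh(r)
    h = 1.959963984540054 / np.sqrt(n - 3)
    return float(np.tanh(z - h)), float(np.tanh(z + h))


def parental_prs_correlation(nt_score: pd.Series, full_score: pd.Series,
                             paternal_score: pd.Series) -> pd.DataFrame:
    """Correlation of maternal NT and full PRS with the paternal PRS.

    Under random mating both correlations should be null; assortative
    mating induces positive correlation in both (each maternal
    haplotype contributes to mate choice).
    """
    pat = pd.Series(paternal_score).dropna()
    if pat.empty:
        raise ValueError("no paternal scores available")
    rows = []
    for name, s in (("nt_vs_paternal", nt_score), ("full_vs_paternal", full_score)):
        both = pd.concat([pd.Series(s).rename("a"), pat.rename("b")], axis=1).dropna()
        r, p = sps.pearsonr(both["a"], both["b"])
        lo, hi = _pearson_ci(float(r), len(both))
        rows.append(dict(pair=name, n=len(both), r=float(r), ci_low=lo, ci_high=hi,
                         p=float(p)))
    return pd.DataFrame(rows)
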