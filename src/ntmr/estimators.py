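"""Per-sample estimators: confounder-adjusted multivariable regression,
one-sample two-stage least squares, the Wald/ratio estimator with
Taylor-series standard errors, and first-stage instrument diagnostics.

All effect sizes are in SD-per-SD units when the phenotype table is
standardised (the simulator and pipeline both standardise internally).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DEFAULT_MODELS",
    "EstimateRecord",
    "RatioInput",
    "WeakInstrumentWarning",
    "mv_regress",
    "tsls",
    "ratio_estimate",
    "first_stage_diagnostics",
    "per_snp_wald",
]


class WeakInstrumentWarning(UserWarning):
    pass


#: Covariate sets for the three nested multivariable models: model one
#: adjusts for maternal age, offspring age and offspring sex; model two
#: adds the measured confounders; model three adds the paternal
#: exposure analogue and is the main multivariable model.
DEFAULT_MODELS: dict[str, list[str]] = {
    "one": ["maternal_age", "child_age", "child_sex"],
    "two": ["maternal_age", "child_age", "child_sex", "conf1", "conf2"],
    "three": ["maternal_age", "child_age", "child_sex", "conf1", "conf2", "paternal_bmi"],
}


@dataclass
class EstimateRecord:
    """One estimator result."""

    method: str
    outcome: str
    stratum: str
    beta: float
    se: float
    n: int
    first_stage_r2: float | None = None
    first_stage_f: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")

    @property
    def p(self) -> float:
        return float(2.0 * sps.norm.sf(abs(self.beta / self.se)))

    @property
    def ci(self) -> tuple[float, float]:
        h = 1.959963984540054 * self.se
        return (self.beta - h, self.beta + h)


@dataclass
class RatioInput:
    """Instrument→outcome and instrument→exposure coefficients."""

    beta_zy: float
    se_zy: float
    beta_zx: float
    se_zx: float
    n: int = 0

    def __post_init__(self) -> None:
        if self.se_zy <= 0 or self.se_zx <= 0:
            raise ValueError("standard errors must be positive")


def _design(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in cols])
    return X


def _check_collinear(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate offending columns: those whose removal restores full rank
        offenders = []
        for j in range(1, X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                offenders.append(names[j - 1])
        raise ValueError(f"collinear covariates: {offenders or names}")


def _ols(y: np.ndarray, X: np.ndarray, robust: bool = False
         ) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and covariance (homoskedastic or HC1 sandwich)."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    n, k = X.shape
    XtX_inv = np.linalg.inv(XtX)
    if robust:
        meat = (X * resid[:, None] ** 2).T @ X
        cov = XtX_inv @ meat @ XtX_inv * n / max(n - k, 1)
    else:
        dof = max(n - k, 1)
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * XtX_inv
    return beta, cov


def mv_regress(pheno: pd.DataFrame, outcome: str, model: str = "three",
               exposure: str = "maternal_bmi",
               models: dict[str, list[str]] | None = None,
               extra_covariates: list[str] | None = None,
               robust: bool = False, stratum: str = "all") -> EstimateRecord:
    """Confounder-adjusted multivariable regression (models one–three).

    The complete-case sample is the intersection of non-missing rows
    over the union of all three models' columns, so models one to three
    are fitted on identical samples and their estimates are directly
    comparable.
    """
    models = models or DEFAULT_MODELS
    if model not in models:
        raise ValueError(f"unknown model {model!r}; have {sorted(models)}")
    covs = list(models[model]) + list(extra_covariates or [])
    all_cols = sorted({c for spec in models.values() for c in spec} | set(covs))
    needed = [outcome, exposure] + all_cols
    cc = pheno[needed].dropna()
    if cc.empty:
        raise ValueError("empty complete-case sample")
    y = cc[outcome].to_numpy(dtype=float)
    X = _design(cc, [exposure] + covs)
    _check_collinear(X, [exposure] + covs)
    beta, cov = _ols(y, X, robust=robust)
    se = float(np.sqrt(cov[1, 1]))
    if se == 0:  # outcome identical to exposure: degenerate but defined
        se = np.finfo(float).tiny
    tag = {"one": "mv1", "two": "mv2", "three": "mv3"}.get(model, f"mv_{model}")
    return EstimateRecord(
        method=tag,
        outcome=outcome,
        stratum=stratum,
        beta=float(beta[1]),
        se=se,
        n=len(cc),
    )


def tsls(pheno: pd.DataFrame, outcome: str, instrument: pd.Series,
         covariates: list[str] | None = None, exposure: str = "maternal_bmi",
         robust: bool = False, f_floor: float = 10.0,
         stratum: str = "all") -> EstimateRecord:
    """One-sample two-stage least squares with a polygenic instrument.

    Covariates (e.g. genetic principal components) enter both stages
    identically.  The standard error is the usual IV asymptotic form
    using residuals from the structural equation.  The partial first
    stage R² and F are reported; F below ``f_floor`` emits a
    weak-instrument warning, never an error.
    """
    covariates = covariates or []
    inst = pd.Series(instrument)
    df = pheno[[outcome, exposure] + covariates].copy()
    df["_z"] = inst.reindex(df.index)
    df = df.dropna()
    if df["_z"].nunique() <= 1:
        raise ValueError("instrument is constant on the analysis sample")
    n = len(df)
    y = df[outcome].to_numpy(dtype=float)
    x = df[exposure].to_numpy(dtype=float)
    z = df["_z"].to_numpy(dtype=float)
    C = _design(df, covariates)  # intercept + covariates

    # first stage
    Z1 = np.column_stack([C, z])
    g1, _ = _ols(x, Z1)
    xhat = Z1 @ g1
    W = np.column_stack([xhat, C])
    Wt = np.column_stack([x, C])
    beta, _ = _ols(y, W)
    resid = y - Wt @ beta  # structural residuals (actual exposure)
    k = W.shape[1]
    WtW_inv = np.linalg.inv(W.T @ W)
    if robust:
        meat = (W * resid[:, None] ** 2).T @ W
        cov = WtW_inv @ meat @ WtW_inv * n / max(n - k, 1)
    else:
        sigma2 = float(resid @ resid) / max(n - k, 1)
        cov = sigma2 * WtW_inv
    se = float(np.sqrt(cov[0, 0]))
    r2, f = first_stage_diagnostics(x, z, C[:, 1:] if covariates else None)
    if np.isfinite(f) and f < f_floor:
        warnings.warn(
            f"first-stage F = {f:.2f} below {f_floor}: weak instrument",
            WeakInstrumentWarning,
        )
    return EstimateRecord(
        method="tsls", outcome=outcome, stratum=stratum,
        beta=float(beta[0]), se=se, n=n,
        first_stage_r2=r2, first_stage_f=f,
    )


def first_stage_diagnostics(exposure: np.ndarray, instrument: np.ndarray,
                            covariates: np.ndarray | None = None
                            ) -> tuple[float, float]:
    """Partial R² of the instrument(s) for the exposure, and the F-statistic
    ``F = R² (n − k − 1) / ((1 − R²) k)`` for ``k`` instruments (with the
    effective n reduced by the number of covariates partialled out).
    Returns ``(r2, inf)`` when the instrument explains the exposure
    exactly."""
    x = np.asarray(exposure, dtype=float)
    Z = np.asarray(instrument, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n, k = Z.shape
    n_cov = 0
    if covariates is not None and covariates.size:
        C = np.column_stack([np.ones(len(x)), covariates])
        n_cov = covariates.shape[1]
        x = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
        Z = Z - C @ np.linalg.lstsq(C, Z, rcond=None)[0]
    xc = x - x.mean()
    Zc = Z - Z.mean(axis=0)
    beta = np.linalg.lstsq(Zc, xc, rcond=None)[0]
    ssr = float(((Zc @ beta) ** 2).sum())
    sst = float((xc**2).sum())
    r2 = ssr / sst if sst > 0 else 0.0
    n_eff = n - n_cov
    if r2 >= 1.0:
        return 1.0, np.inf
    f = r2 * (n_eff - k - 1) / ((1.0 - r2) * k)
    return r2, f


def ratio_estimate(inp: RatioInput, order: str = "first", outcome: str = "",
                   stratum: str = "all") -> EstimateRecord:
    """Wald/ratio estimator with a Taylor-series standard error.

    ``beta = beta_zy / beta_zx``.  First-order SE:
    ``sqrt(se_zy²/beta_zx² + beta_zy²·se_zx²/beta_zx⁴)``; the
    second-order form adds the cross-variance term
    ``se_zy²·se_zx²/beta_zx⁴``.
    """
    if inp.beta_zx == 0:
        raise ZeroDivisionError("undefined ratio: beta_zx = 0")
    b = inp.beta_zy / inp.beta_zx
    var = inp.se_zy**2 / inp.beta_zx**2 + inp.beta_zy**2 * inp.se_zx**2 / inp.beta_zx**4
    if order == "second":
        var += inp.se_zy**2 * inp.se_zx**2 / inp.beta_zx**4
    elif order != "first":
        raise ValueError(f"order must be 'first' or 'second', got {order!r}")
    return EstimateRecord(
        method="ratio", outcome=outcome, stratum=stratum,
        beta=float(b), se=float(np.sqrt(var)), n=inp.n,
    )


def per_snp_wald(pheno: pd.DataFrame, outcome: str, dosages: pd.DataFrame,
                 weights: pd.DataFrame | None = None,
                 exposure: str = "maternal_bmi",
                 covariates: list[str] | None = None) -> pd.DataFrame:
    """Per-SNP Wald ratios: (SNP→outcome) / (SNP→exposure), first-order SE.

    Both association coefficients are estimated on the same
    complete-case sample.  When ``weights`` is given, each SNP's dosage
    is oriented so the weight (hence the expected exposure association)
    is positive — the orientation MR-Egger requires.  Monomorphic SNPs
    are dropped with a warning.
    """
    covariates = covariates or []
    df = pheno[[outcome, exposure] + covariates].copy()
    dos = dosages.reindex(df.index)
    keep = df.notna().all(axis=1) & dos.notna().all(axis=1)
    df, dos = df[keep], dos[keep]
    y = df[outcome].to_numpy(dtype=float)
    x = df[exposure].to_numpy(dtype=float)
    if covariates:
        C = _design(df, covariates)
        y = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
        x = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
    rows = []
    n = len(df)
    for snp_id in dos.columns:
        g = dos[snp_id].to_numpy(dtype=float)
        if weights is not None:
            w = weights.set_index("id")["weight"].get(snp_id, 1.0)
            if w < 0:
                g = 2.0 - g
        if g.std() == 0:
            warnings.warn(f"SNP {snp_id} monomorphic; dropped from per-SNP Wald table")
            continue
        gc = g - g.mean()
        vg = float(gc @ gc)
        b_zy = float(gc @ (y - y.mean())) / vg
        b_zx = float(gc @ (x - x.mean())) / vg
        se_zy = np.sqrt(float((((y - y.mean()) - gc * b_zy) ** 2).sum()) / (n - 2) / vg)
        se_zx = np.sqrt(float((((x - x.mean()) - gc * b_zx) ** 2).sum()) / (n - 2) / vg)
        if b_zx == 0:
            warnings.warn(f"SNP {snp_id} has zero exposure association; dropped")
            continue
        # covariance of the two slope errors (shared-sample delta method)
        res_y = (y - y.mean()) - gc * b_zy
        res_x = (x - x.mean()) - gc * b_zx
        cov_zxzy = float(res_y @ res_x) / (n - 2) / vg
        rec = ratio_estimate(RatioInput(b_zy, se_zy, b_zx, se_zx, n), outcome=outcome)
        rows.append(
            dict(id=snp_id, beta_zy=b_zy, se_zy=se_zy, beta_zx=b_zx, se_zx=se_zx,
                 cov_zxzy=cov_zxzy, wald=rec.beta, se=rec.se, n=n)
        )
    return pd.DataFrame(rows)
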