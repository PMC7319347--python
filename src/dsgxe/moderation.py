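"""Covariate-adjusted interaction regression, standardized betas, the
interaction R-squared change, the quadratic robustness check, and BH-FDR.

The core model is ``y ~ Z + X + Z*X + covariates`` where Z is the moderator
(predicted gene expression) and X the environment (SES composite).  The
quadratic robustness refit adds ``X**2`` and ``Z*X**2`` to verify a
significant crossover interaction is not an artifact of imposing a linear
model on a nonlinear environment-outcome relationship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ModelSpec:
    outcome: str
    moderator: str = "pred_expr"  # Z
    environment: str = "ses_composite"  # X
    covariates: tuple[str, ...] = ("age", "sex", "bmi_z", "pc1", "pc2")
    include_quadratic: bool = False

    def __post_init__(self) -> None:
        if self.moderator == self.environment:
            raise ValueError("moderator and environment must differ")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("covariates must be distinct")

    @property
    def interaction(self) -> str:
        return f"{self.moderator}:{self.environment}"


@dataclass
class RegressionFit:
    """OLS solution with full coefficient covariance.

    ``params``/``cov`` are indexed by term name; ``b1``/``b3`` and the
    covariance entries v11/v13/v33 (moderator main effect and interaction)
    feed the regions-of-significance machinery.
    """

    params: pd.Series
    cov: pd.DataFrame
    df_resid: int
    resid_var: float
    r2: float
    pvalues: pd.Series
    nobs: int
    spec: ModelSpec | None = None

    def term(self, name: str) -> float:
        return float(self.params[name])

    def vcov(self, a: str, b: str) -> float:
        return float(self.cov.loc[a, b])


def synthetic_interaction_fit(
    b1: float,
    b3: float,
    v11: float,
    v13: float,
    v33: float,
    df: int,
    b0: float = 0.0,
    b2: float = 0.0,
    moderator: str = "pred_expr",
    environment: str = "ses_composite",
) -> RegressionFit:
    """Build a RegressionFit directly from interaction-model coefficients.

    Useful for running regions-of-significance or PoI on published
    coefficients (the moderator main effect b1, the interaction b3 and the
    covariance entries v11, v13, v33) without access to the underlying data.
    """
    spec = ModelSpec(outcome="y", moderator=moderator, environment=environment)
    names = ["const", moderator, environment, spec.interaction]
    params = pd.Series([b0, b1, b2, b3], index=names)
    cov = pd.DataFrame(0.0, index=names, columns=names)
    cov.loc[moderator, moderator] = v11
    cov.loc[moderator, spec.interaction] = v13
    cov.loc[spec.interaction, moderator] = v13
    cov.loc[spec.interaction, spec.interaction] = v33
    return RegressionFit(
        params=params,
        cov=cov,
        df_resid=df,
        resid_var=np.nan,
        r2=np.nan,
        pvalues=pd.Series(np.nan, index=names),
        nobs=df + len(names),
        spec=spec,
    )


@dataclass
class FDRResult:
    raw: pd.Series
    adjusted: pd.Series
    reject: pd.Series
    q: float


@dataclass
class QuadraticCheck:
    p_x2: float
    p_zx2: float
    p_interaction_augmented: float
    nonlinear_flag: bool


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name columns involved in an exact linear dependence via pivoted QR."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < tol]
    return bad


def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix (const, Z, X, Z:X, covariates[, X^2, Z:X^2]) and outcome."""
    z = data[spec.moderator].astype(float)
    x = data[spec.environment].astype(float)
    cols = {"const": np.ones(len(data)), spec.moderator: z, spec.environment: x,
            spec.interaction: z * x}
    for c in spec.covariates:
        cols[c] = data[c].astype(float)
    if spec.include_quadratic:
        cols[f"{spec.environment}^2"] = x**2
        cols[f"{spec.moderator}:{spec.environment}^2"] = z * x**2
    return pd.DataFrame(cols, index=data.index), data[spec.outcome].astype(float)


def fit_ols(design: pd.DataFrame, y: pd.Series, spec: ModelSpec | None = None) -> RegressionFit:
    """Least squares with full coefficient covariance.

    Raises on exact collinearity, naming the offending columns, and on
    n <= number of parameters.
    """
    X = design.to_numpy(dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need n > n_params (n={n}, params={k})")
    if np.linalg.matrix_rank(X) < k:
        bad = _collinear_columns(X, list(design.columns))
        raise ValueError(f"collinear design columns: {bad}")
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    names = list(design.columns)
    return RegressionFit(
        params=pd.Series(res.params, index=names),
        cov=pd.DataFrame(res.cov_params(), index=names, columns=names),
        df_resid=int(res.df_resid),
        resid_var=float(res.mse_resid),
        r2=float(res.rsquared),
        pvalues=pd.Series(res.pvalues, index=names),
        nobs=n,
        spec=spec,
    )


def fit_model(data: pd.DataFrame, spec: ModelSpec) -> RegressionFit:
    design, y = build_design(data, spec)
    return fit_ols(design, y, spec)


def _zscore(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=1)
    if sd == 0:
        raise ValueError(f"zero-variance column {s.name!r}")
    return (s - s.mean()) / sd


def standardized_betas(data: pd.DataFrame, spec: ModelSpec) -> pd.Series:
    """Standardized coefficients by the standardize-then-multiply convention.

    Z, X, the outcome and continuous covariates are z-scored before fitting
    and the interaction column is the product of the standardized Z and X.
    Binary covariates are left on their 0/1 scale (standardizing a dummy has
    no accepted interpretation).
    """
    std = data.copy()
    for c in (spec.moderator, spec.environment, spec.outcome):
        std[c] = _zscore(data[c].astype(float))
    for c in spec.covariates:
        col = data[c].astype(float)
        if col.nunique() > 2:
            std[c] = _zscore(col)
    fit = fit_model(std, spec)
    return fit.params.drop("const")


def interaction_r2_change(data: pd.DataFrame, spec: ModelSpec) -> tuple[float, float]:
    """R-squared gained by the interaction term, with the partial-F p-value.

    The partial F with one numerator df equals the squared t of the
    interaction coefficient, so the returned p matches the coefficient's
    t-test p exactly.
    """
    full = fit_model(data, spec)
    design, y = build_design(data, spec)
    reduced = fit_ols(design.drop(columns=[spec.interaction]), y)
    dr2 = full.r2 - reduced.r2
    denom = (1.0 - full.r2) / full.df_resid
    if dr2 <= 1e-15:
        return float(max(dr2, 0.0)), 1.0
    if denom <= 0:  # saturated (noiseless) full model
        return float(dr2), 0.0
    f = dr2 / denom
    return float(dr2), float(stats.f.sf(f, 1, full.df_resid))


def quadratic_robustness(
    data: pd.DataFrame, spec: ModelSpec, alpha: float = 0.05
) -> QuadraticCheck:
    """Refit with X^2 and Z*X^2 added; flag nonlinearity if either is significant.

    Also reports whether the Z*X term retains significance in the augmented
    model (a crossover interaction that vanishes once curvature is allowed
    is suspect).
    """
    aug = ModelSpec(
        outcome=spec.outcome,
        moderator=spec.moderator,
        environment=spec.environment,
        covariates=spec.covariates,
        include_quadratic=True,
    )
    fit = fit_model(data, aug)
    p_x2 = float(fit.pvalues[f"{spec.environment}^2"])
    p_zx2 = float(fit.pvalues[f"{spec.moderator}:{spec.environment}^2"])
    return QuadraticCheck(
        p_x2=p_x2,
        p_zx2=p_zx2,
        p_interaction_augmented=float(fit.pvalues[spec.interaction]),
        nonlinear_flag=bool(p_x2 < alpha or p_zx2 < alpha),
    )


def bh_fdr(pvalues, q: float = 0.15) -> FDRResult:
    """Benjamini-Hochberg step-up FDR across a family of p-values.

    Adjusted p_i = min_{j >= i} m * p_(j) / j over the sorted sequence;
    discoveries are adjusted p <= q.
    """
    p = pd.Series(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or p.isna().any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p.to_numpy(), alpha=q, method="fdr_bh")
    return FDRResult(
        raw=p,
        adjusted=pd.Series(adjusted, index=p.index),
        reject=pd.Series(reject, index=p.index),
        q=q,
    )


@dataclass
class ModelTable:
    """Publication-shaped per-model table: term, beta, p, p_fdr + dR2 footer."""

    outcome: str
    table: pd.DataFrame
    r2: float
    dr2: float
    dr2_p: float


def model_table(
    data: pd.DataFrame, spec: ModelSpec, fdr_adjusted: pd.Series | None = None
) -> ModelTable:
    fit = fit_model(data, spec)
    betas = standardized_betas(data, spec)
    terms = [t for t in fit.params.index if t != "const"]
    tab = pd.DataFrame(
        {
            "beta": betas.reindex(terms),
            "p": fit.pvalues.reindex(terms),
        }
    )
    if fdr_adjusted is not None:
        tab["p_fdr"] = fdr_adjusted.reindex(terms)
    dr2, dr2_p = interaction_r2_change(data, spec)
    return ModelTable(outcome=spec.outcome, table=tab, r2=fit.r2, dr2=dr2, dr2_p=dr2_p)
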