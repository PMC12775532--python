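"""Inference layer: Poisson rate regression with exposure offset, model
comparison, GEE for clustered continuous outcomes, Spearman partial
correlation, and Benjamini–Hochberg FDR.

Counts of NP categories per narration are modelled as

    count ~ Poisson(mu),  log mu = X beta + log(words)

so the group coefficients are differences in log incidence *rates* per
word relative to the reference group (NC).  Continuous outcomes
(similarity, perplexity) observed repeatedly per participant are fit by
generalized estimating equations with Gaussian family, identity link
and an exchangeable working correlation, with robust (sandwich)
standard errors.  Model fitting is delegated to statsmodels; this
module owns the design-matrix conventions (reference coding against NC,
covariate centering on the analysis sample), separation flagging,
family-wise FDR bookkeeping and result containers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

SEPARATION_ABS_COEF = 10.0  # |B| beyond this flags quasi-separation


@dataclass(slots=True)
class DesignMatrix:
    """Observation-level design with named columns, intercept first.

    Group enters via indicator columns against the reference level;
    continuous covariates are mean-centered within the analysis sample
    (so the intercept is the log rate of an average-covariate reference
    participant).
    """

    X: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("X shape does not match column names")
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            raise ValueError(
                f"design matrix rank deficient (rank {rank} < {self.X.shape[1]} "
                f"columns: {self.columns})"
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]


def build_design(
    df: pd.DataFrame,
    group_col: str = "group",
    reference: str = "NC",
    covariates: Sequence[str] = (),
    center: bool = True,
    indicator_cols: Sequence[str] = (),
) -> DesignMatrix:
    """Intercept + group indicators (vs ``reference``) + centered covariates."""
    cols = ["Intercept"]
    parts = [np.ones(len(df))]
    levels = [g for g in pd.unique(df[group_col]) if g != reference]
    # stable, reproducible level order
    levels = sorted(levels)
    for lev in levels:
        cols.append(f"{group_col}[{lev}]")
        parts.append((df[group_col] == lev).to_numpy(dtype=float))
    for cov in covariates:
        x = df[cov].to_numpy(dtype=float)
        if center:
            x = x - x.mean()
        cols.append(cov)
        parts.append(x)
    for ind in indicator_cols:
        for lev in sorted(pd.unique(df[ind]))[1:]:
            cols.append(f"{ind}[{lev}]")
            parts.append((df[ind] == lev).to_numpy(dtype=float))
    return DesignMatrix(X=np.column_stack(parts), columns=cols)


@dataclass(slots=True)
class PoissonFit:
    columns: list[str]
    B: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    q: np.ndarray | None
    llf: float
    aic: float
    converged: bool
    separation: list[str]
    offset_used: bool
    n: int

    def table(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"term": self.columns, "B": self.B, "Se": self.se, "z": self.z, "p": self.p}
        )
        if self.q is not None:
            out["q"] = self.q
        return out


def poisson_glm_offset(
    counts: np.ndarray,
    log_exposure: np.ndarray,
    design: DesignMatrix,
    fdr_family: str | None = "model",
) -> PoissonFit:
    """Poisson log-linear rate model with a fixed log-exposure offset.

    Fit by iteratively reweighted least squares (tolerance 1e-10, at
    most 100 iterations).  Coefficients with |B| > 10 are flagged as
    quasi-separated (e.g. a group producing zero instances of a
    category) and reported as-is rather than penalised.  When
    ``fdr_family`` is set, BH q-values are computed over the model's
    non-intercept terms as one family.
    """
    counts = np.asarray(counts, dtype=float)
    log_exposure = np.asarray(log_exposure, dtype=float)
    if counts.shape[0] != design.n or log_exposure.shape[0] != design.n:
        raise ValueError("counts, exposures and design must have equal length")
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    model = sm.GLM(
        counts, design.X, family=sm.families.Poisson(), offset=log_exposure
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation emits overflow warnings
        res = model.fit(maxiter=100, tol=1e-10)
    B = np.asarray(res.params)
    se = np.asarray(res.bse)
    z = np.where(se > 0, B / se, np.nan)
    p = 2 * stats.norm.sf(np.abs(z))
    separation = [c for c, b in zip(design.columns, B) if abs(b) > SEPARATION_ABS_COEF]
    q = None
    if fdr_family is not None:
        q = np.full_like(p, np.nan)
        mask = np.array([c != "Intercept" for c in design.columns]) & np.isfinite(p)
        if mask.any():
            q[mask] = bh_fdr(p[mask], family=fdr_family).q
    return PoissonFit(
        columns=list(design.columns),
        B=B,
        se=se,
        z=z,
        p=p,
        q=q,
        llf=float(res.llf),
        aic=float(res.aic),
        converged=bool(res.converged),
        separation=separation,
        offset_used=True,
        n=design.n,
    )


def compare_models(fit_full: PoissonFit, fit_reduced: PoissonFit) -> dict:
    """Likelihood-ratio test and AIC difference for nested Poisson fits.

    ``delta_aic`` > 0 favours the full model.  Requires the reduced
    model's terms to be a subset of the full model's, on the same data.
    """
    if fit_full.n != fit_reduced.n:
        raise ValueError("fits are not on the same data (different n)")
    if not set(fit_reduced.columns) <= set(fit_full.columns):
        raise ValueError("models are not nested")
    df = len(fit_full.columns) - len(fit_reduced.columns)
    lrt = 2.0 * (fit_full.llf - fit_reduced.llf)
    p = float(stats.chi2.sf(lrt, df)) if df > 0 else 1.0
    return {
        "lrt_stat": float(lrt),
        "df": df,
        "p": p,
        "delta_aic": float(fit_reduced.aic - fit_full.aic),
    }


@dataclass(slots=True)
class GEEFit:
    columns: list[str]
    B: np.ndarray
    se: np.ndarray  # robust (sandwich)
    z: np.ndarray
    p: np.ndarray
    q: np.ndarray | None
    rho: float
    scale: float
    n_clusters: int
    n: int
    converged: bool
    fitted: np.ndarray
    resid: np.ndarray

    def table(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"term": self.columns, "B": self.B, "Se": self.se, "z": self.z, "p": self.p}
        )
        if self.q is not None:
            out["q"] = self.q
        return out


def gee_gaussian_exchangeable(
    y: np.ndarray,
    design: DesignMatrix,
    cluster: np.ndarray,
    fdr_family: str | None = "model",
) -> GEEFit:
    """Marginal Gaussian regression for clustered outcomes.

    Identity link, exchangeable working correlation (moment estimate
    from Pearson residuals), robust sandwich covariance.  With all
    clusters of size one the exchangeable structure is vacuous and the
    coefficients coincide with ordinary least squares.
    """
    y = np.asarray(y, dtype=float)
    cluster = np.asarray(cluster)
    if y.shape[0] != design.n or cluster.shape[0] != design.n:
        raise ValueError("y, cluster and design must have equal length")
    n_clusters = len(np.unique(cluster))
    if n_clusters < 2:
        raise ValueError("need at least two clusters")
    # exactly-fitting outcomes make the moment estimates degenerate
    # (zero dispersion); return the OLS solution directly
    ols = np.linalg.lstsq(design.X, y, rcond=None)[0]
    resid_ols = y - design.X @ ols
    if float(np.sum(resid_ols**2)) <= 1e-12 * max(1.0, float(np.sum(y**2))):
        nan = np.full(len(ols), np.nan)
        return GEEFit(
            columns=list(design.columns),
            B=ols,
            se=np.zeros(len(ols)),
            z=nan,
            p=nan,
            q=nan.copy() if fdr_family is not None else None,
            rho=0.0,
            scale=0.0,
            n_clusters=n_clusters,
            n=design.n,
            converged=True,
            fitted=design.X @ ols,
            resid=resid_ols,
        )
    cov = sm.cov_struct.Exchangeable()
    model = sm.GEE(
        y, design.X, groups=cluster, family=sm.families.Gaussian(), cov_struct=cov
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=50, ctol=1e-8)
    B = np.asarray(res.params)
    se = np.asarray(res.bse)  # robust by default
    z = np.where(se > 0, B / se, np.nan)
    p = 2 * stats.norm.sf(np.abs(z))
    q = None
    if fdr_family is not None:
        q = np.full_like(p, np.nan)
        mask = np.array([c != "Intercept" for c in design.columns]) & np.isfinite(p)
        if mask.any():
            q[mask] = bh_fdr(p[mask], family=fdr_family).q
    fitted = np.asarray(res.fittedvalues)
    return GEEFit(
        columns=list(design.columns),
        B=B,
        se=se,
        z=z,
        p=p,
        q=q,
        rho=float(cov.dep_params),
        scale=float(res.scale),
        n_clusters=n_clusters,
        n=design.n,
        converged=bool(getattr(res, "converged", True)),
        fitted=fitted,
        resid=y - fitted,
    )


def deviance_gof(fit: GEEFit, scale: float | None = None) -> dict:
    """Gaussian deviance goodness of fit.

    Deviance is the residual sum of squares divided by the dispersion.
    With the model's own Pearson-moment dispersion (the default) the
    deviance-per-df is 1 by construction and the summary is purely
    descriptive; passing a known or externally estimated ``scale``
    turns it into a genuine misfit diagnostic (deviance_per_df >> 1
    indicates a misspecified mean).
    """
    rss = float(np.sum(fit.resid**2))
    dispersion = float(scale) if scale is not None else fit.scale
    df = fit.n - len(fit.columns)
    deviance = rss / dispersion
    return {
        "deviance": deviance,
        "df": df,
        "deviance_per_df": deviance / df if df > 0 else np.nan,
        "dispersion": dispersion,
    }


@dataclass(slots=True)
class PartialCorrResult:
    rho: float
    p: float
    n: int
    controlled: list[str]
    q: float | None = None


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=0)


def spearman_partial(
    x: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray | None = None,
    covariate_names: Sequence[str] = (),
) -> PartialCorrResult:
    """Spearman partial correlation of x and y given covariates Z.

    All variables are rank-transformed; ranked x and y are residualised
    on ranked Z (with intercept) and the Pearson correlation of the
    residuals is reported, with a t-approximation p-value on
    n - 2 - k degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    if Z is None or (hasattr(Z, "size") and np.asarray(Z).size == 0):
        k = 0
        rx, ry = _rank(x), _rank(y)
    else:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[0] != n:
            Z = Z.T
        k = Z.shape[1]
        if n <= k + 2:
            raise ValueError("too few observations for the covariate set")
        rz = np.column_stack([np.ones(n), _rank(Z)])
        rx = _rank(x) - rz @ np.linalg.lstsq(rz, _rank(x), rcond=None)[0]
        ry = _rank(y) - rz @ np.linalg.lstsq(rz, _rank(y), rcond=None)[0]
    # residuals that are numerically zero (x or y fully explained by Z)
    # carry no partial association
    tol = 1e-10 * n
    if np.std(rx) < tol or np.std(ry) < tol:
        return PartialCorrResult(rho=0.0, p=1.0, n=n, controlled=list(covariate_names))
    rho = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - 2 - k
    rho_c = min(max(rho, -0.999999999), 0.999999999)
    t = rho_c * np.sqrt(dof / (1.0 - rho_c**2))
    p = float(2 * stats.t.sf(abs(t), dof))
    return PartialCorrResult(rho=rho, p=p, n=n, controlled=list(covariate_names))


@dataclass(slots=True)
class FDRResult:
    p: np.ndarray
    q: np.ndarray
    family: str


def bh_fdr(p: np.ndarray | Sequence[float], family: str = "") -> FDRResult:
    """Benjamini–Hochberg step-up q-values over one test family.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1; the monotone
    step-up adjustment delegated to statsmodels.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return FDRResult(p=p, q=p.copy(), family=family)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    return FDRResult(p=p, q=np.asarray(q), family=family)
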