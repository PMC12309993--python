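"""Compositional statistics on proportion tables.

Cell-type proportions live on the simplex, so they cannot enter a linear
model untouched: the parts are negatively coupled by the sum-to-one
constraint.  This module provides the two covariate constructions used
downstream — the centered log-ratio (CLR) transform, which maps the
simplex to an unconstrained zero-sum space, and principal-component
scores of the proportions — plus Dirichlet regression for testing how
composition responds to design factors.

Dirichlet regression uses the common parameterization: every
concentration parameter is an exponential-linear function of the
covariates, alpha_ic = exp(x_i' beta_c).  The log-likelihood

    sum_i [ ln G(sum_c a_ic) - sum_c ln G(a_ic) + sum_c (a_ic - 1) ln y_ic ]

is maximized by quasi-Newton with an analytic gradient; Wald z and
p-values come from the inverse observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, gammaln
from scipy.stats import norm
from sklearn.decomposition import PCA
from statsmodels.tools.numdiff import approx_hess2

from .deconv import ProportionTable
from .design import build_design_matrix

__all__ = ["CompositionCovariates", "DirichletFit", "clr_transform",
           "pca_props", "fit_dirichlet", "dirichlet_loglik"]


@dataclass
class CompositionCovariates:
    """Samples x components covariate block derived from proportions."""

    values: pd.DataFrame
    kind: str
    explained_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("clr", "pca", "raw"):
            raise ValueError("kind must be 'clr', 'pca' or 'raw'")
        if self.kind == "clr":
            if np.abs(self.values.sum(axis=1).to_numpy()).max() > 1e-9:
                raise ValueError("CLR rows must sum to 0")

    @property
    def component_labels(self) -> list:
        return self.values.columns.tolist()


def _interior(Y: np.ndarray, pseudo: float | None) -> np.ndarray:
    """Push boundary compositions into the open simplex.

    With ``pseudo`` set, adds the pseudocount and re-closes.  Otherwise
    applies the standard compression y* = (y (n-1) + 1/C) / n only when
    zeros (or ones) are present.
    """
    Y = np.asarray(Y, dtype=float)
    n, C = Y.shape
    if pseudo is not None:
        Y = Y + pseudo
        return Y / Y.sum(axis=1, keepdims=True)
    if (Y <= 0).any() or (Y >= 1).any():
        Y = (Y * (n - 1) + 1.0 / C) / n
    return Y


def clr_transform(props: ProportionTable, pseudo: float | None = None
                  ) -> CompositionCovariates:
    """Centered log-ratio coordinates z_k = ln(p_k / g(p)).

    g(p) is the geometric mean of the parts, so each row sums to zero.
    Zeros are handled first (compression by default, or an additive
    ``pseudo`` count); anything still non-positive is an error.
    """
    Y = _interior(props.df.to_numpy(), pseudo)
    if (Y <= 0).any():
        raise ValueError("proportions must be strictly positive after "
                         "zero handling")
    L = np.log(Y)
    Z = L - L.mean(axis=1, keepdims=True)
    values = pd.DataFrame(Z, index=props.df.index, columns=props.df.columns)
    return CompositionCovariates(values=values, kind="clr")


def pca_props(props: ProportionTable, n_components: int = 1
              ) -> CompositionCovariates:
    """Principal-component scores of column-centered proportions.

    The default single component follows the covariate use downstream
    ("PC1").  Components are ordered by explained variance.
    """
    P = props.df.to_numpy()
    n, C = P.shape
    if n_components > C:
        raise ValueError(f"n_components={n_components} exceeds the "
                         f"{C} cell types")
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    k = min(n_components, n)
    pca = PCA(n_components=k)
    with np.errstate(invalid="ignore"):
        scores = pca.fit_transform(P)
    evr_k = np.nan_to_num(pca.explained_variance_ratio_)  # 0 if no variance
    if k < n_components:  # fewer samples than requested components
        scores = np.hstack([scores, np.zeros((n, n_components - k))])
        evr = np.concatenate([evr_k, np.zeros(n_components - k)])
    else:
        evr = evr_k
    cols = [f"PC{i + 1}" for i in range(n_components)]
    values = pd.DataFrame(scores, index=props.df.index, columns=cols)
    return CompositionCovariates(values=values, kind="pca",
                                 explained_variance=evr)


@dataclass
class DirichletFit:
    """Maximum-likelihood Dirichlet regression fit (common parameterization)."""

    beta: pd.DataFrame       # covariates x cell types
    se: pd.DataFrame
    z: pd.DataFrame
    pvalues: pd.DataFrame
    loglik: float
    vcov: np.ndarray         # over vec(beta), covariate-major ordering
    converged: bool
    n_obs: int
    grad_norm: float = np.nan  # max |score| at the reported optimum

    def alpha(self, X: pd.DataFrame) -> pd.DataFrame:
        """Fitted concentration parameters for a design matrix."""
        A = np.exp(X.to_numpy() @ self.beta.to_numpy())
        return pd.DataFrame(A, index=X.index, columns=self.beta.columns)


def dirichlet_loglik(Y: np.ndarray, A: np.ndarray) -> float:
    """Dirichlet log-likelihood of compositions Y under concentrations A."""
    return float(np.sum(gammaln(A.sum(axis=1)) - gammaln(A).sum(axis=1)
                        + ((A - 1.0) * np.log(Y)).sum(axis=1)))


def fit_dirichlet(props: ProportionTable, design: pd.DataFrame,
                  terms=None, pseudo: float | None = None,
                  maxiter: int = 500) -> DirichletFit:
    """Fit a Dirichlet regression of proportions on design covariates.

    With ``terms`` given, a treatment-coded design matrix (with
    intercept) is built from the design table; otherwise ``design`` is
    taken as a ready numeric design matrix.  Initialization is
    moment-based on the intercept (pooled mean/variance give a starting
    precision); optimization is L-BFGS with analytic gradient.
    """
    if not design.index.equals(props.df.index):
        raise ValueError("design rows must align with the proportion table")
    X_df = build_design_matrix(design, terms) if terms is not None else design
    X = X_df.to_numpy(dtype=float)
    Y = _interior(props.df.to_numpy(), pseudo)
    logY = np.log(Y)
    n, C = Y.shape
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    # moment start: alpha_c = mean_c * precision, on the intercept
    mean = Y.mean(axis=0)
    var = Y.var(axis=0, ddof=1) if n > 1 else np.full(C, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = mean * (1 - mean) / var - 1.0
    prec = prec[np.isfinite(prec) & (prec > 0)]
    s0 = float(np.exp(np.mean(np.log(prec)))) if prec.size else 1.0
    B0 = np.zeros((p, C))
    const_cols = np.where(np.ptp(X, axis=0) < 1e-12)[0]
    if const_cols.size:
        j = const_cols[0]
        B0[j, :] = np.log(np.maximum(mean * s0, 1e-6)) / X[0, j]

    def unpack(b):
        return b.reshape(p, C)

    def nll(b):
        A = np.exp(np.clip(X @ unpack(b), -30.0, 30.0))
        return -dirichlet_loglik(Y, A)

    def grad(b):
        A = np.exp(np.clip(X @ unpack(b), -30.0, 30.0))
        G = A * (digamma(A.sum(axis=1))[:, None] - digamma(A) + logY)
        return -(X.T @ G).ravel()

    res = minimize(nll, B0.ravel(), jac=grad, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9})
    B = unpack(res.x)
    gmax = float(np.max(np.abs(grad(res.x))))
    converged = bool(res.success or gmax < 1e-5)
    if not converged:
        warnings.warn(f"Dirichlet fit did not converge: {res.message} "
                      f"(max |grad| = {gmax:.2e})", UserWarning)

    H = approx_hess2(res.x, nll)
    try:
        vcov = np.linalg.inv(H)
        se_flat = np.sqrt(np.maximum(np.diag(vcov), 0.0))
        if (np.diag(vcov) <= 0).any():
            warnings.warn("observed information not positive definite "
                          "(separation-like degeneracy?); some SEs undefined",
                          UserWarning)
            se_flat[np.diag(vcov) <= 0] = np.nan
    except np.linalg.LinAlgError:
        warnings.warn("observed information is singular; SEs undefined",
                      UserWarning)
        vcov = np.full((p * C, p * C), np.nan)
        se_flat = np.full(p * C, np.nan)

    cell_types = props.df.columns
    beta = pd.DataFrame(B, index=X_df.columns, columns=cell_types)
    se = pd.DataFrame(se_flat.reshape(p, C), index=X_df.columns,
                      columns=cell_types)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = beta / se
    pvals = 2.0 * norm.sf(np.abs(zstat.to_numpy()))
    return DirichletFit(
        beta=beta, se=se, z=zstat,
        pvalues=pd.DataFrame(pvals, index=X_df.columns, columns=cell_types),
        loglik=-float(res.fun), vcov=vcov, converged=converged, n_obs=n,
        grad_norm=gmax,
    )
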