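"""Per-gene negative-binomial GLM differential expression.

Counts for gene g in sample i are modeled as NB(mu_gi, phi_g) with a
log link and a size-factor offset:

    ln mu_gi = ln s_i + x_i' beta_g,    Var = mu + phi mu^2.

Size factors are median-of-ratios.  The per-gene dispersion phi_g is
estimated by maximum likelihood (profiled over beta) from a
method-of-moments start; coefficients are fit by IRLS.  Inference is a
Wald test per contrast with Benjamini-Hochberg adjustment across genes.
There is no dispersion-trend shrinkage and no fold-change shrinkage:
the estimator is deliberately self-contained, with null-calibration
checks as the guardrail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import norm

from .multitest import bh_adjust
from .design import cell_means_design

__all__ = ["DEResult", "filter_genes", "size_factors", "fit_de",
           "bh_adjust", "compare_models"]

_LOG2 = np.log(2.0)


def filter_genes(counts: pd.DataFrame, min_count: int = 10,
                 min_samples: int = 4) -> pd.DataFrame:
    """Keep genes with more than ``min_count`` reads in >= ``min_samples`` samples.

    The comparison is strict (a count of exactly ``min_count`` does not
    qualify).  Raises if nothing survives.
    """
    keep = (counts > min_count).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError("no genes pass the expression filter")
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    s_i is the median over reference genes (positive in every sample) of
    counts_gi divided by the gene's geometric mean.  If no gene is
    positive everywhere, falls back to library-size ratios (normalized
    to geometric mean 1) with a warning.
    """
    C = counts.to_numpy(dtype=float)
    pos = (C > 0).all(axis=1)
    if pos.any():
        logC = np.log(C[pos])
        log_geo = logC.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logC - log_geo, axis=0))
    else:
        warnings.warn("no gene is positive in all samples; using "
                      "library-size ratios", UserWarning)
        lib = C.sum(axis=0)
        sf = lib / np.exp(np.mean(np.log(lib)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _nb_loglik(y, mu, phi) -> float:
    if phi < 1e-10:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    a = 1.0 / phi
    return float(np.sum(gammaln(y + a) - gammaln(a) - gammaln(y + 1)
                        + y * np.log(mu / (mu + a)) + a * np.log(a / (a + mu))))


def _irls(y, X, offset, phi, beta=None, max_iter=100, tol=1e-8):
    """IRLS for the NB log-link GLM at fixed dispersion.

    Converges on the relative change of the log-likelihood (equivalently
    the deviance at fixed phi).
    """
    if beta is None:
        mu = y + 0.5
        eta = np.log(mu)
    else:
        eta = np.clip(offset + X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        W = mu / (1.0 + phi * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * W
        A = XtW @ X
        b = XtW @ z
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(A, b, rcond=None)[0]
        eta = np.clip(offset + X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        ll = _nb_loglik(y, mu, phi)
        if abs(ll - ll_old) <= tol * (abs(ll_old) + 0.1):
            converged = True
            break
        ll_old = ll
    return beta, mu, ll, converged


def _fit_gene(y, X, offset, max_iter=100, tol=1e-8,
              phi_bounds=(1e-8, 100.0)):
    """Full per-gene fit: Poisson start, moment phi, profiled MLE phi."""
    n, p = X.shape
    beta, mu, ll0, conv0 = _irls(y, X, offset, 0.0, max_iter=max_iter, tol=tol)
    # method-of-moments dispersion from the Poisson fit
    denom = float(np.sum(mu ** 2))
    phi_mom = float(np.sum((y - mu) ** 2 - mu)) / denom if denom > 0 else 0.0
    lo, hi = phi_bounds
    phi_mom = min(max(phi_mom, lo), hi)

    state = {"beta": beta}

    def negll(logphi):
        b, _, ll, _ = _irls(y, X, offset, float(np.exp(logphi)),
                            beta=state["beta"], max_iter=50, tol=tol)
        state["beta"] = b
        return -ll

    res = minimize_scalar(negll, bounds=(np.log(lo), np.log(hi)),
                          method="bounded",
                          options={"xatol": 1e-3, "maxiter": 50})
    phi = float(np.exp(res.x))
    beta, mu, ll, conv = _irls(y, X, offset, phi, beta=state["beta"],
                               max_iter=max_iter, tol=tol)
    if ll0 >= ll:  # Poisson boundary wins
        phi, ll = 0.0, ll0
        beta, mu, _, conv = _irls(y, X, offset, 0.0, max_iter=max_iter, tol=tol)
        conv = conv or conv0
    W = mu / (1.0 + phi * mu)
    XtW = X.T * W
    try:
        cov = np.linalg.inv(XtW @ X)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        conv = False
    return beta, cov, phi, mu, ll, conv


@dataclass
class DEResult:
    """Differential-expression results keyed by contrast name.

    Each frame has columns gene, baseMean, log2FC, lfcSE, stat, pvalue,
    padj (padj computed across the genes in this result).  Genes whose
    fit failed carry NaN statistics.
    """

    results: dict
    dispersions: pd.Series
    size_factors: pd.Series
    design: pd.DataFrame
    converged: pd.Series

    def n_significant(self, contrast: str, alpha: float = 0.05) -> int:
        padj = self.results[contrast]["padj"]
        return int((padj < alpha).sum())


def fit_de(counts: pd.DataFrame, design: pd.DataFrame,
           contrasts: dict | None = None,
           sf: pd.Series | None = None,
           max_iter: int = 100, tol: float = 1e-8) -> DEResult:
    """Per-gene NB GLM over a (filtered) count matrix.

    ``design`` is a numeric design matrix aligned with the count
    columns; ``contrasts`` maps names to contrast vectors over its
    columns (default: one unit contrast per column).  Effects are
    reported as log2 fold changes; Wald p-values are BH-adjusted per
    contrast across genes, with NaN passthrough for failed fits.
    """
    if not design.index.equals(counts.columns):
        raise ValueError("design rows must align with count columns")
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (drop collinear "
                         "covariates, e.g. keep a subset of CLR components)")
    if contrasts is None:
        contrasts = {}
        for j, col in enumerate(design.columns):
            vec = np.zeros(X.shape[1])
            vec[j] = 1.0
            contrasts[str(col)] = vec
    if sf is None:
        sf = size_factors(counts)
    offset = np.log(sf.to_numpy(dtype=float))
    Y = counts.to_numpy(dtype=float)
    G = Y.shape[0]

    names = list(contrasts)
    cvecs = [np.asarray(contrasts[nm], dtype=float) for nm in names]
    est = np.full((G, len(names)), np.nan)
    se = np.full((G, len(names)), np.nan)
    phis = np.full(G, np.nan)
    conv = np.zeros(G, dtype=bool)
    for g in range(G):
        beta, cov, phi, mu, ll, ok = _fit_gene(Y[g], X, offset,
                                               max_iter=max_iter, tol=tol)
        phis[g] = phi
        conv[g] = ok
        if not ok or not np.isfinite(cov).all():
            continue
        for j, c in enumerate(cvecs):
            var = float(c @ cov @ c)
            if var <= 0:
                continue
            est[g, j] = float(c @ beta)
            se[g, j] = np.sqrt(var)

    base_mean = (Y / sf.to_numpy()[None, :]).mean(axis=1)
    results = {}
    for j, nm in enumerate(names):
        stat = est[:, j] / se[:, j]
        pval = 2.0 * norm.sf(np.abs(stat))
        frame = pd.DataFrame({
            "gene": counts.index,
            "baseMean": base_mean,
            "log2FC": est[:, j] / _LOG2,
            "lfcSE": se[:, j] / _LOG2,
            "stat": stat,
            "pvalue": pval,
            "padj": bh_adjust(pval),
        }).set_index("gene")
        results[nm] = frame
    return DEResult(
        results=results,
        dispersions=pd.Series(phis, index=counts.index, name="dispersion"),
        size_factors=sf,
        design=design,
        converged=pd.Series(conv, index=counts.index, name="converged"),
    )


def compare_models(counts: pd.DataFrame, groups: pd.Series, baseline,
                   covariate_sets: dict, sf: pd.Series | None = None,
                   **kwargs) -> dict:
    """Run the cell-means group model once per covariate representation.

    ``covariate_sets`` maps a representation name (e.g. "none", "clr")
    to a samples x components covariate frame, or None for the
    unadjusted model.  All runs share the gene universe and size
    factors, so results are directly comparable.
    """
    if sf is None:
        sf = size_factors(counts)
    out = {}
    for name, cov in covariate_sets.items():
        X, contrasts = cell_means_design(groups, baseline, cov)
        out[name] = fit_de(counts, X, contrasts, sf=sf, **kwargs)
    return out
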