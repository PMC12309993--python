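"""Marker-restricted, variance-weighted NNLS deconvolution of bulk samples.

Each bulk sample's relative abundances over the marker genes are modeled
as y_g ~ sum_k c_k * S_k * theta_gk with c_k >= 0, where theta_gk is a
cell type's relative expression of gene g and S_k its RNA content per
nucleus.  The fit is an iteratively re-weighted non-negative least
squares: genes whose signature is noisy across reference subjects, or
which fit poorly, are down-weighted via

    w_g = 1 / (r_g^2 + sum_k c_k^2 sigma2_gk S_k^2 + eps).

Reported proportions are RNA fractions p_k = c_k S_k / sum_j c_j S_j —
the share of transcripts originating from each type, not cell counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .refbuild import Signature

__all__ = ["ProportionTable", "DeconvFit", "estimate_proportions",
           "deconvolve_cohort"]


@dataclass
class ProportionTable:
    """Samples x cell types RNA-fraction proportions (rows sum to 1)."""

    proportions: pd.DataFrame

    def __post_init__(self) -> None:
        P = self.proportions.to_numpy(dtype=float)
        if (P < -1e-12).any():
            raise ValueError("proportions must be non-negative")
        if np.abs(P.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("each row must sum to 1 within 1e-9")

    @property
    def df(self) -> pd.DataFrame:
        return self.proportions

    @property
    def sample_ids(self) -> list:
        return self.proportions.index.tolist()

    @property
    def cell_types(self) -> list:
        return self.proportions.columns.tolist()


@dataclass
class DeconvFit:
    """Converged deconvolution with per-gene diagnostics.

    weights and residuals are marker genes x samples frames at the final
    iterate; n_iterations and converged are per sample.
    """

    proportions: ProportionTable
    weights: pd.DataFrame
    residuals: pd.DataFrame
    n_iterations: pd.Series
    converged: pd.Series


def _solve_sample(y: np.ndarray, X: np.ndarray, sigma_term: np.ndarray,
                  max_iter: int, tol: float, eps: float):
    """Iteratively re-weighted NNLS for one sample.

    sigma_term is the marker x type matrix sigma2_gk * S_k^2, so the
    per-gene variance contribution is sigma_term @ c^2.
    """
    c, _ = nnls(X, y)
    converged = False
    n_iter = 0
    w = np.ones_like(y)
    for n_iter in range(1, max_iter + 1):
        r = y - X @ c
        w = 1.0 / (r ** 2 + sigma_term @ (c ** 2) + eps)
        sw = np.sqrt(w)
        c_new, _ = nnls(X * sw[:, None], y * sw)
        denom = max(np.max(np.abs(c)), 1e-300)
        step = np.max(np.abs(c_new - c)) / denom
        c = c_new
        if step < tol:
            converged = True
            break
    r = y - X @ c
    return c, w, r, n_iter, converged


def estimate_proportions(bulk: pd.DataFrame, signature: Signature,
                         max_iter: int = 1000, tol: float = 1e-6,
                         eps: float = 1e-8) -> DeconvFit:
    """Weighted-NNLS proportions for every column of a bulk count matrix.

    ``bulk`` holds raw counts (genes x samples) and must contain every
    signature marker gene; only marker rows enter the fit, scaled to
    relative abundance by the sample's total counts over those markers
    so the model is depth-free and unaffected by non-marker rows.
    """
    genes = signature.theta.index
    missing = genes.difference(bulk.index)
    if len(missing):
        raise ValueError(f"bulk is missing marker genes: {missing[:5].tolist()}")
    if (bulk.sum(axis=0) <= 0).any():
        dead = bulk.columns[bulk.sum(axis=0) <= 0]
        raise ValueError(f"all-zero bulk column(s): {dead.tolist()}")
    lib = bulk.loc[genes].sum(axis=0).to_numpy(dtype=float)
    zero = np.where(lib <= 0)[0]
    if zero.size:
        raise ValueError(
            f"no marker reads in bulk column(s): {bulk.columns[zero].tolist()}")

    S = signature.cell_sizes.to_numpy(dtype=float)
    theta = signature.theta.to_numpy(dtype=float)
    X = theta * S[None, :]
    sigma_term = signature.sigma2.to_numpy(dtype=float) * (S ** 2)[None, :]
    # duplicate signature columns make the system singular; NNLS still
    # returns a (smallest-index-preferring) solution, so warn only.
    K = X.shape[1]
    for a in range(K):
        for b in range(a + 1, K):
            if np.allclose(X[:, a], X[:, b]):
                warnings.warn(
                    f"signature columns {signature.cell_types[a]!r} and "
                    f"{signature.cell_types[b]!r} are identical; proportions "
                    "between them are not identifiable", UserWarning)

    Y = bulk.loc[genes].to_numpy(dtype=float) / lib[None, :]
    props, W, R, iters, conv = [], [], [], [], []
    for j, sample in enumerate(bulk.columns):
        c, w, r, n_iter, ok = _solve_sample(Y[:, j], X, sigma_term,
                                            max_iter, tol, eps)
        scaled = c * S
        total = scaled.sum()
        if total <= 0:
            raise ValueError(f"sample {sample!r}: deconvolution returned an "
                             "all-zero solution")
        props.append(scaled / total)
        W.append(w)
        R.append(r)
        iters.append(n_iter)
        conv.append(ok)

    prop_df = pd.DataFrame(props, index=bulk.columns, columns=signature.cell_types)
    return DeconvFit(
        proportions=ProportionTable(prop_df),
        weights=pd.DataFrame(np.column_stack(W), index=genes, columns=bulk.columns),
        residuals=pd.DataFrame(np.column_stack(R), index=genes, columns=bulk.columns),
        n_iterations=pd.Series(iters, index=bulk.columns, name="n_iterations"),
        converged=pd.Series(conv, index=bulk.columns, name="converged"),
    )


def deconvolve_cohort(bulk: pd.DataFrame, signature: Signature,
                      **kwargs) -> ProportionTable:
    """Proportions for a whole cohort (thin wrapper over the sample fit)."""
    return estimate_proportions(bulk, signature, **kwargs).proportions
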