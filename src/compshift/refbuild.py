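"""Build a cell-type signature from a clustered single-nucleus count matrix.

The reference arrives already clustered and labeled (one cluster label and
one subject ID per nucleus).  This module turns it into the three
quantities the downstream weighted deconvolution consumes:

* ``theta`` — per cell type, each gene's share of that type's total RNA
  output (columns sum to 1 over the shared gene universe),
* ``sigma2`` — the across-subject variance of those shares, which drives
  the per-gene weighting of the deconvolution, and
* ``cell_sizes`` — mean total counts per nucleus of each type, the
  RNA-content factor that separates RNA fractions from cell fractions.

Marker selection is one-vs-rest: for every retained cluster each gene is
tested for higher log-normalized expression inside the cluster than in
the rest, p-values are BH-adjusted within the cluster, and the top-k
positive-effect genes form the cluster's marker list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps

from .multitest import bh_adjust

__all__ = [
    "ClusteredReference",
    "MarkerPanel",
    "Signature",
    "dedupe_genes",
    "intersect_genes",
    "select_markers",
    "build_signature",
    "per_subject_profiles",
]


@dataclass
class ClusteredReference:
    """Gene x nucleus count matrix with per-nucleus cluster/subject labels.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes in rows, nuclei in columns.
        Accepts dense arrays or any scipy sparse format; stored as CSR.
    gene_ids
        Gene symbols, one per row.  May contain duplicates until
        :func:`dedupe_genes` is applied.
    nucleus_meta
        One row per nucleus with columns ``cluster`` and ``subject``.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    nucleus_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.counts.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"counts has {self.counts.shape[0]} rows but "
                f"{len(self.gene_ids)} gene ids were given"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        meta = self.nucleus_meta
        if not {"cluster", "subject"}.issubset(meta.columns):
            raise ValueError("nucleus_meta needs 'cluster' and 'subject' columns")
        if len(meta) != self.counts.shape[1]:
            raise ValueError(
                f"counts has {self.counts.shape[1]} nuclei but metadata has "
                f"{len(meta)} rows"
            )
        if meta["cluster"].isna().any() or meta["subject"].isna().any():
            raise ValueError("every nucleus needs a cluster and a subject label")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_nuclei(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_types(self) -> list:
        return sorted(self.nucleus_meta["cluster"].unique().tolist())

    def subset_genes(self, genes) -> "ClusteredReference":
        """Return a reference restricted (and reordered) to ``genes``.

        Requires unique gene ids (run :func:`dedupe_genes` first).
        """
        idx = pd.Index(self.gene_ids)
        if idx.has_duplicates:
            raise ValueError("subset_genes requires deduplicated gene ids")
        pos = idx.get_indexer(list(genes))
        if (pos < 0).any():
            missing = [g for g, p in zip(genes, pos) if p < 0]
            raise KeyError(f"genes absent from reference: {missing[:5]}")
        return ClusteredReference(self.counts[pos], self.gene_ids[pos], self.nucleus_meta)


@dataclass
class MarkerPanel:
    """Per-cluster marker lists plus the statistics behind them.

    ``markers`` maps cluster label to an ordered gene list (ascending
    adjusted p-value); ``statistics`` holds one row per selected
    (cluster, gene) with columns ``cluster, gene, rank, effect, padj``.
    """

    markers: dict
    statistics: pd.DataFrame

    def __post_init__(self) -> None:
        all_genes = [g for lst in self.markers.values() for g in lst]
        if len(all_genes) != len(set(all_genes)):
            raise ValueError("a gene may appear in at most one cluster's marker list")

    @property
    def all_genes(self) -> list:
        return [g for lst in self.markers.values() for g in lst]


@dataclass
class Signature:
    """Deconvolution signature restricted to a marker panel.

    theta : DataFrame, marker genes x cell types, per-gene relative
        abundance within each type (non-negative).
    sigma2 : DataFrame, same shape, across-subject variance of theta.
    cell_sizes : Series per cell type, mean total counts per nucleus.
    """

    theta: pd.DataFrame
    sigma2: pd.DataFrame
    cell_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.theta.to_numpy() < 0).any():
            raise ValueError("theta must be non-negative")
        if (self.sigma2.to_numpy() < 0).any():
            raise ValueError("sigma2 must be non-negative")
        if (self.cell_sizes.to_numpy() <= 0).any():
            raise ValueError("cell_sizes must be positive")
        if not (self.theta.index.equals(self.sigma2.index)
                and self.theta.columns.equals(self.sigma2.columns)):
            raise ValueError("theta and sigma2 must share genes and cell types")
        if not self.theta.columns.equals(self.cell_sizes.index):
            raise ValueError("cell_sizes must be indexed by the theta cell types")

    @property
    def gene_ids(self) -> list:
        return self.theta.index.tolist()

    @property
    def cell_types(self) -> list:
        return self.theta.columns.tolist()


def dedupe_genes(reference: ClusteredReference) -> ClusteredReference:
    """Resolve duplicate gene symbols, keeping the highest-mean row.

    Among rows sharing a symbol, the one with the highest mean expression
    across all nuclei is retained (first occurrence on exact ties).
    References without duplicates are returned unchanged.
    """
    idx = pd.Index(reference.gene_ids)
    if not idx.has_duplicates:
        return reference
    means = np.asarray(reference.counts.mean(axis=1)).ravel()
    tbl = pd.DataFrame({"gene": reference.gene_ids, "mean": means,
                        "row": np.arange(len(means))})
    keep = (
        tbl.sort_values(["gene", "mean", "row"], ascending=[True, False, True],
                        kind="mergesort")
        .drop_duplicates("gene")["row"]
        .to_numpy()
    )
    keep.sort()
    return ClusteredReference(reference.counts[keep], reference.gene_ids[keep],
                              reference.nucleus_meta)


def intersect_genes(reference_genes, bulk_genes) -> list:
    """Sorted intersection of two deduplicated gene universes.

    Downstream stages (signature, deconvolution) operate only on this
    shared universe.  An empty intersection is a hard error.
    """
    common = sorted(set(reference_genes) & set(bulk_genes))
    if not common:
        raise ValueError(
            f"no genes shared between reference ({len(list(reference_genes))} genes) "
            f"and bulk ({len(list(bulk_genes))} genes)"
        )
    return common


def _log_normalize(counts: sp.csr_matrix, scale: float = 1e4,
                   pseudocount: float = 1.0) -> sp.csr_matrix:
    """log(counts-per-`scale` / pseudocount + 1), sparse-preserving.

    Differs from log(cp + pseudocount) by a per-gene constant log(pc),
    which location tests are invariant to.
    """
    libs = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    if (libs <= 0).any():
        raise ValueError("nuclei with zero total counts cannot be normalized")
    X = counts.multiply(scale / libs).tocsr()
    X.data = np.log1p(X.data / pseudocount)
    return X


def _welch_one_vs_rest(X: sp.csr_matrix, in_mask: np.ndarray):
    """Vectorized Welch t-test per gene: nuclei in ``in_mask`` vs the rest.

    Returns (effect, t, p) arrays over genes, with effect the difference
    of group means on the normalized log scale.
    """
    n1 = int(in_mask.sum())
    n0 = int((~in_mask).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("both groups need at least 2 nuclei")
    Xsq = X.copy()
    Xsq.data = Xsq.data ** 2
    s1 = np.asarray(X[:, in_mask].sum(axis=1)).ravel()
    s0 = np.asarray(X[:, ~in_mask].sum(axis=1)).ravel()
    q1 = np.asarray(Xsq[:, in_mask].sum(axis=1)).ravel()
    q0 = np.asarray(Xsq[:, ~in_mask].sum(axis=1)).ravel()
    m1, m0 = s1 / n1, s0 / n0
    v1 = np.maximum(q1 - n1 * m1 ** 2, 0.0) / (n1 - 1)
    v0 = np.maximum(q0 - n0 * m0 ** 2, 0.0) / (n0 - 1)
    effect = m1 - m0
    se2 = v1 / n1 + v0 / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
    p = np.ones_like(effect)
    ok = se2 > 0
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df[ok])
    # zero variance in both groups: identical constants -> p=1 (effect 0);
    # distinct constants cannot occur with equal variance 0 unless n==1.
    t[~ok] = 0.0
    return effect, t, p


def select_markers(reference: ClusteredReference, k: int = 15,
                   min_cluster_size: int = 500, scale: float = 1e4,
                   pseudocount: float = 1.0) -> MarkerPanel:
    """One-vs-rest marker selection over retained clusters.

    Clusters with fewer than ``min_cluster_size`` nuclei are dropped.
    Per retained cluster, each gene gets a Welch t-test of in-cluster vs
    out-of-cluster log-normalized expression and BH adjustment across
    genes; the top ``k`` positive-effect genes (ascending adjusted
    p-value, ties broken by larger effect then gene symbol) become the
    cluster's markers.  A gene winning in several clusters is assigned
    to the one where its adjusted p-value is smallest.
    """
    if pd.Index(reference.gene_ids).has_duplicates:
        raise ValueError("run dedupe_genes before select_markers")
    sizes = reference.nucleus_meta["cluster"].value_counts()
    kept_clusters = sorted(sizes[sizes >= min_cluster_size].index.tolist())
    if len(kept_clusters) < 2:
        raise ValueError(
            f"need >=2 clusters with >= {min_cluster_size} nuclei, "
            f"got {len(kept_clusters)}"
        )
    in_kept = reference.nucleus_meta["cluster"].isin(kept_clusters).to_numpy()
    X = _log_normalize(reference.counts[:, in_kept], scale, pseudocount)
    clusters = reference.nucleus_meta.loc[in_kept, "cluster"].to_numpy()

    rows = []
    for c in kept_clusters:
        effect, _, p = _welch_one_vs_rest(X, clusters == c)
        padj = bh_adjust(p)
        pos = effect > 0
        rows.append(pd.DataFrame({
            "cluster": c,
            "gene": reference.gene_ids[pos],
            "effect": effect[pos],
            "padj": padj[pos],
        }))
    cand = pd.concat(rows, ignore_index=True)
    # collisions: each gene goes to its best cluster
    cand = (
        cand.sort_values(["gene", "padj", "effect", "cluster"],
                         ascending=[True, True, False, True], kind="mergesort")
        .drop_duplicates("gene")
    )
    cand = cand.sort_values(["cluster", "padj", "effect", "gene"],
                            ascending=[True, True, False, True], kind="mergesort")
    markers: dict = {}
    stat_rows = []
    for c in kept_clusters:
        sub = cand[cand["cluster"] == c].head(k).copy()
        if len(sub) < k:
            warnings.warn(
                f"cluster {c!r}: only {len(sub)} positive-effect marker "
                f"candidates (requested {k})", UserWarning,
            )
        sub["rank"] = np.arange(1, len(sub) + 1)
        markers[c] = sub["gene"].tolist()
        stat_rows.append(sub[["cluster", "gene", "rank", "effect", "padj"]])
    statistics = pd.concat(stat_rows, ignore_index=True)
    return MarkerPanel(markers=markers, statistics=statistics)


def per_subject_profiles(reference: ClusteredReference) -> dict:
    """Per-subject relative expression profile of each cell type.

    Returns ``{subject: DataFrame genes x cell types}`` where each column
    is that subject's summed counts for the type divided by the type's
    total counts (columns sum to 1).  Types absent in a subject are
    omitted from that subject's frame.
    """
    out = {}
    meta = reference.nucleus_meta
    for subject in sorted(meta["subject"].unique().tolist()):
        cols = {}
        s_mask = (meta["subject"] == subject).to_numpy()
        for ct in sorted(meta.loc[s_mask, "cluster"].unique().tolist()):
            mask = s_mask & (meta["cluster"] == ct).to_numpy()
            sums = np.asarray(reference.counts[:, mask].sum(axis=1)).ravel().astype(float)
            total = sums.sum()
            if total > 0:
                cols[ct] = sums / total
        out[subject] = pd.DataFrame(cols, index=reference.gene_ids)
    return out


def build_signature(reference: ClusteredReference, panel: MarkerPanel,
                    universe) -> Signature:
    """Aggregate theta / sigma2 / cell sizes over the marker panel.

    theta is computed per subject over the full shared gene universe
    (columns sum to 1 there), averaged across the subjects in which the
    type occurs, then restricted to the panel genes.  sigma2 is the
    across-subject sample variance of the per-subject theta (0 with a
    warning for types seen in fewer than two subjects).  Cell sizes are
    mean per-nucleus total counts within each type, on universe genes.
    """
    universe = list(universe)
    missing = set(panel.all_genes) - set(universe)
    if missing:
        raise ValueError(f"panel genes outside the universe: {sorted(missing)[:5]}")
    ref_u = reference.subset_genes(universe)
    profiles = per_subject_profiles(ref_u)
    cell_types = sorted({ct for prof in profiles.values() for ct in prof.columns})

    marker_genes = sorted(set(panel.all_genes))
    theta = pd.DataFrame(index=pd.Index(marker_genes, name="gene"),
                         columns=cell_types, dtype=float)
    sigma2 = theta.copy()
    for ct in cell_types:
        cols = [prof[ct] for prof in profiles.values() if ct in prof.columns]
        block = pd.concat(cols, axis=1)
        mean_full = block.mean(axis=1)
        if block.shape[1] < 2:
            warnings.warn(
                f"cell type {ct!r} present in fewer than 2 subjects; "
                "sigma2 set to 0", UserWarning,
            )
            var_full = pd.Series(0.0, index=block.index)
        else:
            var_full = block.var(axis=1, ddof=1)
        theta[ct] = mean_full.loc[marker_genes]
        sigma2[ct] = var_full.loc[marker_genes]

    meta = ref_u.nucleus_meta
    totals = np.asarray(ref_u.counts.sum(axis=0)).ravel().astype(float)
    cell_sizes = pd.Series(
        {ct: totals[(meta["cluster"] == ct).to_numpy()].mean() for ct in cell_types},
        name="cell_size",
    )
    return Signature(theta=theta, sigma2=sigma2, cell_sizes=cell_sizes)
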