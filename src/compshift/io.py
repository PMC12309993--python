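"""Readers and writers for the plain-text interchange formats.

Reference counts arrive either as MatrixMarket (matrix.mtx with
genes.tsv / barcodes.tsv sidecars) or as a dense TSV; nucleus metadata
is a TSV with columns barcode, cluster, subject.  Everything written is
TSV/CSV/YAML so runs are inspectable and diff-able.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import scipy.sparse as sp
import yaml
from scipy.io import mmread, mmwrite

from .refbuild import ClusteredReference, MarkerPanel, Signature
from .deconv import ProportionTable

__all__ = [
    "read_reference", "write_reference",
    "read_bulk", "write_bulk",
    "read_marker_panel", "write_marker_panel",
    "read_signature", "write_signature",
    "read_proportions", "write_proportions",
    "read_design", "write_config", "read_config",
]


def _read_meta(meta_path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t")
    need = {"barcode", "cluster", "subject"}
    if not need.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(need)}")
    return meta.set_index("barcode")


def read_reference(counts_path, meta_path) -> ClusteredReference:
    """Load a clustered reference from MTX-with-sidecars or a dense TSV.

    ``counts_path`` may be a directory (or .mtx file) containing
    matrix.mtx + genes.tsv + barcodes.tsv, or a gene x barcode TSV with
    gene ids in the first column.
    """
    counts_path = Path(counts_path)
    meta = _read_meta(meta_path)
    if counts_path.is_dir() or counts_path.suffix == ".mtx":
        d = counts_path if counts_path.is_dir() else counts_path.parent
        mtx = d / "matrix.mtx" if counts_path.is_dir() else counts_path
        counts = sp.csr_matrix(mmread(mtx))
        genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None)[0].to_numpy()
        barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0]
    else:
        dense = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts = sp.csr_matrix(dense.to_numpy())
        genes = dense.index.to_numpy()
        barcodes = pd.Series(dense.columns)
    meta = meta.loc[barcodes.tolist(), ["cluster", "subject"]]
    return ClusteredReference(counts=counts, gene_ids=genes, nucleus_meta=meta)


def write_reference(reference: ClusteredReference, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(out / "matrix.mtx", reference.counts)
    pd.Series(reference.gene_ids).to_csv(out / "genes.tsv", sep="\t",
                                         index=False, header=False)
    pd.Series(reference.nucleus_meta.index).to_csv(
        out / "barcodes.tsv", sep="\t", index=False, header=False)
    meta = reference.nucleus_meta.reset_index(names="barcode")
    meta.to_csv(out / "meta.tsv", sep="\t", index=False)


def read_bulk(path) -> pd.DataFrame:
    """Gene x sample raw-count TSV (gene ids in the first column)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_bulk(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def write_marker_panel(panel: MarkerPanel, path) -> None:
    panel.statistics.to_csv(path, sep="\t", index=False)


def read_marker_panel(path) -> MarkerPanel:
    stats = pd.read_csv(path, sep="\t")
    stats = stats.sort_values(["cluster", "rank"])
    markers = {c: sub["gene"].tolist() for c, sub in stats.groupby("cluster")}
    return MarkerPanel(markers=markers, statistics=stats)


def write_signature(signature: Signature, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    signature.theta.to_csv(out / "theta.tsv", sep="\t")
    signature.sigma2.to_csv(out / "sigma2.tsv", sep="\t")
    signature.cell_sizes.rename_axis("cell_type").to_csv(
        out / "cell_sizes.tsv", sep="\t")


def read_signature(in_dir) -> Signature:
    d = Path(in_dir)
    theta = pd.read_csv(d / "theta.tsv", sep="\t", index_col=0)
    sigma2 = pd.read_csv(d / "sigma2.tsv", sep="\t", index_col=0)
    sizes = pd.read_csv(d / "cell_sizes.tsv", sep="\t", index_col=0)["cell_size"]
    return Signature(theta=theta, sigma2=sigma2, cell_sizes=sizes)


def write_proportions(props: ProportionTable, path) -> None:
    long = (props.df.rename_axis("sample")
            .reset_index()
            .melt(id_vars="sample", var_name="cell_type",
                  value_name="proportion"))
    long.to_csv(path, index=False)


def read_proportions(path) -> ProportionTable:
    long = pd.read_csv(path)
    wide = long.pivot(index="sample", columns="cell_type", values="proportion")
    wide.columns.name = None
    return ProportionTable(wide)


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
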