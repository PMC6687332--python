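"""Reading and writing count matrices and per-cell annotation tables.

On disk counts live either as a 10x-style MatrixMarket triplet directory
(matrix.mtx genes x cells, with genes.tsv / barcodes.tsv sidecars) or as a
dense CSV (genes as rows). In memory everything is an AnnData with cells as
observations and genes as variables, raw integer counts in ``.X`` (sparse).
"""

from __future__ import annotations

import os
import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

CELL_TABLE_COLUMNS = ["barcode", "condition", "cluster", "umi_total", "mito_fraction", "qc_pass"]

__all__ = [
    "read_counts",
    "write_counts",
    "read_cell_table",
    "write_cell_table",
    "attach_cell_table",
    "CELL_TABLE_COLUMNS",
]


def _check_ids(ids, what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


def _build(counts_genes_by_cells, genes, barcodes) -> ad.AnnData:
    genes = _check_ids(genes, "gene")
    barcodes = _check_ids(barcodes, "barcode")
    m = sp.csr_matrix(counts_genes_by_cells.T)
    if m.shape != (len(barcodes), len(genes)):
        raise ValueError("matrix dimensions do not match sidecar identifier lists")
    data = m.data
    if len(data) and ((data < 0).any() or not np.allclose(data, np.round(data))):
        raise ValueError("counts must be nonnegative integers")
    adata = ad.AnnData(
        X=m.astype(np.int32),
        obs=pd.DataFrame({"barcode": barcodes}, index=barcodes),
        var=pd.DataFrame({"gene": genes}, index=genes),
    )
    adata.obs.index.name = None
    return adata


def read_counts(path, fmt: str = "mtx_triplet") -> ad.AnnData:
    """Read a count matrix.

    ``mtx_triplet``: *path* is a directory holding matrix.mtx (genes x
    cells), genes.tsv and barcodes.tsv. ``csv``: *path* is a dense CSV with
    gene rows, barcode columns.
    """
    if fmt == "mtx_triplet":
        mtx = os.path.join(path, "matrix.mtx")
        genes_f = os.path.join(path, "genes.tsv")
        barcodes_f = os.path.join(path, "barcodes.tsv")
        for f in (mtx, genes_f, barcodes_f):
            if not os.path.exists(f):
                raise FileNotFoundError(f)
        try:
            m = scipy.io.mmread(mtx)
        except Exception as exc:  # malformed header / truncated triplets
            raise ValueError(f"malformed MatrixMarket file {mtx}: {exc}") from exc
        genes = pd.read_csv(genes_f, sep="\t", header=None)[0].tolist()
        barcodes = pd.read_csv(barcodes_f, sep="\t", header=None)[0].tolist()
        if m.shape[0] != len(genes):
            raise ValueError(f"matrix rows ({m.shape[0]}) != genes in {genes_f} ({len(genes)})")
        if m.shape[1] != len(barcodes):
            raise ValueError(
                f"matrix columns ({m.shape[1]}) != barcodes in {barcodes_f} ({len(barcodes)})"
            )
        return _build(sp.csr_matrix(m), genes, barcodes)
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        return _build(sp.csr_matrix(df.to_numpy()), df.index, df.columns)
    raise ValueError(f"unknown format {fmt!r}")


def write_counts(adata: ad.AnnData, path, fmt: str = "mtx_triplet") -> None:
    """Inverse of :func:`read_counts`; round trips are exact."""
    if fmt == "mtx_triplet":
        os.makedirs(path, exist_ok=True)
        m = sp.coo_matrix(adata.X.T)  # genes x cells
        scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), m, field="integer")
        pd.Series(adata.var_names).to_csv(
            os.path.join(path, "genes.tsv"), sep="\t", header=False, index=False
        )
        pd.Series(adata.obs_names).to_csv(
            os.path.join(path, "barcodes.tsv"), sep="\t", header=False, index=False
        )
    elif fmt == "csv":
        dense = np.asarray(adata.X.todense()).T  # genes x cells
        pd.DataFrame(dense, index=adata.var_names, columns=adata.obs_names).to_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_cell_table(adata: ad.AnnData, path) -> None:
    """Cell table TSV with fixed column order (missing QC columns omitted)."""
    cols = [c for c in CELL_TABLE_COLUMNS if c in adata.obs.columns]
    adata.obs[cols].to_csv(path, sep="\t", index=False)


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "cluster": str})
    if "barcode" not in df.columns:
        raise ValueError(f"{path} lacks a 'barcode' column")
    return df


def attach_cell_table(adata: ad.AnnData, cells: pd.DataFrame) -> ad.AnnData:
    """Join a cell annotation table onto an AnnData by barcode."""
    cells = cells.set_index("barcode", drop=False)
    missing = adata.obs_names.difference(cells.index)
    if len(missing):
        raise ValueError(f"cell table lacks {len(missing)} barcodes (e.g. {missing[0]!r})")
    extra = cells.index.difference(adata.obs_names)
    if len(extra):
        warnings.warn(f"cell table has {len(extra)} barcodes absent from the matrix; ignored")
    aligned = cells.loc[adata.obs_names]
    for col in aligned.columns:
        if col != "barcode":
            adata.obs[col] = aligned[col].to_numpy()
    adata.obs["barcode"] = adata.obs_names
    return adata
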