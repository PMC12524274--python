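"""Dataset I/O: Matrix Market counts + features/barcodes/metadata TSVs.

Layout mirrors the common gene-expression matrix exchange convention:
``matrix.mtx`` holds integer counts in coordinate form (genes x cells,
1-based indices), ``features.tsv`` / ``barcodes.tsv`` one identifier per
line, and ``metadata.tsv`` the per-nucleus annotations. Writing is
byte-deterministic; reading validates dimensions and reports the offending
line on malformed input.
"""

from __future__ import annotations

import pathlib

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_mtx",
    "read_mtx",
    "write_reference_markers",
    "read_reference_markers",
]

_MTX_HEADER = "%%MatrixMarket matrix coordinate integer general"

METADATA_COLUMNS = ("breed", "replicate", "cluster", "true_type")


class MatrixMarketError(ValueError):
    """Malformed Matrix Market file (message names the offending line)."""


def write_mtx(path, matrix: sparse.spmatrix) -> None:
    """Write an integer sparse matrix in coordinate MTX form (1-based)."""
    coo = sparse.coo_matrix(matrix)
    order = np.lexsort((coo.row, coo.col))  # column-major, the usual layout
    rows, cols, data = coo.row[order], coo.col[order], coo.data[order]
    with open(path, "w") as fh:
        fh.write(_MTX_HEADER + "\n")
        fh.write(f"{coo.shape[0]} {coo.shape[1]} {coo.nnz}\n")
        for r, c, v in zip(rows, cols, data):
            fh.write(f"{r + 1} {c + 1} {int(v)}\n")


def read_mtx(path) -> sparse.csr_matrix:
    """Read an integer coordinate MTX file written by :func:`write_mtx`."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("%%MatrixMarket"):
            raise MatrixMarketError(f"{path}: line 1: missing MatrixMarket header")
        if "coordinate" not in header:
            raise MatrixMarketError(f"{path}: line 1: expected coordinate format")
        lineno = 1
        line = fh.readline()
        lineno += 1
        while line.startswith("%"):
            line = fh.readline()
            lineno += 1
        try:
            n_rows, n_cols, nnz = (int(tok) for tok in line.split())
        except ValueError:
            raise MatrixMarketError(
                f"{path}: line {lineno}: malformed size line {line!r}") from None
        rows = np.empty(nnz, dtype=np.int64)
        cols = np.empty(nnz, dtype=np.int64)
        vals = np.empty(nnz, dtype=np.int64)
        for k in range(nnz):
            line = fh.readline()
            lineno += 1
            if not line:
                raise MatrixMarketError(
                    f"{path}: line {lineno}: truncated file, expected "
                    f"{nnz} entries but found {k}")
            try:
                r, c, v = line.split()
                rows[k], cols[k], vals[k] = int(r), int(c), int(v)
            except ValueError:
                raise MatrixMarketError(
                    f"{path}: line {lineno}: malformed entry {line.strip()!r}"
                ) from None
            if not (1 <= rows[k] <= n_rows and 1 <= cols[k] <= n_cols):
                raise MatrixMarketError(
                    f"{path}: line {lineno}: index out of bounds")
    mat = sparse.coo_matrix(
        (vals, (rows - 1, cols - 1)), shape=(n_rows, n_cols))
    return mat.tocsr()


def write_dataset(adata: ad.AnnData, directory) -> None:
    """Write counts + identifiers + metadata under ``directory``.

    The matrix is stored genes x cells; the AnnData is cells x genes.
    """
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_mtx(directory / "matrix.mtx", adata.X.T)
    (directory / "features.tsv").write_text(
        "".join(f"{g}\n" for g in adata.var_names))
    (directory / "barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in adata.obs_names))
    meta_cols = [c for c in METADATA_COLUMNS if c in adata.obs.columns]
    meta = adata.obs[meta_cols].copy()
    meta.insert(0, "barcode", adata.obs_names)
    meta.to_csv(directory / "metadata.tsv", sep="\t", index=False)


def read_dataset(directory) -> ad.AnnData:
    """Read a dataset written by :func:`write_dataset`."""
    directory = pathlib.Path(directory)
    mat = read_mtx(directory / "matrix.mtx")
    genes = (directory / "features.tsv").read_text().splitlines()
    barcodes = (directory / "barcodes.tsv").read_text().splitlines()
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(genes)} features "
            f"x {len(barcodes)} barcodes")
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["mito"] = var.index.str.startswith("MT-")
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    meta_path = directory / "metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("barcode")
        if not meta.index.equals(obs.index):
            raise ValueError("metadata barcodes do not match barcodes.tsv")
        obs = meta
    return ad.AnnData(X=mat.T.tocsr(), obs=obs, var=var)


def write_reference_markers(ref: dict[str, set[str]], path) -> None:
    """TSV with one row per cell type: name TAB comma-separated genes."""
    with open(path, "w") as fh:
        for ctype in ref:
            fh.write(f"{ctype}\t{','.join(sorted(ref[ctype]))}\n")


def read_reference_markers(path) -> dict[str, set[str]]:
    ref: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 'cell_type<TAB>genes'")
            ctype, genes = parts
            ref[ctype] = {g for g in genes.split(",") if g}
    if not ref:
        raise ValueError(f"{path}: empty reference marker table")
    return ref
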