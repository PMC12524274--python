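"""Nucleus-level quality control and log-normalization.

QC keeps nuclei with more than ``min_features`` detected genes, fewer than
``max_counts`` total UMIs, and a mitochondrial fraction below
``max_mito_pct`` percent (all strict inequalities). Normalization is the
standard per-cell log transform ``ln(1 + scale_factor * count / total)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["QCThresholds", "compute_qc", "filter_cells", "log_normalize",
           "qc_pipeline"]


@dataclass(frozen=True)
class QCThresholds:
    min_features: int = 200      # keep if n_features > min_features
    max_counts: int = 3000       # keep if n_counts < max_counts
    max_mito_pct: float = 10.0   # keep if mito_pct < max_mito_pct
    min_counts: int = 0          # optional lower bound, keep if n_counts > it

    def __post_init__(self):
        if self.min_features < 0 or self.max_counts <= 0 or self.max_mito_pct <= 0:
            raise ValueError("QC thresholds must be positive")


def compute_qc(counts, mito_flags=None) -> pd.DataFrame:
    """Per-cell QC covariates: n_features, n_counts, mito_pct.

    ``counts`` may be an AnnData (mito flags taken from ``var['mito']``) or
    a cells x genes matrix together with a boolean ``mito_flags`` vector.
    Cells with zero total counts get ``mito_pct = 0``.
    """
    if isinstance(counts, ad.AnnData):
        index = counts.obs_names
        if mito_flags is None:
            mito_flags = counts.var["mito"].to_numpy()
        counts = counts.X
    else:
        index = None
    if mito_flags is None:
        raise ValueError("mito_flags required when counts is a raw matrix")
    mito_flags = np.asarray(mito_flags, dtype=bool)
    if mito_flags.shape[0] != counts.shape[1]:
        raise ValueError(
            f"mito_flags length {mito_flags.shape[0]} != n_genes {counts.shape[1]}")
    X = sparse.csr_matrix(counts)
    n_features = X.getnnz(axis=1)
    n_counts = np.asarray(X.sum(axis=1)).ravel()
    mito_counts = np.asarray(X[:, mito_flags].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(n_counts > 0, 100.0 * mito_counts / np.maximum(n_counts, 1), 0.0)
    return pd.DataFrame(
        {"n_features": n_features, "n_counts": n_counts.astype(np.int64),
         "mito_pct": mito_pct},
        index=index if index is not None else pd.RangeIndex(X.shape[0]))


def filter_cells(qc: pd.DataFrame, thresholds: QCThresholds = QCThresholds()):
    """Barcodes passing all thresholds (strict inequalities, as stated)."""
    keep = (
        (qc["n_features"] > thresholds.min_features)
        & (qc["n_counts"] < thresholds.max_counts)
        & (qc["mito_pct"] < thresholds.max_mito_pct)
    )
    if thresholds.min_counts:
        keep &= qc["n_counts"] > thresholds.min_counts
    return qc.index[keep]


def log_normalize(adata: ad.AnnData, scale_factor: float = 10_000.0,
                  base: float | None = None) -> ad.AnnData:
    """Return a copy with ``X = log(1 + scale_factor * count / cell_total)``.

    Natural log by default (``base`` overrides). Zero entries stay zero, so
    the sparsity pattern is preserved. Cells with zero total counts are
    rejected: filter first.
    """
    X = sparse.csr_matrix(adata.X).astype(np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        raise ValueError(
            "cells with zero total counts present; run filter_cells first")
    scale = scale_factor / totals
    X = sparse.diags(scale) @ X
    X.data = np.log1p(X.data)
    if base is not None:
        X.data /= np.log(base)
    out = adata.copy()
    out.X = X.tocsr()
    return out


def qc_pipeline(adata: ad.AnnData, thresholds: QCThresholds = QCThresholds(),
                scale_factor: float = 10_000.0):
    """Convenience: compute QC, filter, log-normalize. Returns
    (normalized AnnData, qc table)."""
    qc = compute_qc(adata)
    kept = filter_cells(qc, thresholds)
    filtered = adata[kept].copy()
    return log_normalize(filtered, scale_factor=scale_factor), qc
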