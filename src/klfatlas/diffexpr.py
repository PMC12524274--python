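"""One-vs-rest marker statistics per cluster.

For every cluster and gene: Wilcoxon rank-sum test (tie-corrected normal
approximation, no continuity correction), Bonferroni-adjusted p, log2 fold
change of de-logged group means, expressing fractions, and the AUC effect
size (the probability that a random in-cluster cell exceeds a random
out-of-cluster cell, i.e. U / (n1*n2)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = [
    "DEGFilters",
    "rank_sum_u",
    "auc_effect",
    "log2_fold_change",
    "pct_expressing",
    "find_markers",
    "apply_deg_filters",
    "rank_marker_rows",
]


@dataclass(frozen=True)
class DEGFilters:
    """Thresholds defining a differentially expressed gene (all strict)."""

    max_p_adj: float = 0.05
    min_abs_log2fc: float = 0.25
    min_pct: float = 0.1
    min_auc_margin: float = 0.1  # requires |AUC - 0.5| > this

    def __post_init__(self):
        if not (0 < self.max_p_adj <= 1):
            raise ValueError("max_p_adj must be in (0, 1]")
        if self.min_abs_log2fc < 0 or not 0 <= self.min_pct < 1:
            raise ValueError("invalid DEG filter values")
        if not 0 <= self.min_auc_margin < 0.5:
            raise ValueError("min_auc_margin must be in [0, 0.5)")


def _tie_term(values: np.ndarray) -> float:
    """sum(t^3 - t) over groups of tied values."""
    _, counts = np.unique(values, return_counts=True)
    t = counts.astype(np.float64)
    return float(np.sum(t ** 3 - t))


def rank_sum_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U for x over y and the two-sided asymptotic p-value.

    U counts pairs with x_i > y_j plus half the tied pairs. The p-value uses
    the tie-corrected normal approximation without continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    tie = _tie_term(combined)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:  # every value identical
        return float(u), 1.0
    z = (u - n1 * n2 / 2.0) / np.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return float(u), float(p)


def auc_effect(u: float, n1: int, n2: int) -> float:
    """AUC = U / (n1 * n2); 0.5 means no discrimination."""
    return float(u) / (n1 * n2)


def log2_fold_change(x, y, pseudo: float = 1.0) -> float:
    """log2 ratio of de-logged group means with a pseudo-count.

    ``x`` and ``y`` are log-normalized (natural-log) values; means are taken
    on the de-logged scale, expm1.
    """
    mx = float(np.mean(np.expm1(np.asarray(x, float))))
    my = float(np.mean(np.expm1(np.asarray(y, float))))
    return float(np.log2((mx + pseudo) / (my + pseudo)))


def pct_expressing(x) -> float:
    """Fraction of cells with value > 0."""
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("empty expression vector")
    return float(np.mean(x > 0))


def find_markers(
    norm,
    labels=None,
    filters: DEGFilters = DEGFilters(),
    groupby: str = "cluster",
    pseudo: float = 1.0,
    min_cells: int = 3,
    bonferroni_all_genes: bool = False,
) -> pd.DataFrame:
    """One-vs-rest marker statistics for every cluster.

    ``norm`` is a log-normalized AnnData (labels taken from
    ``obs[groupby]``) or a cells x genes matrix with ``labels`` supplied.
    Genes enter the test only if ``max(pct1, pct2) > filters.min_pct``
    (the usual pre-test screen); the Bonferroni factor is the number of
    genes actually tested in that comparison unless
    ``bonferroni_all_genes`` is set.
    """
    if isinstance(norm, ad.AnnData):
        if labels is None:
            labels = norm.obs[groupby].to_numpy()
        gene_names = np.asarray(norm.var_names)
        X = norm.X
    else:
        if labels is None:
            raise ValueError("labels required when norm is a raw matrix")
        gene_names = np.array([f"g{j}" for j in range(norm.shape[1])])
        X = norm
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels must cover all cells")
    # gene-major orientation: contiguous per-gene rows rank much faster
    if sparse.issparse(X):
        Xt = np.asarray(X.T.todense(), dtype=np.float64)
    else:
        Xt = np.ascontiguousarray(np.asarray(X, dtype=np.float64).T)
    n_genes, n_cells = Xt.shape
    clusters = sorted(pd.unique(labels))
    if len(clusters) < 2:
        raise ValueError("need at least two clusters for one-vs-rest tests")

    # global per-gene ranks serve every one-vs-rest comparison
    ranks = stats.rankdata(Xt, axis=1)
    tie = np.empty(n_genes)
    Xs = np.sort(Xt, axis=1)
    boundary = Xs[:, 1:] != Xs[:, :-1]
    for g in range(n_genes):
        pos = np.flatnonzero(boundary[g])
        t = np.diff(np.concatenate(([0], pos + 1, [n_cells]))).astype(float)
        tie[g] = np.sum(t ** 3 - t)
    expr = Xt > 0
    expm1 = np.expm1(Xt)
    tot_expr = expr.sum(axis=1)
    tot_expm1 = expm1.sum(axis=1)

    rows = []
    for cl in clusters:
        in_cl = labels == cl
        n1 = int(in_cl.sum())
        n2 = n_cells - n1
        if n1 < min_cells:
            warnings.warn(
                f"cluster {cl!r} has only {n1} cells (<{min_cells}); skipped",
                stacklevel=2)
            continue
        expr1 = expr[:, in_cl].sum(axis=1)
        pct1 = expr1 / n1
        pct2 = (tot_expr - expr1) / n2
        tested = np.maximum(pct1, pct2) > filters.min_pct
        if not tested.any():
            continue
        r1 = ranks[tested][:, in_cl].sum(axis=1)
        u = r1 - n1 * (n1 + 1) / 2.0
        n = n_cells
        var = n1 * n2 / 12.0 * ((n + 1) - tie[tested] / (n * (n - 1)))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(var > 0, (u - n1 * n2 / 2.0) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
        p = np.where(var > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
        p = np.minimum(p, 1.0)
        n_tested = int(tested.sum())
        factor = n_genes if bonferroni_all_genes else n_tested
        p_adj = np.minimum(1.0, p * factor)
        sum1 = expm1[tested][:, in_cl].sum(axis=1)
        mean1 = sum1 / n1
        mean2 = (tot_expm1[tested] - sum1) / n2
        log2fc = np.log2((mean1 + pseudo) / (mean2 + pseudo))
        auc = u / (n1 * n2)
        rows.append(pd.DataFrame({
            "cluster": cl,
            "gene": gene_names[tested],
            "p_value": p,
            "p_adj": p_adj,
            "log2fc": log2fc,
            "auc": auc,
            "pct1": pct1[tested],
            "pct2": pct2[tested],
            "n1": n1,
            "n2": n2,
        }))
    if not rows:
        return pd.DataFrame(columns=["cluster", "gene", "p_value", "p_adj",
                                     "log2fc", "auc", "pct1", "pct2", "n1", "n2"])
    return pd.concat(rows, ignore_index=True)


def apply_deg_filters(table: pd.DataFrame,
                      f: DEGFilters = DEGFilters()) -> pd.DataFrame:
    """Keep rows passing all DEG criteria (strict inequalities)."""
    if table.empty:
        return table.copy()
    keep = (
        (table["p_adj"] < f.max_p_adj)
        & (table["log2fc"].abs() > f.min_abs_log2fc)
        & (np.maximum(table["pct1"], table["pct2"]) > f.min_pct)
        & ((table["auc"] - 0.5).abs() > f.min_auc_margin)
    )
    return table[keep].reset_index(drop=True)


def rank_marker_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Canonical marker ordering: log2fc desc, then p_adj asc, then gene."""
    return table.sort_values(
        ["log2fc", "p_adj", "gene"], ascending=[False, True, True],
        kind="mergesort").reset_index(drop=True)
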