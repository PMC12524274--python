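"""Gene-set module scores with expression-matched control genes.

Per cell: mean log-normalized expression of the gene set minus the mean of
control genes sampled from the same average-expression bins, the standard
module-score construction for single-cell data. Genes are binned into
``n_bins`` quantile bins of their mean expression across all cells; each set
gene draws ``n_ctrl`` controls from its own bin (excluding set genes, with
replacement only when the bin is too small), and controls are pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["ModuleScoreConfig", "module_score", "score_by_group"]


@dataclass(frozen=True)
class ModuleScoreConfig:
    n_bins: int = 24
    n_ctrl: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_bins < 1 or self.n_ctrl < 1:
            raise ValueError("n_bins and n_ctrl must be >= 1")


def module_score(norm, gene_set,
                 cfg: ModuleScoreConfig = ModuleScoreConfig(),
                 gene_names=None) -> pd.Series:
    """Per-cell module score for ``gene_set``.

    ``norm`` is a log-normalized AnnData or cells x genes matrix (with
    ``gene_names``). Deterministic under ``cfg.seed``.
    """
    if isinstance(norm, ad.AnnData):
        gene_names = np.asarray(norm.var_names)
        index = norm.obs_names
        X = norm.X
    else:
        if gene_names is None:
            raise ValueError("gene_names required for a raw matrix")
        gene_names = np.asarray(gene_names)
        index = pd.RangeIndex(norm.shape[0])
        X = norm
    X = np.asarray(X.todense() if sparse.issparse(X) else X, dtype=np.float64)
    gene_set = list(dict.fromkeys(gene_set))
    if not gene_set:
        raise ValueError("gene set is empty")
    name_to_idx = {g: j for j, g in enumerate(gene_names)}
    missing = [g for g in gene_set if g not in name_to_idx]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    set_idx = np.array([name_to_idx[g] for g in gene_set])
    if len(set_idx) >= len(gene_names):
        raise ValueError("gene set covers the whole universe; no controls")

    means = X.mean(axis=0)
    n_bins = min(cfg.n_bins, len(gene_names))
    bins = pd.qcut(pd.Series(means).rank(method="first"), q=n_bins,
                   labels=False, duplicates="drop").to_numpy()
    if bins.max() + 1 < cfg.n_bins:
        warnings.warn(
            f"only {bins.max() + 1} usable expression bins (requested "
            f"{cfg.n_bins})", stacklevel=2)

    in_set = np.zeros(len(gene_names), dtype=bool)
    in_set[set_idx] = True
    rng = np.random.default_rng(cfg.seed)
    control_idx: list[np.ndarray] = []
    for j in set_idx:
        pool = np.flatnonzero((bins == bins[j]) & ~in_set)
        if pool.size == 0:
            raise ValueError(
                f"no control genes available in the bin of {gene_names[j]!r}")
        replace = pool.size < cfg.n_ctrl
        if replace:
            warnings.warn(
                f"bin of {gene_names[j]!r} has {pool.size} candidates < "
                f"n_ctrl={cfg.n_ctrl}; sampling with replacement",
                stacklevel=2)
        control_idx.append(rng.choice(pool, size=cfg.n_ctrl, replace=replace))
    controls = np.concatenate(control_idx)

    score = X[:, set_idx].mean(axis=1) - X[:, controls].mean(axis=1)
    return pd.Series(score, index=index, name="module_score")


def score_by_group(scores: pd.Series, meta: pd.DataFrame,
                   groupby: str = "true_type") -> pd.DataFrame:
    """Group summaries (n, mean, quartiles) suitable for box-plot export."""
    df = pd.DataFrame({"score": scores, "group": meta.loc[scores.index, groupby]})
    out = df.groupby("group", observed=True)["score"].agg(
        n="size", mean="mean",
        q25=lambda s: s.quantile(0.25),
        median="median",
        q75=lambda s: s.quantile(0.75),
    )
    return out.sort_values("mean", ascending=False)
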