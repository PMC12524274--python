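"""Cell-type composition and two-breed comparison statistics.

Per-replicate cell-type percentages, (mean, SD, n) group summaries, and
summary-level comparisons: Welch's t-test with Satterthwaite degrees of
freedom, the Welch confidence interval of the mean difference, and Cohen's d
with the pooled-SD denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupSummary", "ComparisonResult", "proportions", "summarize",
           "compare_groups", "compare_all_types"]


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class ComparisonResult:
    mean_diff: float
    ci_low: float
    ci_high: float
    cohens_d: float
    t_stat: float
    welch_df: float
    p_value: float


def proportions(meta: pd.DataFrame, replicate_col: str = "replicate",
                type_col: str = "true_type") -> pd.DataFrame:
    """Replicate x cell-type percentage table; rows sum to 100."""
    if meta.empty:
        raise ValueError("empty cell metadata")
    if meta[type_col].isna().any() or meta[replicate_col].isna().any():
        raise ValueError("every cell needs replicate and type labels")
    counts = pd.crosstab(meta[replicate_col], meta[type_col])
    return 100.0 * counts.div(counts.sum(axis=1), axis=0)


def summarize(values) -> GroupSummary:
    """Sample mean and SD (n-1 denominator) of per-replicate percentages."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicates to summarize")
    return GroupSummary(mean=float(v.mean()), sd=float(v.std(ddof=1)),
                        n=int(v.size))


def compare_groups(a: GroupSummary, b: GroupSummary, level: float = 0.95,
                   pooled: bool = False) -> ComparisonResult:
    """Compare group a minus group b from summary statistics.

    Welch by default: SE = sqrt(sa^2/na + sb^2/nb) with Satterthwaite df.
    ``pooled=True`` switches to the equal-variance Student test. Cohen's d
    always uses the pooled SD (the classic convention).
    """
    diff = a.mean - b.mean
    va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / (a.n + b.n - 2)
    if a.sd == 0 and b.sd == 0:
        if diff == 0:
            return ComparisonResult(0.0, 0.0, 0.0, 0.0, 0.0,
                                    float(a.n + b.n - 2), 1.0)
        raise ValueError("zero variance in both groups with unequal means")
    if pooled:
        se = float(np.sqrt(sp2 * (1 / a.n + 1 / b.n)))
        df = float(a.n + b.n - 2)
    else:
        se = float(np.sqrt(va + vb))
        df = float((va + vb) ** 2
                   / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1)))
    t = diff / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    half = float(stats.t.ppf(0.5 + level / 2.0, df) * se)
    d = diff / float(np.sqrt(sp2)) if sp2 > 0 else 0.0
    return ComparisonResult(
        mean_diff=float(diff), ci_low=float(diff - half),
        ci_high=float(diff + half), cohens_d=float(d), t_stat=float(t),
        welch_df=df, p_value=min(1.0, p))


def compare_all_types(props: pd.DataFrame, breeds: pd.Series,
                      level: float = 0.95,
                      adjust: str | None = None) -> pd.DataFrame:
    """Per-cell-type breed comparison from a replicate x type percentage
    table. ``breeds`` maps replicate -> breed label (two levels; the first
    sorted label is group a). Descriptive by default; ``adjust`` may be
    "bonferroni" or "bh" to append adjusted p-values.
    """
    labels = sorted(breeds.unique())
    if len(labels) != 2:
        raise ValueError("need exactly two breeds")
    rows = {}
    for ctype in props.columns:
        a = summarize(props.loc[breeds == labels[0], ctype])
        b = summarize(props.loc[breeds == labels[1], ctype])
        r = compare_groups(a, b, level=level)
        rows[ctype] = {
            f"mean_{labels[0]}": a.mean, f"sd_{labels[0]}": a.sd,
            f"mean_{labels[1]}": b.mean, f"sd_{labels[1]}": b.sd,
            "mean_diff": r.mean_diff, "ci_low": r.ci_low,
            "ci_high": r.ci_high, "cohens_d": r.cohens_d,
            "t_stat": r.t_stat, "welch_df": r.welch_df, "p_value": r.p_value,
        }
    out = pd.DataFrame(rows).T
    if adjust == "bonferroni":
        out["p_adj"] = np.minimum(1.0, out["p_value"] * len(out))
    elif adjust == "bh":
        p = out["p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank_i in range(m - 1, -1, -1):
            idx = order[rank_i]
            running = min(running, p[idx] * m / (rank_i + 1))
            adj[idx] = running
        out["p_adj"] = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out
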