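"""Cluster annotation by intersecting top markers with reference marker sets.

For each cluster: take the top-k filtered markers (k = 25 by default),
intersect with every candidate cell type's reference marker set, normalize
each intersecting gene's log2FC to a score in (0, 1] by dividing by the
largest log2FC in the top list, and sum per candidate. The cluster is
assigned the argmax type; exact ties are flagged and all tied candidates
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .diffexpr import rank_marker_rows

__all__ = ["ClusterAnnotation", "AnnotationResult", "top_markers",
           "score_cluster", "assign_types", "annotate_clusters",
           "annotation_accuracy"]

UNASSIGNED = "unassigned"


@dataclass
class ClusterAnnotation:
    scores: dict[str, float]
    assigned: str
    tie: bool
    tied_candidates: list[str]
    intersections: dict[str, list[str]]


@dataclass
class AnnotationResult:
    clusters: dict[str, ClusterAnnotation] = field(default_factory=dict)

    @property
    def assignments(self) -> dict[str, str]:
        return {cl: a.assigned for cl, a in self.clusters.items()}

    def score_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(
            {cl: a.scores for cl, a in self.clusters.items()}).T.fillna(0.0)


def top_markers(table: pd.DataFrame, cluster, k: int = 25) -> pd.DataFrame:
    """Top-k markers of one cluster from a DEG-filtered marker table,
    ranked by log2fc (ties: smaller p_adj, then gene name)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    sub = table[table["cluster"] == cluster]
    if sub.empty and cluster not in set(table.get("cluster", [])):
        raise KeyError(f"unknown cluster {cluster!r}")
    return rank_marker_rows(sub).head(k)


def score_cluster(top: pd.DataFrame,
                  ref: dict[str, set[str]],
                  normalization: str = "max") -> tuple[dict[str, float], dict[str, list[str]]]:
    """Candidate-type scores for one cluster's top marker list.

    Each gene in the intersection contributes ``log2fc / max(log2fc in top)``
    (``normalization="max"``) or ``log2fc / sum(log2fc in top)``
    (``normalization="sum"``); a type's score is the sum over its
    intersecting genes. Types with empty intersection score 0.
    """
    if top.empty:
        raise ValueError("top marker list is empty")
    fc = dict(zip(top["gene"], top["log2fc"].astype(float)))
    top_max = max(fc.values())
    if top_max <= 0:
        raise ValueError(
            "all log2fc <= 0 in top markers; positive markers expected")
    if normalization == "max":
        denom = top_max
    elif normalization == "sum":
        denom = sum(v for v in fc.values() if v > 0)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    scores: dict[str, float] = {}
    hits: dict[str, list[str]] = {}
    for ctype, genes in ref.items():
        inter = [g for g in fc if g in genes]
        hits[ctype] = inter
        scores[ctype] = float(sum(fc[g] / denom for g in inter))
    return scores, hits


def assign_types(scores_per_cluster: dict[str, dict[str, float]],
                 intersections: dict[str, dict[str, list[str]]] | None = None
                 ) -> AnnotationResult:
    """Argmax assignment; max score 0 means unassigned; exact ties flagged
    and broken lexicographically."""
    result = AnnotationResult()
    for cl, scores in scores_per_cluster.items():
        inter = intersections.get(cl, {}) if intersections else {}
        if not scores or max(scores.values()) <= 0:
            result.clusters[cl] = ClusterAnnotation(
                scores=dict(scores), assigned=UNASSIGNED, tie=False,
                tied_candidates=[], intersections=inter)
            continue
        best = max(scores.values())
        tied = sorted(t for t, s in scores.items() if s == best)
        result.clusters[cl] = ClusterAnnotation(
            scores=dict(scores), assigned=tied[0], tie=len(tied) > 1,
            tied_candidates=tied if len(tied) > 1 else [],
            intersections=inter)
    return result


def annotate_clusters(marker_table: pd.DataFrame,
                      ref: dict[str, set[str]],
                      k: int = 25,
                      normalization: str = "max") -> AnnotationResult:
    """Full annotation pass over every cluster in a filtered marker table."""
    scores: dict[str, dict[str, float]] = {}
    inters: dict[str, dict[str, list[str]]] = {}
    for cl in sorted(marker_table["cluster"].unique()):
        top = top_markers(marker_table, cl, k)
        if top.empty or float(top["log2fc"].max()) <= 0:
            scores[cl] = {t: 0.0 for t in ref}
            inters[cl] = {t: [] for t in ref}
            continue
        scores[cl], inters[cl] = score_cluster(top, ref, normalization)
    return assign_types(scores, inters)


def annotation_accuracy(result: AnnotationResult,
                        cluster_types: dict[str, str]
                        ) -> tuple[float, pd.DataFrame]:
    """Fraction of clusters assigned their true type, plus a per-cluster
    confusion listing. ``cluster_types`` maps cluster label -> true type."""
    missing = set(cluster_types) - set(result.clusters)
    if missing:
        raise ValueError(f"clusters missing from result: {sorted(missing)}")
    rows = []
    for cl, truth in cluster_types.items():
        assigned = result.clusters[cl].assigned
        rows.append((cl, truth, assigned, assigned == truth))
    confusion = pd.DataFrame(
        rows, columns=["cluster", "true_type", "assigned", "correct"])
    return float(confusion["correct"].mean()), confusion
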