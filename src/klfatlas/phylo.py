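"""Protein-family phylogenetics: p-distances and neighbor joining.

Distances are uncorrected p-distances with pairwise gap deletion (Poisson
correction optional); trees are built with the Saitou-Nei neighbor-joining
algorithm, exact on additive distance matrices. Clade groups are obtained by
cutting the longest internal branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = ["DistanceMatrix", "Tree", "p_distance", "neighbor_joining",
           "extract_clades", "read_alignment", "read_distance_tsv",
           "write_distance_tsv"]


@dataclass
class DistanceMatrix:
    names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match names")
        if np.any(self.values < 0):
            raise ValueError("negative distances")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("diagonal must be zero")


@dataclass
class Tree:
    """Unrooted tree as an edge list over integer node ids.

    Leaves carry taxon names; internal nodes have name None. Branch lengths
    are clamped nonnegative during construction.
    """

    node_names: dict[int, str | None]
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def leaves(self) -> list[int]:
        return [n for n, name in self.node_names.items() if name is not None]

    @property
    def leaf_names(self) -> list[str]:
        return [self.node_names[n] for n in self.leaves]

    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {n: [] for n in self.node_names}
        for u, v, ln in self.edges:
            adj[u].append((v, ln))
            adj[v].append((u, ln))
        return adj

    def leaf_distances(self) -> pd.DataFrame:
        """All-pairs path lengths between leaves (additivity checks)."""
        adj = self.adjacency()
        leaves = self.leaves
        names = [self.node_names[n] for n in leaves]
        out = pd.DataFrame(0.0, index=names, columns=names)
        for start in leaves:
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, ln in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + ln
                        stack.append(v)
            for leaf in leaves:
                out.loc[self.node_names[start], self.node_names[leaf]] = dist[leaf]
        return out

    def to_newick(self) -> str:
        adj = self.adjacency()
        # root at an internal node if any (standard unrooted representation)
        internal = [n for n, name in self.node_names.items() if name is None]
        root = internal[0] if internal else self.leaves[0]

        def fmt(node, parent):
            children = [(v, ln) for v, ln in adj[node] if v != parent]
            if not children:
                return self.node_names[node]
            inner = ",".join(f"{fmt(v, node)}:{ln:.10g}" for v, ln in children)
            return f"({inner})"

        return fmt(root, None) + ";"


def read_alignment(path) -> list[tuple[str, str]]:
    """Aligned FASTA -> list of (name, sequence)."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no sequences found")
    return records


GAP_CHARS = frozenset("-.")


def p_distance(alignment, poisson_correct: bool = False) -> DistanceMatrix:
    """Pairwise mismatch fraction over positions where neither sequence has
    a gap. ``poisson_correct=True`` applies -ln(1 - p)."""
    if hasattr(alignment, "items"):
        alignment = list(alignment.items())
    names = [name for name, _ in alignment]
    seqs = [seq for _, seq in alignment]
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must have equal (aligned) length")
    arr = np.array([list(s) for s in seqs])
    gaps = np.isin(arr, list(GAP_CHARS))
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gaps[i] & ~gaps[j]
            n_ok = int(ok.sum())
            if n_ok == 0:
                raise ValueError(
                    f"no comparable positions between {names[i]!r} and "
                    f"{names[j]!r}")
            p = float((arr[i, ok] != arr[j, ok]).mean())
            if poisson_correct:
                if p >= 1.0:
                    raise ValueError("p-distance of 1 cannot be corrected")
                p = -float(np.log(1.0 - p))
            d[i, j] = d[j, i] = p
    return DistanceMatrix(names=names, values=d)


def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    At each step join the pair minimizing
    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k),
    with ties broken by lexicographic order of the smallest leaf name in
    each subtree. Negative branch lengths are clamped to zero. Exact on
    additive matrices.
    """
    n = len(D.names)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    node_names: dict[int, str | None] = {i: name for i, name in enumerate(D.names)}
    edges: list[tuple[int, int, float]] = []
    # sort key per active node: smallest leaf name in its subtree
    key = {i: name for i, name in enumerate(D.names)}
    active = list(range(n))
    dist = {(i, j): D.values[i, j] for i in range(n) for j in range(n) if i < j}

    def d(i, j):
        return 0.0 if i == j else dist[(i, j) if i < j else (j, i)]

    next_id = n
    while len(active) > 2:
        m = len(active)
        row_sum = {i: sum(d(i, k) for k in active) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - row_sum[i] - row_sum[j]
                tie_key = tuple(sorted((key[i], key[j])))
                cand = (q, tie_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        new = next_id
        next_id += 1
        li = 0.5 * d(i, j) + (row_sum[i] - row_sum[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        node_names[new] = None
        edges.append((new, i, li))
        edges.append((new, j, lj))
        key[new] = min(key[i], key[j])
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
            dist[(min(new, k), max(new, k))] = max(dk, 0.0)
        active = [k for k in active if k not in (i, j)] + [new]
    i, j = active
    edges.append((i, j, max(d(i, j), 0.0)))
    return Tree(node_names=node_names, edges=edges)


def extract_clades(tree: Tree, k: int) -> list[set[str]]:
    """Partition the leaves into ``k`` groups by cutting the longest
    branches, internal branches first (the formalization of drawing clade
    boundaries at the deepest splits of the tree)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    leaves = set(tree.leaves)
    if k > len(leaves):
        raise ValueError(f"k={k} exceeds {len(leaves)} leaves")
    is_internal = {n: name is None for n, name in tree.node_names.items()}
    indexed = list(enumerate(tree.edges))
    # priority: internal-internal edges by length desc, then pendant edges
    indexed.sort(key=lambda e: (
        not (is_internal[e[1][0]] and is_internal[e[1][1]]),
        -e[1][2], e[0]))
    cut: set[int] = set()

    def group_count():
        adj: dict[int, list[int]] = {n: [] for n in tree.node_names}
        for idx, (u, v, _) in enumerate(tree.edges):
            if idx in cut:
                continue
            adj[u].append(v)
            adj[v].append(u)
        seen: set[int] = set()
        groups = []
        for n in tree.node_names:
            if n in seen:
                continue
            comp = []
            stack = [n]
            seen.add(n)
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            names = {tree.node_names[c] for c in comp if c in leaves}
            if names:
                groups.append(names)
        return groups

    groups = group_count()
    for idx, _edge in indexed:
        if len(groups) >= k:
            break
        cut.add(idx)
        groups = group_count()
    if len(groups) != k:
        raise ValueError(f"could not partition into exactly {k} groups")
    return sorted(groups, key=lambda g: sorted(g)[0])


def read_distance_tsv(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("distance TSV must have matching row/column names")
    return DistanceMatrix(names=list(df.index), values=df.to_numpy(float))


def write_distance_tsv(D: DistanceMatrix, path) -> None:
    pd.DataFrame(D.values, index=D.names, columns=D.names).to_csv(path, sep="\t")
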