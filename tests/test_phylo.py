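"""p-distance, neighbor joining (vs additive oracles and scikit-bio),
clade extraction, and Newick round-trips."""

import dendropy
import numpy as np
import pytest
import skbio

from klfatlas.phylo import (DistanceMatrix, Tree, extract_clades,
                            neighbor_joining, p_distance, read_distance_tsv,
                            write_distance_tsv)


# ------------------------------------------------------------- oracles
def random_additive_tree(n_leaves, rng):
    """Random binary topology with random branch lengths; returns the
    leaf-distance matrix computed by brute-force path summation on an
    independent adjacency structure."""
    nodes = [f"T{i}" for i in range(n_leaves)]
    adj = {}
    active = list(nodes)
    nxt = 0
    while len(active) > 2:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[min(i, j)], active[max(i, j)]
        new = f"I{nxt}"
        nxt += 1
        for child in (a, b):
            ln = float(rng.uniform(0.1, 2.0))
            adj.setdefault(new, []).append((child, ln))
            adj.setdefault(child, []).append((new, ln))
        active = [x for x in active if x not in (a, b)] + [new]
    ln = float(rng.uniform(0.1, 2.0))
    a, b = active
    adj.setdefault(a, []).append((b, ln))
    adj.setdefault(b, []).append((a, ln))

    D = np.zeros((n_leaves, n_leaves))
    for i, start in enumerate(nodes):
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, leaf in enumerate(nodes):
            D[i, j] = dist[leaf]
    return DistanceMatrix(names=nodes, values=D)


# ------------------------------------------------------------- p-distance
def test_p_distance_counts():
    D = p_distance([("a", "AAAA"), ("b", "AAAT")])
    assert D.values[0, 1] == 0.25
    D = p_distance([("a", "ACGT"), ("b", "ACGT")])
    assert D.values[0, 1] == 0.0


def test_p_distance_gap_skipping_and_errors():
    D = p_distance([("a", "A-AA"), ("b", "AGAT")])
    assert D.values[0, 1] == pytest.approx(1 / 3)
    with pytest.raises(ValueError, match="equal"):
        p_distance([("a", "AA"), ("b", "AAA")])
    with pytest.raises(ValueError, match="comparable"):
        p_distance([("a", "A-"), ("b", "-A")])
    with pytest.raises(ValueError):
        p_distance([("a", "AA")])


def test_p_distance_poisson_correction():
    D = p_distance([("a", "AAAA"), ("b", "AAAT")], poisson_correct=True)
    assert D.values[0, 1] == pytest.approx(-np.log(0.75))


# ------------------------------------------------------------- NJ
def test_nj_recovers_known_quartet():
    """Additive matrix from ((A:1,B:4):1,(C:2,D:3)) -> exact recovery."""
    D = DistanceMatrix(list("ABCD"), np.array(
        [[0, 5, 4, 5], [5, 0, 7, 8], [4, 7, 0, 5], [5, 8, 5, 0]], float))
    tree = neighbor_joining(D)
    path = tree.leaf_distances()
    assert np.allclose(path.loc[list("ABCD"), list("ABCD")].to_numpy(),
                       D.values, atol=1e-12)
    assert extract_clades(tree, 2) == [{"A", "B"}, {"C", "D"}]


def test_nj_three_taxa_closed_form():
    D = DistanceMatrix(list("ABC"),
                       np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
    tree = neighbor_joining(D)
    path = tree.leaf_distances()
    assert np.allclose(path.to_numpy(), D.values, atol=1e-12)


def test_nj_invalid_matrices_rejected():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(list("AB"), np.array([[0, 1], [2, 0]], float))
    with pytest.raises(ValueError, match="negative"):
        DistanceMatrix(list("AB"), np.array([[0, -1], [-1, 0]], float))
    with pytest.raises(ValueError, match="3 taxa"):
        neighbor_joining(DistanceMatrix(list("AB"),
                                        np.array([[0, 1], [1, 0]], float)))


@pytest.mark.parametrize("n_leaves", [4, 6, 9, 12])
def test_nj_exact_on_random_additive_matrices(n_leaves):
    rng = np.random.default_rng(n_leaves)
    for rep in range(5):
        D = random_additive_tree(n_leaves, rng)
        tree = neighbor_joining(D)
        path = tree.leaf_distances()
        assert np.allclose(path.loc[D.names, D.names].to_numpy(), D.values,
                           atol=1e-9)


def test_nj_matches_skbio_oracle():
    rng = np.random.default_rng(99)
    D = random_additive_tree(7, rng)
    ours = neighbor_joining(D)
    sym = (D.values + D.values.T) / 2.0  # exact symmetry for skbio
    sk = skbio.tree.nj(skbio.DistanceMatrix(sym, ids=D.names))
    for a in D.names:
        for b in D.names:
            if a == b:
                continue
            assert ours.leaf_distances().loc[a, b] == pytest.approx(
                sk.find(a).distance(sk.find(b)), abs=1e-9)


def test_newick_round_trip():
    rng = np.random.default_rng(7)
    D = random_additive_tree(8, rng)
    tree = neighbor_joining(D)
    newick = tree.to_newick()
    parsed = dendropy.Tree.get(data=newick, schema="newick")
    pdm = parsed.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in parsed.taxon_namespace}
    ours = tree.leaf_distances()
    for a in D.names:
        for b in D.names:
            if a != b:
                assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                    ours.loc[a, b], abs=1e-6)


# ------------------------------------------------------------- clades
def test_extract_clades_edge_cases():
    D = DistanceMatrix(list("ABCD"), np.array(
        [[0, 5, 4, 5], [5, 0, 7, 8], [4, 7, 0, 5], [5, 8, 5, 0]], float))
    tree = neighbor_joining(D)
    assert extract_clades(tree, 1) == [{"A", "B", "C", "D"}]
    singles = extract_clades(tree, 4)
    assert sorted(map(sorted, singles)) == [["A"], ["B"], ["C"], ["D"]]
    with pytest.raises(ValueError):
        extract_clades(tree, 0)
    with pytest.raises(ValueError):
        extract_clades(tree, 5)


def test_extract_clades_three_groups():
    # three well-separated cherries joined by long internal branches
    rng = np.random.default_rng(1)
    names = ["a1", "a2", "b1", "b2", "c1", "c2"]
    group = {n: n[0] for n in names}
    D = np.zeros((6, 6))
    for i in range(6):
        for j in range(6):
            if i == j:
                continue
            D[i, j] = 0.2 if group[names[i]] == group[names[j]] else 3.0
    tree = neighbor_joining(DistanceMatrix(names, D))
    clades = extract_clades(tree, 3)
    assert clades == [{"a1", "a2"}, {"b1", "b2"}, {"c1", "c2"}]


def test_distance_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    D = random_additive_tree(5, rng)
    write_distance_tsv(D, tmp_path / "d.tsv")
    back = read_distance_tsv(tmp_path / "d.tsv")
    assert back.names == D.names
    assert np.allclose(back.values, D.values)
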