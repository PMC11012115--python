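"""Alignment, distances, neighbor joining, bootstrap and rooting."""

import numpy as np
import pytest

from orexpress.phylo import (
    MultipleAlignment,
    align,
    bootstrap_and_root,
    distance_matrix,
    jukes_cantor,
    neighbor_joining,
)


def random_tree_distances(n_leaves, rng):
    """Random binary tree -> (additive distance matrix, set of bipartitions).

    Built by random sequential joins, independent of the NJ implementation.
    """
    ids = [f"t{i}" for i in range(n_leaves)]
    # paths: leaf -> dict(node -> distance); nodes are frozensets of leaves
    clusters = {i: {frozenset([ids[i]]): 0.0} for i in range(n_leaves)}
    sets = {i: frozenset([ids[i]]) for i in range(n_leaves)}
    D = np.zeros((n_leaves, n_leaves))
    dist_to_cluster = {i: {ids[i]: 0.0} for i in range(n_leaves)}
    splits = set()
    active = list(range(n_leaves))
    nxt = n_leaves
    while len(active) > 1:
        i, j = sorted(rng.choice(active, size=2, replace=False))
        li, lj = rng.uniform(0.05, 1.0), rng.uniform(0.05, 1.0)
        for a in dist_to_cluster[i]:
            for b in dist_to_cluster[j]:
                ai, bi = ids.index(a), ids.index(b)
                d = dist_to_cluster[i][a] + li + lj + dist_to_cluster[j][b]
                D[ai, bi] = D[bi, ai] = d
        merged = {a: d + li for a, d in dist_to_cluster[i].items()}
        merged.update({b: d + lj for b, d in dist_to_cluster[j].items()})
        sets[nxt] = sets[i] | sets[j]
        if 2 <= len(sets[nxt]) <= n_leaves - 2:
            splits.add(sets[nxt])
        dist_to_cluster[nxt] = merged
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    return ids, D, splits


def canonical_splits(tree):
    universe = frozenset(tree.leaf_names.values())
    out = set()
    for split in tree.bipartitions():
        if 2 <= len(split) <= len(universe) - 2:
            other = universe - split
            out.add(min(split, other, key=lambda s: tuple(sorted(s))))
    return out


def canonical(splits, ids):
    universe = frozenset(ids)
    out = set()
    for s in splits:
        if 2 <= len(s) <= len(universe) - 2:
            out.add(min(s, universe - s, key=lambda x: tuple(sorted(x))))
    return out


# ---------------------------------------------------------------------------
# alignment


def test_identical_sequences_align_without_gaps():
    s = "ATGGCCAAATTTGGG"
    aln = align({"a": s, "b": s, "c": s})
    assert aln.rows == [s, s, s]
    assert aln.ids == ["a", "b", "c"]


def test_single_deletion_produces_exactly_that_gap():
    full = "ATGGCCAAATTTGGGCCCAAA"
    short = full[:9] + full[15:]  # 6-base deletion
    aln = align({"a": full, "b": short, "c": full})
    row_b = aln.rows[aln.ids.index("b")]
    assert row_b.count("-") == 6
    assert row_b.replace("-", "") == short


def test_alignment_degap_round_trip(genome):
    from orexpress.synthetic import gene_sequences

    seqs = gene_sequences(genome.contigs, genome.annotations)
    intact = {
        a.gene_id: seqs[a.gene_id]
        for a in genome.annotations
        if a.is_or and a.true_status == "intact"
    }
    sub = dict(list(intact.items())[:5])
    aln = align(sub)
    for i, gid in enumerate(aln.ids):
        assert aln.degapped(i) == sub[gid]


def test_alignment_input_order_invariance():
    seqs = {"x": "ACGTACCTGGATTT", "y": "ACGAACCTGGATTT", "z": "ACTTACCAGGATTT", "w": "AGGTACCTGAATTT"}
    a1 = align(seqs)
    a2 = align(dict(reversed(list(seqs.items()))))
    assert a1.ids == a2.ids and a1.rows == a2.rows


def test_alignment_needs_three_sequences():
    with pytest.raises(ValueError):
        align({"a": "ACGT", "b": "ACGT"})


# ---------------------------------------------------------------------------
# distances


def test_jukes_cantor_closed_form():
    assert jukes_cantor(0.0) == 0.0
    assert jukes_cantor(0.03) == pytest.approx(-0.75 * np.log(1 - 0.04), rel=1e-12)


def test_jukes_cantor_saturation_capped():
    with pytest.warns(UserWarning, match="saturated"):
        assert jukes_cantor(0.8) == 10.0


def test_distance_matrix_symmetric_zero_diagonal():
    aln = MultipleAlignment(
        ids=["a", "b", "c"],
        rows=["ACGTACGTAC", "ACGTACGAAC", "AC-TACGTAT"],
    )
    D = distance_matrix(aln)
    assert np.allclose(D, D.T)
    assert np.all(np.diag(D) == 0)
    # identical rows -> 0 distance
    aln2 = MultipleAlignment(ids=["a", "b", "c"], rows=["ACGT", "ACGT", "AGGT"])
    assert distance_matrix(aln2)[0, 1] == 0.0


def test_distance_uses_pairwise_deletion():
    # gap column ignored for the (a, b) pair: 1 mismatch over 8 columns
    aln = MultipleAlignment(ids=["a", "b"], rows=["ACGTACGTA", "ACGTACG-C"])
    D = distance_matrix(aln)
    assert D[0, 1] == pytest.approx(jukes_cantor(1 / 8))


# ---------------------------------------------------------------------------
# neighbor joining


def test_nj_three_taxa_closed_form():
    D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
    tree = neighbor_joining(D, ["A", "B", "C"])
    lengths = {tree.leaf_names[u] if u in tree.leaf_names else "inner": l for u, v, l in tree.edges()}
    by_leaf = {}
    for u, v, l in tree.edges():
        leaf = tree.leaf_names.get(u) or tree.leaf_names.get(v)
        by_leaf[leaf] = l
    assert by_leaf["A"] == pytest.approx((2 + 3 - 4) / 2)
    assert by_leaf["B"] == pytest.approx((2 + 4 - 3) / 2)
    assert by_leaf["C"] == pytest.approx((3 + 4 - 2) / 2)


def test_nj_four_taxa_additive_exact():
    # tree: A-u:1, B-u:2, u-v:1, C-v:3, D-v:4
    D = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
    )
    tree = neighbor_joining(D, list("ABCD"))
    assert canonical_splits(tree) == {frozenset({"A", "B"})}
    lengths = sorted(l for _u, _v, l in tree.edges())
    assert lengths == pytest.approx([1, 1, 2, 3, 4])


def test_nj_recovers_random_additive_trees():
    rng = np.random.default_rng(2024)
    for _ in range(10):
        n = int(rng.integers(4, 13))
        ids, D, true_splits = random_tree_distances(n, rng)
        tree = neighbor_joining(D, ids)
        assert canonical_splits(tree) == canonical(true_splits, ids)


def test_nj_matches_dendropy_on_random_matrix():
    dendropy = pytest.importorskip("dendropy")
    rng = np.random.default_rng(5)
    ids, D, _splits = random_tree_distances(8, rng)
    ours = neighbor_joining(D, ids)

    # dendropy as an independent NJ oracle
    csv = "," + ",".join(ids) + "\n"
    for i, a in enumerate(ids):
        csv += a + "," + ",".join(str(D[i, j]) for j in range(len(ids))) + "\n"
    import io

    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        io.StringIO(csv), taxon_namespace=dendropy.TaxonNamespace(ids)
    )
    ref = pdm.nj_tree()
    ref_splits = set()
    ref.encode_bipartitions()
    universe = frozenset(ids)
    for edge in ref.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        side = frozenset(t.label for t in edge.bipartition.leafset_taxa(ref.taxon_namespace))
        if 2 <= len(side) <= len(ids) - 2:
            ref_splits.add(min(side, universe - side, key=lambda s: tuple(sorted(s))))
    assert canonical_splits(ours) == ref_splits


def test_nj_tie_break_is_deterministic():
    D = np.full((4, 4), 2.0)
    np.fill_diagonal(D, 0.0)
    t1 = neighbor_joining(D, list("ABCD"))
    t2 = neighbor_joining(D, list("ABCD"))
    assert t1.edges() == t2.edges()
    assert canonical_splits(t1) == {frozenset({"A", "B"})}, "lexicographic pair joins first"


def test_nj_rejects_asymmetric_matrix():
    D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
    with pytest.raises(ValueError):
        neighbor_joining(D, list("ABC"))


# ---------------------------------------------------------------------------
# bootstrap and rooting


@pytest.fixture(scope="module")
def intact_alignment(genome):
    from orexpress.synthetic import gene_sequences

    seqs = gene_sequences(genome.contigs, genome.annotations)
    intact = {
        a.gene_id: seqs[a.gene_id]
        for a in genome.annotations
        if a.is_or and a.true_status == "intact"
    }
    nonclass2 = sorted(
        a.gene_id
        for a in genome.annotations
        if a.true_status == "intact" and a.true_class == "nonclass2"
    )
    return align(intact), nonclass2


def test_bootstrap_deterministic_for_fixed_seed(intact_alignment):
    aln, nc2 = intact_alignment
    t1 = bootstrap_and_root(aln, 25, seed=7, nonclass2_ids=nc2)
    t2 = bootstrap_and_root(aln, 25, seed=7, nonclass2_ids=nc2)
    assert t1.newick() == t2.newick()


def test_single_replicate_supports_are_binary(intact_alignment):
    aln, nc2 = intact_alignment
    tree = bootstrap_and_root(aln, 1, seed=3, nonclass2_ids=nc2)

    def supports(node):
        out = [] if node.support is None else [node.support]
        for c in node.children:
            out.extend(supports(c))
        return out

    assert set(supports(tree.root)) <= {0.0, 100.0}


def test_class_split_has_full_support_and_root_separates_outgroup(intact_alignment):
    aln, nc2 = intact_alignment
    tree = bootstrap_and_root(aln, 50, seed=11, nonclass2_ids=nc2)
    assert tree.monophyletic_outgroup
    sides = [set(c.leaves()) for c in tree.root.children]
    assert set(nc2) in sides
    # the deep class split is recovered in every replicate
    outgroup_side = next(c for c in tree.root.children if set(c.leaves()) == set(nc2))
    ingroup_side = next(c for c in tree.root.children if set(c.leaves()) != set(nc2))
    for child in (outgroup_side, ingroup_side):
        if child.support is not None:
            assert child.support == 100.0


def test_bootstrap_requires_outgroup_present(intact_alignment):
    aln, _nc2 = intact_alignment
    with pytest.raises(ValueError):
        bootstrap_and_root(aln, 5, seed=1, nonclass2_ids=["missing_gene"])


def test_supports_invariant_under_leaf_relabeling(intact_alignment):
    aln, nc2 = intact_alignment
    t1 = bootstrap_and_root(aln, 20, seed=5, nonclass2_ids=nc2)
    mapping = {gid: f"X{i:02d}" for i, gid in enumerate(aln.ids)}
    renamed = MultipleAlignment(
        ids=[mapping[g] for g in aln.ids], rows=list(aln.rows)
    )
    order = np.argsort(renamed.ids)
    renamed = MultipleAlignment(
        ids=[renamed.ids[i] for i in order], rows=[renamed.rows[i] for i in order]
    )
    t2 = bootstrap_and_root(renamed, 20, seed=5, nonclass2_ids=[mapping[g] for g in nc2])

    def support_multiset(node, acc):
        if node.support is not None:
            acc.append(node.support)
        for c in node.children:
            support_multiset(c, acc)
        return acc

    # identical column resampling on identical rows: same supports, new names
    assert sorted(support_multiset(t1.root, [])) == sorted(support_multiset(t2.root, []))
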