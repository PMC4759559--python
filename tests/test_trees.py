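"""Distances, UPGMA, tree cutting, neighbor joining, Newick round trips."""

import random

import numpy as np
import pytest

from oracles import random_additive_tree, upgma_reference_merges
from phagepan.trees import (
    DistanceMatrix,
    NewickError,
    average_linkage_hcl,
    cut_tree,
    dendrogram_to_tree,
    from_newick,
    jaccard_distance_matrix,
    neighbor_joining,
    to_newick,
    tree_path_lengths,
)


class TestJaccard:
    def test_identical_vectors_zero(self):
        dm = jaccard_distance_matrix(
            np.array([[1, 1, 0], [1, 1, 0]], dtype=bool), ["a", "b"]
        )
        assert dm.d[0, 1] == 0.0

    def test_disjoint_vectors_one(self):
        dm = jaccard_distance_matrix(
            np.array([[1, 0], [0, 1]], dtype=bool), ["a", "b"]
        )
        assert dm.d[0, 1] == 1.0

    def test_hand_counted_example(self):
        dm = jaccard_distance_matrix(
            np.array([[1, 1, 0], [1, 0, 1]], dtype=bool), ["a", "b"]
        )
        assert dm.d[0, 1] == pytest.approx(1 - 1 / 3)

    def test_all_false_pair_zero_by_convention(self):
        dm = jaccard_distance_matrix(
            np.array([[0, 0], [0, 0]], dtype=bool), ["a", "b"]
        )
        assert dm.d[0, 1] == 0.0


class TestDistanceMatrix:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[0.1, 1.0], [1.0, 0.0]]))


TWO_BLOCK = DistanceMatrix(
    ["a", "b", "c", "d"],
    np.array([
        [0.0, 0.1, 0.9, 0.9],
        [0.1, 0.0, 0.9, 0.9],
        [0.9, 0.9, 0.0, 0.1],
        [0.9, 0.9, 0.1, 0.0],
    ]),
)


class TestAverageLinkage:
    def test_two_labels_single_merge(self):
        dm = DistanceMatrix(["x", "y"], np.array([[0.0, 0.4], [0.4, 0.0]]))
        dendro = average_linkage_hcl(dm)
        assert len(dendro.merges) == 1
        assert dendro.merges[0][2] == pytest.approx(0.4)

    def test_two_block_matrix_blocks_merge_first(self):
        dendro = average_linkage_hcl(TWO_BLOCK)
        first_two = {frozenset(m[0] | m[1]) for m in dendro.merges[:2]}
        assert first_two == {frozenset({"a", "b"}), frozenset({"c", "d"})}
        assert dendro.merges[2][2] == pytest.approx(0.9)

    def test_matches_from_scratch_oracle_small_matrices(self):
        rnd = random.Random(21)
        for trial in range(30):
            n = rnd.randint(2, 6)
            labels = [f"l{i}" for i in range(n)]
            d = [[0.0] * n for _ in range(n)]
            for i in range(n):
                for j in range(i + 1, n):
                    # quantized distances so ties actually occur
                    d[i][j] = d[j][i] = rnd.choice([0.2, 0.4, 0.6, 0.8])
            dendro = average_linkage_hcl(DistanceMatrix(labels, np.array(d)))
            expected = upgma_reference_merges(labels, d)
            ours = [
                (set(a), set(b), pytest.approx(h)) for a, b, h in dendro.merges
            ]
            theirs = [
                ({*a} if min(a) < min(b) else {*b},
                 {*b} if min(a) < min(b) else {*a}, h)
                for a, b, h in expected
            ]
            for (oa, ob, oh), (ea, eb, eh) in zip(ours, theirs):
                assert {frozenset(oa), frozenset(ob)} == {
                    frozenset(ea), frozenset(eb)
                }
                assert oh == pytest.approx(eh)

    def test_merge_heights_monotone(self):
        rnd = random.Random(8)
        for _ in range(10):
            n = rnd.randint(3, 9)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = rnd.uniform(0.05, 1.0)
            dendro = average_linkage_hcl(
                DistanceMatrix([f"x{i}" for i in range(n)], d)
            )
            heights = dendro.heights
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))


class TestCutTree:
    def test_k_one_single_cluster(self):
        dendro = average_linkage_hcl(TWO_BLOCK)
        assert set(cut_tree(dendro, 1).values()) == {1}

    def test_k_n_all_singletons(self):
        dendro = average_linkage_hcl(TWO_BLOCK)
        cut = cut_tree(dendro, 4)
        assert sorted(cut.values()) == [1, 2, 3, 4]

    def test_two_block_fixture_recovers_blocks(self):
        cut = cut_tree(average_linkage_hcl(TWO_BLOCK), 2)
        assert cut["a"] == cut["b"] != cut["c"] == cut["d"]

    def test_k_out_of_range_rejected(self):
        dendro = average_linkage_hcl(TWO_BLOCK)
        for k in (0, 5):
            with pytest.raises(ValueError):
                cut_tree(dendro, k)

    def test_successive_cuts_are_refinements(self):
        rnd = random.Random(31)
        n = 8
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = rnd.uniform(0.1, 1.0)
        dendro = average_linkage_hcl(DistanceMatrix([f"g{i}" for i in range(n)], d))
        for k in range(1, n):
            coarse = cut_tree(dendro, k)
            fine = cut_tree(dendro, k + 1)
            for a in dendro.labels:
                for b in dendro.labels:
                    if fine[a] == fine[b]:
                        assert coarse[a] == coarse[b]


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 5.0], [5.0, 0.0]]))
        tree = neighbor_joining(dm)
        paths = tree_path_lengths(tree)
        assert paths.value("a", "b") == pytest.approx(5.0)

    def test_four_taxon_additive_matrix_recovered(self):
        # tree: ((a:2,b:3):1,(c:4,d:5)); distances are path sums
        labels = ["a", "b", "c", "d"]
        d = np.array([
            [0.0, 5.0, 7.0, 8.0],
            [5.0, 0.0, 8.0, 9.0],
            [7.0, 8.0, 0.0, 9.0],
            [8.0, 9.0, 0.0, 0.0],
        ])
        d[3, 2] = d[2, 3] = 9.0
        d[3, 3] = 0.0
        tree = neighbor_joining(DistanceMatrix(labels, d))
        paths = tree_path_lengths(tree)
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                assert paths.value(x, y) == pytest.approx(d[i, j], abs=1e-9)

    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]]),
        )
        tree = neighbor_joining(dm)
        lengths = {c.name: c.length for c in tree.children}
        assert lengths == pytest.approx({"a": 1.0, "b": 1.0, "c": 3.0})

    def test_random_additive_trees_recovered(self):
        rnd = random.Random(77)
        for _ in range(12):
            labels, d = random_additive_tree(rnd.randint(4, 8), rnd)
            tree = neighbor_joining(DistanceMatrix(labels, d))
            paths = tree_path_lengths(tree)
            for i, x in enumerate(labels):
                for j, y in enumerate(labels):
                    assert paths.value(x, y) == pytest.approx(
                        d[i, j], abs=1e-9
                    )

    def test_negative_branch_lengths_clamped(self):
        rnd = random.Random(13)
        for _ in range(20):
            n = rnd.randint(4, 7)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = rnd.uniform(0.01, 1.0)
            tree = neighbor_joining(
                DistanceMatrix([f"t{i}" for i in range(n)], d)
            )

            def walk(node):
                assert node.length is None or node.length >= 0.0
                for c in node.children:
                    walk(c)

            walk(tree)


class TestNewick:
    def test_simple_round_trip(self):
        tree = from_newick("(A:1,B:1);")
        assert to_newick(tree) == "(A:1.000000,B:1.000000);"

    def test_random_trees_round_trip(self):
        rnd = random.Random(55)
        for _ in range(10):
            labels, d = random_additive_tree(20, rnd)
            tree = neighbor_joining(DistanceMatrix(labels, d))
            text = to_newick(tree)
            again = from_newick(text)
            assert to_newick(again) == text
            assert sorted(again.leaf_names()) == sorted(labels)

    def test_round_trip_preserves_path_lengths(self):
        rnd = random.Random(56)
        labels, d = random_additive_tree(12, rnd)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        again = from_newick(to_newick(tree))
        p1, p2 = tree_path_lengths(tree), tree_path_lengths(again)
        assert np.allclose(p1.d, p2.d, atol=1e-5)  # 6-decimal serialization

    def test_nj_root_is_trifurcating(self):
        rnd = random.Random(57)
        labels, d = random_additive_tree(6, rnd)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert len(tree.children) == 3

    @pytest.mark.parametrize(
        "text", ["(A:1,B:1)", "(A,B;", "(A,,B);", "(A:x,B:1);"]
    )
    def test_malformed_reports_position(self, text):
        with pytest.raises(NewickError, match="position"):
            from_newick(text)

    def test_quoted_labels(self):
        text = "('taxon one':1.000000,'it''s':2.000000);"
        tree = from_newick(text)
        assert sorted(tree.leaf_names()) == ["it's", "taxon one"]
        assert to_newick(tree) == text

    def test_agrees_with_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        rnd = random.Random(58)
        labels, d = random_additive_tree(10, rnd)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        text = to_newick(tree)
        dtree = dendropy.Tree.get(data=text, schema="newick")
        pdm = dtree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dtree.taxon_namespace}
        ours = tree_path_lengths(tree)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                    ours.value(a, b), abs=1e-5
                )


def test_dendrogram_to_tree_is_ultrametric():
    dendro = average_linkage_hcl(TWO_BLOCK)
    tree = dendrogram_to_tree(dendro)
    paths = tree_path_lengths(tree)
    # leaf depth = final merge height / 2 for every leaf
    root_height = dendro.heights[-1]
    for a in ("a", "b"):
        for b in ("c", "d"):
            assert paths.value(a, b) == pytest.approx(root_height)
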