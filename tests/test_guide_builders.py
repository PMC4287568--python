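"""Distance matrices, clustering and chained guide-tree construction."""
import numpy as np
import pytest

from treealign import (
    DistanceMatrix,
    GuideTree,
    OrderingSpec,
    SequenceRecord,
    build_distance_matrix,
    chained_tree_from_order,
    cluster_guide_tree,
    ktuple_distance,
    nj_guide_tree,
    order_by_descriptors,
    percent_identity,
    shape_of,
)
from treealign.guide_builders import BuilderError
from treealign.tree_metrics import rooted_rf_distance

from conftest import random_records


def dm(ids, square):
    return DistanceMatrix(ids=tuple(ids), values=np.array(square, dtype=float))


class TestDistanceMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(BuilderError):
            dm("ab", [[0, 1], [2, 0]])  # asymmetric
        with pytest.raises(BuilderError):
            dm("ab", [[1, 0], [0, 0]])  # nonzero diagonal

    def test_identical_sequences_zero_distances(self):
        recs = [SequenceRecord(f"s{i}", "MKVAW") for i in range(3)]
        for method in ("ktuple", "aligned_identity"):
            D = build_distance_matrix(recs, method=method)
            assert np.allclose(D.values, 0.0)

    def test_entries_match_descriptor_module(self):
        rng = np.random.default_rng(31)
        recs = random_records(rng, n=3, min_len=6, max_len=12)
        Dk = build_distance_matrix(recs, method="ktuple", k=2)
        Da = build_distance_matrix(recs, method="aligned_identity")
        for i in range(3):
            for j in range(i + 1, 3):
                assert Dk.values[i, j] == pytest.approx(
                    ktuple_distance(recs[i], recs[j], k=2))
                assert Da.values[i, j] == pytest.approx(
                    1.0 - percent_identity(recs[i], recs[j]) / 100.0)


class TestClusterGuideTree:
    def test_upgma_hand_agglomeration(self):
        D = dm("ABC", [[0, 2, 4], [2, 0, 4], [4, 4, 0]])
        tree = cluster_guide_tree(D, "upgma")
        assert tree.canonical_newick() == "((A,B),C);"
        depths = {}

        def walk(node, d):
            if node.is_leaf:
                depths[node.label] = d
            for c in node.children:
                walk(c, d + c.length)

        walk(tree.root, 0.0)
        # A,B join at height 1, C at height 2
        assert depths == pytest.approx({"A": 2.0, "B": 2.0, "C": 2.0})
        ab = next(c for c in tree.root.children if not c.is_leaf)
        assert ab.length == pytest.approx(1.0)

    def test_ultrametric_input_reproduced_exactly(self):
        """UPGMA recovers the generating ultrametric tree, topology and
        heights; single and complete agree on the topology."""
        # heights: (a,b) at 1, ((a,b),c) at 3, root at 5 with (d,e) at 2
        ids = list("abcde")
        h = {frozenset("ab"): 2.0, frozenset("ac"): 6.0, frozenset("bc"): 6.0,
             frozenset("de"): 4.0}
        D = np.zeros((5, 5))
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i == j:
                    continue
                D[i, j] = h.get(frozenset(x + y), 10.0)
        mat = dm(ids, D)
        expected = "(((a,b),c),(d,e));"
        for scheme in ("upgma", "single", "complete"):
            assert cluster_guide_tree(mat, scheme).canonical_newick() == expected
        # UPGMA heights = half the merge distances
        tree = cluster_guide_tree(mat, "upgma")
        depths = {}

        def walk(node, d):
            if node.is_leaf:
                depths[node.label] = d
            for c in node.children:
                walk(c, d + c.length)

        walk(tree.root, 0.0)
        assert all(d == pytest.approx(5.0) for d in depths.values())

    def test_two_sequences_unique_cherry_for_all_schemes(self):
        D = dm("xy", [[0, 3], [3, 0]])
        for scheme in ("single", "complete", "mean", "ward", "upgma"):
            tree = cluster_guide_tree(D, scheme)
            assert tree.canonical_newick() == "(x,y);"

    def test_unknown_scheme_rejected(self):
        with pytest.raises(BuilderError):
            cluster_guide_tree(dm("ab", [[0, 1], [1, 0]]), "median")

    def test_output_covers_input_ids(self):
        rng = np.random.default_rng(41)
        v = rng.random((6, 6))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        D = DistanceMatrix(ids=tuple("uvwxyz"), values=v)
        for scheme in ("single", "complete", "mean", "ward", "upgma"):
            tree = cluster_guide_tree(D, scheme)
            assert tree.label_set() == frozenset("uvwxyz")


class TestNJGuideTree:
    def test_additive_four_leaf_recovery(self):
        # unrooted tree ((A:1,B:2):1,(C:3,D:1)): split AB|CD
        D = dm("ABCD", [[0, 3, 5, 3],
                        [3, 0, 6, 4],
                        [5, 6, 0, 4],
                        [3, 4, 4, 0]])
        tree = nj_guide_tree(D)
        clades = {frozenset(GuideTree(n, validate=False).leaf_labels())
                  for n in tree.root.postorder() if not n.is_leaf}
        assert frozenset("AB") in clades or frozenset("CD") in clades

    def test_three_leaves_rooted_binary(self):
        D = dm("ABC", [[0, 2, 3], [2, 0, 3], [3, 3, 0]])
        tree = nj_guide_tree(D)
        assert tree.label_set() == frozenset("ABC")
        assert len(tree.root.children) == 2

    def test_too_few_sequences_rejected(self):
        with pytest.raises(BuilderError):
            nj_guide_tree(dm("ab", [[0, 1], [1, 0]]))


class TestChainedTrees:
    def test_definition(self):
        tree = chained_tree_from_order(["a", "b", "c", "d"])
        assert tree.canonical_newick() == "(((a,b),c),d);"

    def test_shape_is_perfectly_chained(self):
        tree = chained_tree_from_order(list("abcdef"))
        assert shape_of(tree).symmetry_degree == 1

    def test_reversal_changes_labeling_not_shape(self):
        fwd = chained_tree_from_order(list("abcde"))
        rev = chained_tree_from_order(list("edcba"))
        assert shape_of(fwd) == shape_of(rev)
        assert fwd.canonical_newick() != rev.canonical_newick()

    def test_duplicates_rejected(self):
        with pytest.raises(BuilderError):
            chained_tree_from_order(["a", "a", "b"])


class TestOrderings:
    def make_family(self):
        return [
            SequenceRecord("s1", "MKVAW"),        # len 5
            SequenceRecord("s2", "MKV"),          # len 3
            SequenceRecord("s3", "MKVAWDEQRPL"),  # len 11 (9 would tie-test)
            SequenceRecord("s4", "MKVAWDE"),      # len 7
        ]

    def test_length_ascending(self):
        order = order_by_descriptors(self.make_family(), "len/a")
        assert order == ["s2", "s1", "s4", "s3"]

    def test_length_descending(self):
        order = order_by_descriptors(self.make_family(), "len/d")
        assert order == ["s3", "s4", "s1", "s2"]

    def test_stability_on_all_ties(self):
        fam = [SequenceRecord(f"t{i}", "MKVAW") for i in range(4)]
        order = order_by_descriptors(fam, OrderingSpec("len", "asc"))
        assert order == ["t0", "t1", "t2", "t3"]

    def test_hi_descending_puts_most_similar_pair_first(self):
        fam = [SequenceRecord("A", "AAAA"), SequenceRecord("B", "CCCC"),
               SequenceRecord("C", "DDDD")]
        from treealign.descriptors import family_descriptors

        identity = {("A", "B"): 90.0, ("B", "A"): 90.0,
                    ("A", "C"): 50.0, ("C", "A"): 50.0,
                    ("B", "C"): 50.0, ("C", "B"): 50.0}
        desc = family_descriptors(fam, identity=identity)
        order = order_by_descriptors(fam, "hi/d", descriptors=desc)
        assert order[:2] == ["A", "B"]

    def test_secondary_key_breaks_ties(self):
        fam = [SequenceRecord("p", "KKKK"), SequenceRecord("q", "DDDD"),
               SequenceRecord("r", "KKKK")]
        # all length 4; secondary ip/d puts basic (high-pI) sequences first
        order = order_by_descriptors(fam, "len/a+ip/d")
        assert order == ["p", "r", "q"]

    def test_spec_parsing_and_errors(self):
        spec = OrderingSpec.parse("hi/d+len/a")
        assert spec.key == "hi" and spec.direction == "desc"
        assert spec.secondary.key == "len"
        assert spec.short() == "hi/d+len/a"
        with pytest.raises(BuilderError):
            OrderingSpec.parse("mass/a")
        with pytest.raises(BuilderError):
            OrderingSpec.parse("len/a+ip/d+hm/a")
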