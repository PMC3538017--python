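import io

import numpy as np
import pytest
from scipy.spatial.distance import jaccard as scipy_jaccard
from skbio import DistanceMatrix, TreeNode

from _oracles import random_additive_tree
from conftest import build_table
from capssr.genotype_typing import NULL
from capssr.diversity import (assign_clusters, binarize_bands,
                              clamp_negative_branches, distance_matrix,
                              jaccard_distance, neighbor_joining,
                              negative_branches)


def bipartitions(tree):
    """Set of non-trivial leaf bipartitions (as frozensets of the smaller
    side's names) — a topology fingerprint for unrooted trees."""
    all_tips = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if len(side) > 1 and len(other) > 1:
            parts.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return parts


class TestBinarizeBands:
    def test_codominant_marker_band_scoring(self):
        table = build_table({"m1": {"x": 100, "y": 102}})
        band = binarize_bands(table)
        assert band.bands == [("m1", 100), ("m1", 102)]
        assert band.vector("x").tolist() == [1, 0]
        assert band.vector("y").tolist() == [0, 1]

    def test_dominant_marker_single_band(self):
        table = build_table({"m1": {"x": 100, "y": NULL, "z": 100}})
        band = binarize_bands(table)
        assert band.bands == [("m1", 100)]
        assert band.matrix[:, 0].tolist() == [1, 0, 1]

    def test_heterozygote_scores_both_bands(self):
        table = build_table({"m1": {"x": (100, 102), "y": 100, "z": 102}})
        band = binarize_bands(table)
        assert band.vector("x").tolist() == [1, 1]

    def test_monomorphic_markers_dropped_and_distance_errors(self):
        table = build_table({"m1": {"x": 100, "y": 100}})
        band = binarize_bands(table)
        assert band.bands == []
        with pytest.raises(ValueError, match="no bands"):
            distance_matrix(band)


class TestJaccardDistance:
    def test_identical_vectors(self):
        assert jaccard_distance([1, 0, 1], [1, 0, 1]) == 0.0

    def test_disjoint_band_sets(self):
        assert jaccard_distance([1, 1, 0], [0, 0, 1]) == 1.0

    def test_counted_example(self):
        assert jaccard_distance([1, 1, 0, 0], [1, 0, 1, 0]) == \
            pytest.approx(2.0 / 3.0)

    def test_shared_absences_ignored(self):
        assert jaccard_distance([1, 0, 0, 0], [1, 0, 0, 0]) == 0.0

    def test_all_zero_pair_is_an_error(self):
        with pytest.raises(ValueError, match="no bands"):
            jaccard_distance([0, 0], [0, 0])

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.integers(0, 2, size=30)
            b = rng.integers(0, 2, size=30)
            if not (a | b).any():
                continue
            assert jaccard_distance(a, b) == pytest.approx(
                scipy_jaccard(a.astype(bool), b.astype(bool)))

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 1000:
            a, b, c = (rng.integers(0, 2, size=12) for _ in range(3))
            if not ((a | b).any() and (b | c).any() and (a | c).any()):
                continue
            dab = jaccard_distance(a, b)
            dbc = jaccard_distance(b, c)
            dac = jaccard_distance(a, c)
            assert dac <= dab + dbc + 1e-12
            checked += 1

    def test_distance_matrix_agrees_with_pairwise_calls(self):
        table = build_table({
            "m1": {"x": 100, "y": 102, "z": (100, 102)},
            "m2": {"x": 90, "y": 90, "z": NULL},
        })
        band = binarize_bands(table)
        dm = distance_matrix(band)
        for i, a in enumerate(band.lines):
            for j, b in enumerate(band.lines):
                if i != j:
                    assert dm[a, b] == pytest.approx(
                        jaccard_distance(band.matrix[i], band.matrix[j]))


class TestNeighborJoining:
    def test_three_leaf_closed_form(self):
        dm = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ids=list("ABC"))
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_fewer_than_three_leaves_is_an_error(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ids=["A", "B"]))

    def test_four_leaf_tree_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) -> additive distances
        dm = DistanceMatrix([[0, 3, 5, 3],
                             [3, 0, 6, 4],
                             [5, 6, 0, 4],
                             [3, 4, 4, 0]], ids=list("ABCD"))
        tree = neighbor_joining(dm)
        assert bipartitions(tree) == {frozenset({"A", "B"})}
        patristic = tree.tip_tip_distances(endpoints=list("ABCD"))
        np.testing.assert_allclose(patristic.data, dm.data, atol=1e-12)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 1})

    def test_additivity_on_random_six_leaf_trees(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            newick, leaves, D = random_additive_tree(rng, 6)
            dm = DistanceMatrix(D, ids=leaves)
            tree = neighbor_joining(dm)
            patristic = tree.tip_tip_distances(endpoints=leaves)
            np.testing.assert_allclose(patristic.data, D, atol=1e-9)
            # topology matches the generating tree
            truth = TreeNode.read(io.StringIO(newick))
            assert bipartitions(tree) == bipartitions(truth)

    def test_agrees_with_independent_nj_implementation(self):
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(3)
        for _ in range(5):
            newick, leaves, D = random_additive_tree(rng, 8)
            dm = DistanceMatrix(D, ids=leaves)
            ours = neighbor_joining(dm)
            theirs = skbio_nj(dm)
            assert bipartitions(ours) == bipartitions(theirs)

    def test_negative_branch_report_and_clamping(self):
        # a sharply non-additive matrix produces a negative NJ branch
        dm = DistanceMatrix([[0, 1, 9, 9.1],
                             [1, 0, 9.1, 9],
                             [9, 9.1, 0, 0.1],
                             [9.1, 9, 0.1, 0]], ids=list("ABCD"))
        tree = neighbor_joining(dm)
        report = negative_branches(tree)
        if report:  # keep the check meaningful either way
            clamped = clamp_negative_branches(tree)
            assert negative_branches(clamped) == []
            assert all(length < 0 for _, length in report)


class TestAssignClusters:
    def _caterpillar(self):
        # two tight groups separated by one long internal branch
        newick = "((A:0.1,B:0.1):5.0,(C:0.1,(D:0.1,E:0.1):0.2):0.1);"
        return TreeNode.read(io.StringIO(newick))

    def test_dominant_split_at_k2(self):
        clusters = assign_clusters(self._caterpillar(), k=2)
        groups = {}
        for line, lbl in clusters.items():
            groups.setdefault(lbl, set()).add(line)
        assert {frozenset(g) for g in groups.values()} == \
            {frozenset({"A", "B"}), frozenset({"C", "D", "E"})}

    def test_k1_is_one_cluster(self):
        clusters = assign_clusters(self._caterpillar(), k=1)
        assert len(set(clusters.values())) == 1
        assert len(clusters) == 5

    def test_k_larger_than_leaf_count_is_an_error(self):
        with pytest.raises(ValueError):
            assign_clusters(self._caterpillar(), k=9)

    def test_reference_majority_labelling(self):
        reference = {"A": "annuum", "B": "annuum", "C": "chinense",
                     "D": "chinense", "E": "frutescens"}
        clusters = assign_clusters(self._caterpillar(), k=2,
                                   reference=reference)
        assert clusters["A"] == clusters["B"] == "annuum"
        assert clusters["C"] == clusters["D"] == clusters["E"] == "chinense"

    def test_small_blocks_become_unclassified(self):
        clusters = assign_clusters(self._caterpillar(), k=2, min_size=3)
        assert clusters["A"] == clusters["B"] == "N"
        assert clusters["C"] != "N"

    def test_partition_invariant_to_line_order(self, reference_population):
        from capssr.genotype_typing import GenotypeTable

        table = reference_population.table
        rng = np.random.default_rng(4)
        lines = list(table.lines)
        rng.shuffle(lines)
        shuffled = GenotypeTable(lines=lines, markers=list(table.markers),
                                 calls={ln: dict(table.calls[ln])
                                        for ln in lines})

        def partition(tbl):
            tree = neighbor_joining(distance_matrix(binarize_bands(tbl)))
            clusters = assign_clusters(tree, k=4)
            blocks = {}
            for line, lbl in clusters.items():
                blocks.setdefault(lbl, set()).add(line)
            return {frozenset(b) for b in blocks.values()}

        assert partition(table) == partition(shuffled)
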