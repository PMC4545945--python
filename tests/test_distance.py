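"""Simple-matching distances and UPGMA trees."""

import dendropy
import numpy as np
import pytest

from helpers_oracles import clades_of, upgma_oracle
from ssrkit import (
    DistanceMatrix,
    GenotypeTable,
    build_distance_matrix,
    simple_matching_distance,
    upgma,
    write_newick,
)
from ssrkit.distance import IncomparablePairError, TreeNode, UltrametricTree


def _random_distance_matrix(rng, labels):
    n = len(labels)
    m = np.round(rng.random((n, n)), 3)
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(list(labels), m)


def _random_ultrametric(rng, labels):
    """Cophenetic matrix of a random binary tree with increasing heights."""
    nodes = [TreeNode(height=0.0, name=l) for l in labels]
    height = 0.0
    while len(nodes) > 1:
        height += float(rng.random()) + 0.01
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(height=height, children=(nodes[i], nodes[j]))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return UltrametricTree(root=nodes[0]).cophenetic()


class TestSimpleMatching:
    def test_identical_rows_distance_zero(self, small_table):
        assert simple_matching_distance(small_table, "a1", "a1") == 0.0

    def test_half_match_scoring(self):
        table = GenotypeTable(
            loci=["L1", "L2"], accessions=["i1", "i2"],
            calls={"L1": {"i1": ("A", "A"), "i2": ("A", "B")},
                   "L2": {"i1": ("B", "C"), "i2": ("B", "C")}})
        # scores 0.5 and 1.0 -> similarity 0.75 -> distance 0.25
        assert simple_matching_distance(table, "i1", "i2") == pytest.approx(0.25)

    def test_disjoint_alleles_distance_one(self):
        table = GenotypeTable(
            loci=["L1"], accessions=["i1", "i2"],
            calls={"L1": {"i1": ("A", "A"), "i2": ("B", "B")}})
        assert simple_matching_distance(table, "i1", "i2") == 1.0

    def test_missing_data_pairwise_deletion(self, small_table):
        # a4 is missing at L2: distance uses L1 and L3 only
        d = simple_matching_distance(small_table, "a1", "a4")
        assert d == pytest.approx(1.0 - (1.0 + 1.0) / 2)

    def test_no_shared_loci_raises(self):
        table = GenotypeTable(
            loci=["L1", "L2"], accessions=["i1", "i2"],
            calls={"L1": {"i1": ("A", "A"), "i2": None},
                   "L2": {"i1": None, "i2": ("B", "B")}})
        with pytest.raises(IncomparablePairError):
            simple_matching_distance(table, "i1", "i2")

    def test_genotype_level_switch_loses_half_matches(self):
        table = GenotypeTable(
            loci=["L1"], accessions=["i1", "i2"],
            calls={"L1": {"i1": ("A", "A"), "i2": ("A", "B")}})
        assert simple_matching_distance(table, "i1", "i2", level="allele") == 0.5
        assert simple_matching_distance(table, "i1", "i2", level="genotype") == 1.0

    def test_single_locus_distances_quantized(self, rng):
        labels = ["i1", "i2", "i3"]
        table = GenotypeTable(
            loci=["L1"], accessions=labels,
            calls={"L1": {"i1": ("A", "B"), "i2": ("A", "A"), "i3": ("C", "C")}})
        D = build_distance_matrix(table)
        off = D.values[np.triu_indices(3, k=1)]
        assert set(off.tolist()) <= {0.0, 0.5, 1.0}


class TestDistanceMatrix:
    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 0.1], [0.2, 0.0]]))

    def test_block_structure_of_grouped_panel(self):
        groups = {"g1": ("A", "A"), "g2": ("B", "B"), "g3": ("C", "C")}
        accs = [f"{g}_{i}" for g in groups for i in range(2)]
        calls = {"L1": {a: groups[a.split("_")[0]] for a in accs}}
        table = GenotypeTable(["L1"], accs, calls)
        D = build_distance_matrix(table)
        for a in accs:
            for b in accs:
                expected = 0.0 if a.split("_")[0] == b.split("_")[0] else 1.0
                assert D.get(a, b) == expected

    def test_tsv_round_trip(self, tmp_path, rng):
        D = _random_distance_matrix(rng, ["a", "b", "c", "d"])
        D.to_tsv(tmp_path / "d.tsv")
        back = DistanceMatrix.from_tsv(tmp_path / "d.tsv")
        assert back.labels == D.labels
        np.testing.assert_allclose(back.values, D.values)


class TestUpgma:
    def test_hand_computed_three_leaf_example(self):
        D = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]]))
        assert upgma(D).newick() == "((A:0.1,B:0.1):0.2,C:0.3);"

    def test_equal_distances_tie_break_deterministic(self):
        D = DistanceMatrix(["c", "a", "b"], np.full((3, 3), 0.4) - 0.4 * np.eye(3))
        tree = upgma(D)
        # all merges at the same height, first merge is the (a, b) pair
        assert tree.newick() == "((a:0.2,b:0.2):0,c:0.2);"

    def test_matches_bruteforce_oracle_on_random_matrices(self, rng):
        labels = ["t1", "t2", "t3", "t4", "t5", "t6"]
        for _ in range(100):
            D = _random_distance_matrix(rng, labels)
            got = clades_of(upgma(D))
            want = upgma_oracle(labels, D.values.tolist())
            assert set(got) == set(want)
            for clade, h in want.items():
                assert got[clade] == pytest.approx(h, abs=1e-9)

    def test_matches_scipy_average_linkage_heights(self, rng):
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform

        labels = [f"x{i}" for i in range(8)]
        D = _random_distance_matrix(rng, labels)
        Z = average(squareform(D.values))
        coph = squareform(cophenet(Z))
        mine = upgma(D).cophenetic()
        order = [mine.labels.index(l) for l in labels]
        np.testing.assert_allclose(
            mine.values[np.ix_(order, order)], coph, atol=1e-9)

    def test_reconstructs_ultrametric_input_exactly(self, rng):
        labels = [f"u{i}" for i in range(7)]
        for _ in range(25):
            U = _random_ultrametric(rng, labels)
            coph = upgma(U).cophenetic()
            assert coph.labels == U.labels
            np.testing.assert_allclose(coph.values, U.values, atol=1e-9)

    def test_invariant_under_label_permutation(self, rng):
        labels = ["a", "b", "c", "d", "e"]
        D = _random_distance_matrix(rng, labels)
        perm = [3, 1, 4, 0, 2]
        Dp = DistanceMatrix([labels[i] for i in perm],
                            D.values[np.ix_(perm, perm)])
        assert clades_of(upgma(D)) == clades_of(upgma(Dp))

    def test_nan_rejected(self):
        m = np.zeros((2, 2))
        m[0, 1] = m[1, 0] = np.nan
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(["a", "b"], m))

    def test_cophenetic_is_ultrametric(self, rng):
        D = _random_distance_matrix(rng, ["a", "b", "c", "d", "e", "f"])
        C = upgma(D).cophenetic().values
        n = len(C)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert C[i, j] <= max(C[i, k], C[k, j]) + 1e-9


class TestNewick:
    def test_two_leaf_tree(self):
        tree = UltrametricTree(root=TreeNode(
            height=0.5, children=(TreeNode(0.0, "A"), TreeNode(0.0, "B"))))
        assert tree.newick() == "(A:0.5,B:0.5);"

    def test_labels_with_spaces_are_quoted(self):
        tree = UltrametricTree(root=TreeNode(
            height=0.5, children=(TreeNode(0.0, "C oxyacantha"),
                                  TreeNode(0.0, "C palaestinus"))))
        text = tree.newick()
        assert "'C oxyacantha'" in text
        parsed = dendropy.Tree.get(data=text, schema="newick")
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == \
            {"C oxyacantha", "C palaestinus"}

    def test_round_trips_through_dendropy(self, rng, tmp_path):
        labels = [f"n{i}" for i in range(6)]
        D = _random_distance_matrix(rng, labels)
        tree = upgma(D)
        path = tmp_path / "tree.nwk"
        write_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        parsed_dist = {}
        pdm = parsed.phylogenetic_distance_matrix()
        for t1 in parsed.taxon_namespace:
            for t2 in parsed.taxon_namespace:
                parsed_dist[(t1.label, t2.label)] = pdm.patristic_distance(t1, t2)
        coph = tree.cophenetic()
        for i, a in enumerate(coph.labels):
            for j, b in enumerate(coph.labels):
                assert parsed_dist[(a, b)] == pytest.approx(
                    coph.values[i, j], abs=1e-9)
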