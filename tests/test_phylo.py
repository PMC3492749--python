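import random

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import p_distance_brute, random_additive_tree
from rmlstkit.phylo import (DistanceMatrix, TreeNode, UndefinedDistanceError,
                            distance_matrix, neighbor_joining, p_distance,
                            p_distance_protein, write_newick)


class TestPDistance:
    def test_identical(self):
        assert p_distance("ACGT", "ACGT") == (0.0, 4)

    def test_one_difference(self):
        assert p_distance("ACGT", "ACGA") == (0.25, 4)

    def test_ambiguity_column_removed(self):
        d, sites = p_distance("ACNT", "ACGA")
        assert sites == 3
        assert d == pytest.approx(1 / 3)

    def test_gap_column_removed(self):
        d, sites = p_distance("AC-T", "ACGT")
        assert (d, sites) == (0.0, 3)

    def test_no_comparable_sites_undefined(self):
        d, sites = p_distance("NNNN", "ACGT")
        assert d is None and sites == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            p_distance("ACGT", "ACG")

    def test_protein_mode(self):
        d, sites = p_distance_protein("MKV-X", "MKIAL")
        assert sites == 3          # gap and X columns dropped
        assert d == pytest.approx(1 / 3)


@settings(max_examples=200, deadline=None)
@given(st.integers(0, 10_000))
def test_p_distance_equals_brute_force(seed):
    rng = random.Random(seed)
    n = rng.randint(1, 60)
    alphabet = "ACGTN-"
    a = "".join(rng.choice(alphabet) for _ in range(n))
    b = "".join(rng.choice(alphabet) for _ in range(n))
    assert p_distance(a, b) == p_distance_brute(a, b)


def tree_path_lengths(tree: TreeNode):
    """Leaf-to-leaf path lengths by direct traversal of the TreeNode."""
    dists = {}

    def below(node, length):
        if node.is_leaf():
            return {node.label: length}
        out = {}
        for child, bl in node.children:
            out.update(below(child, length + bl))
        return out

    def walk(node):
        parts = [below(child, bl) for child, bl in node.children]
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                for la, da in parts[i].items():
                    for lb, db in parts[j].items():
                        dists[frozenset([la, lb])] = da + db
        for child, _ in node.children:
            if not child.is_leaf():
                walk(child)

    walk(tree)
    return dists


def rf_distance(newick_a: str, newick_b: str) -> int:
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick_a, schema="newick",
                           taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick_b, schema="newick",
                           taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # solve the three-point equations independently:
        # la+lb=dab, la+lc=dac, lb+lc=dbc
        dab, dac, dbc = 0.3, 0.5, 0.6
        la = (dab + dac - dbc) / 2
        lb = (dab + dbc - dac) / 2
        lc = (dac + dbc - dab) / 2
        m = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, dab, dac],
                                     [dab, 0, dbc],
                                     [dac, dbc, 0]]))
        tree = neighbor_joining(m)
        lengths = {child.label: bl for child, bl in tree.children}
        assert lengths["A"] == pytest.approx(la, abs=1e-12)
        assert lengths["B"] == pytest.approx(lb, abs=1e-12)
        assert lengths["C"] == pytest.approx(lc, abs=1e-12)

    def test_additive_six_taxon_recovery(self):
        rng = random.Random(42)
        newick, dists, labels = random_additive_tree(6, rng)
        n = len(labels)
        mat = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    mat[i, j] = dists[frozenset([a, b])]
        tree = neighbor_joining(DistanceMatrix(labels, mat))
        assert rf_distance(write_newick(tree), newick) == 0
        recovered = tree_path_lengths(tree)
        for pair, expected in dists.items():
            assert recovered[pair] == pytest.approx(expected, abs=1e-9)

    def test_identical_rows_zero_length_cherry(self):
        mat = np.array([[0.0, 0.0, 0.4, 0.4],
                        [0.0, 0.0, 0.4, 0.4],
                        [0.4, 0.4, 0.0, 0.2],
                        [0.4, 0.4, 0.2, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], mat))
        lengths = tree_path_lengths(tree)
        assert lengths[frozenset(["A", "B"])] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_labels(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"],
                                            np.array([[0, .1], [.1, 0]])))

    def test_undefined_distance_names_pair(self):
        mat = np.array([[0.0, np.nan, 0.2],
                        [np.nan, 0.0, 0.2],
                        [0.2, 0.2, 0.0]])
        labels = ["A", "B", "C"]
        m = DistanceMatrix.__new__(DistanceMatrix)
        m.labels, m.values, m.site_counts = labels, mat, None
        with pytest.raises(UndefinedDistanceError, match="A.*B"):
            neighbor_joining(m)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000), st.integers(6, 8))
def test_nj_consistency_random_additive(seed, n_taxa):
    rng = random.Random(seed)
    newick, dists, labels = random_additive_tree(n_taxa, rng)
    n = len(labels)
    mat = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                mat[i, j] = dists[frozenset([a, b])]
    tree = neighbor_joining(DistanceMatrix(labels, mat))
    assert rf_distance(write_newick(tree), newick) == 0
    recovered = tree_path_lengths(tree)
    for pair, expected in dists.items():
        assert recovered[pair] == pytest.approx(expected, abs=1e-9)


class TestNewick:
    def test_cherry_output(self):
        tree = TreeNode(children=[(TreeNode("A"), 0.1), (TreeNode("B"), 0.1),
                                  (TreeNode("C"), 0.2)])
        text = write_newick(tree)
        assert text == "(A:0.1,B:0.1,C:0.2);"

    def test_round_trip_topology(self):
        rng = random.Random(3)
        newick, dists, labels = random_additive_tree(7, rng)
        n = len(labels)
        mat = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    mat[i, j] = dists[frozenset([a, b])]
        tree = neighbor_joining(DistanceMatrix(labels, mat))
        text = write_newick(tree)
        parsed = dendropy.Tree.get(data=text, schema="newick")
        assert sorted(t.label for t in parsed.taxon_namespace) == sorted(labels)
        assert rf_distance(text, text) == 0

    def test_labels_with_spaces_quoted(self):
        tree = TreeNode(children=[(TreeNode("iso 1"), 0.1),
                                  (TreeNode("B"), 0.1)])
        text = write_newick(tree)
        assert "'iso 1'" in text
        parsed = dendropy.Tree.get(data=text, schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == {"iso 1", "B"}


def test_distance_matrix_from_alignment():
    rows = {"a": "ACGTACGT", "b": "ACGAACGT", "c": "ACNTACGA"}
    m = distance_matrix(rows)
    assert m.labels == ["a", "b", "c"]
    i, j = m.labels.index("a"), m.labels.index("b")
    assert m.values[i, j] == pytest.approx(1 / 8)
    text = m.to_phylip()
    assert text.splitlines()[0] == "3"
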