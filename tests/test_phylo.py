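"""Distances, neighbor joining, bootstrap, Newick I/O, family assignment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bhlhkit.phylo import (
    assign_all,
    assign_family,
    bootstrap_support,
    nj_from_alignment,
    nj_tree,
    p_distance,
    read_newick,
    write_newick,
)
from bhlhkit.synthetic import make_reference_panel

from conftest import newick_splits, random_additive_tree, support_tree_splits


class TestPDistance:
    def test_identical(self):
        assert p_distance("ACDEF", "ACDEF") == 0.0

    def test_one_in_five(self):
        assert p_distance("ACDEF", "ACDEG") == pytest.approx(0.2)

    def test_gap_columns_excluded(self):
        assert p_distance("A-DEF", "AKDEF") == 0.0

    def test_all_gap_pair_rejected(self):
        with pytest.raises(ValueError):
            p_distance("--", "AB")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            p_distance("AB", "ABC")

    @given(st.text(alphabet="ACDG-", min_size=1, max_size=30))
    def test_symmetry_and_bounds(self, s):
        other = s[::-1]
        if set(s) == {"-"} or not any(
            a != "-" and b != "-" for a, b in zip(s, other)
        ):
            return
        d = p_distance(s, other)
        assert d == p_distance(other, s)
        assert 0.0 <= d <= 1.0


class TestNeighborJoining:
    def test_four_taxon_split_recovered(self):
        # additive distances from ((A,B),(C,D)) with all branch lengths 1
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]],
            dtype=float,
        )
        stree = nj_tree(D, labels)
        splits = support_tree_splits(stree)
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_three_taxon_closed_form(self):
        labels = ["A", "B", "C"]
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        stree = nj_tree(D, labels)
        lengths = {
            lf.taxon.label: lf.edge.length
            for lf in stree.tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    @pytest.mark.parametrize("n_taxa", [8, 12])
    def test_additive_topology_recovered(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        newick, labels, D = random_additive_tree(n_taxa, rng)
        stree = nj_tree(D, labels)
        assert support_tree_splits(stree) == newick_splits(newick, labels)

    def test_matches_independent_nj_implementation(self):
        """Cross-check against scikit-bio's neighbor joining on a noisy
        (non-additive) matrix."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(99)
        newick, labels, D = random_additive_tree(10, rng)
        D = D + rng.uniform(0, 0.02, D.shape)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        mine = support_tree_splits(nj_tree(D, labels))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, labels))
        theirs_splits = newick_splits(str(theirs).strip(), labels)
        assert mine == theirs_splits

    def test_input_validation(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0.0, -1.0], [-1.0, 0.0]]), ["A", "B"])
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1, -2], [1, 0, 1], [-2, 1, 0]], float),
                    ["A", "B", "C"])
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1], [2, 0]], float), ["A", "B"])


def two_family_alignment(ncols=200):
    rows = [
        ("A1", "A" * ncols),
        ("A2", "A" * ncols),
        ("B1", "C" * ncols),
        ("B2", "C" * ncols),
    ]
    return rows


class TestBootstrap:
    def test_seed_determinism(self):
        rows, _ = make_reference_panel(n_families=3, n_queries=2, seed=4)
        t1 = bootstrap_support(rows, n_reps=20, seed=9)
        t2 = bootstrap_support(rows, n_reps=20, seed=9)
        assert t1.support == t2.support

    def test_clean_signal_fully_supported(self):
        stree = bootstrap_support(two_family_alignment(), n_reps=50, seed=0)
        sup = stree.clade_support(frozenset({"A1", "A2"}))
        assert sup == 100.0

    def test_single_replicate_supports_binary(self):
        rows, _ = make_reference_panel(n_families=3, n_queries=2, seed=4)
        stree = bootstrap_support(rows, n_reps=1, seed=0)
        assert set(stree.support.values()) <= {0.0, 100.0}

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bootstrap_support(two_family_alignment()[:3], n_reps=5, seed=0)
        with pytest.raises(ValueError):
            bootstrap_support([("a", "A"), ("b", "C"), ("c", "A"), ("d", "C")][:4],
                              n_reps=5, seed=0)

    def test_supports_are_percentages(self):
        rows, _ = make_reference_panel(n_families=4, n_queries=3, seed=6)
        stree = bootstrap_support(rows, n_reps=25, seed=3)
        assert all(0.0 <= v <= 100.0 for v in stree.support.values())


class TestNewick:
    def test_labeled_splits(self):
        st_ = read_newick("((A,B)95,(C,D)80);")
        assert st_.support[frozenset({"A", "B"})] == 95.0
        assert st_.support[frozenset({"C", "D"})] == 80.0

    def test_two_leaf_degenerate(self):
        st_ = read_newick("(A,B);")
        assert sorted(st_.leaf_labels) == ["A", "B"]
        assert st_.support == {}

    def test_round_trip_random_tree(self):
        rng = np.random.default_rng(17)
        newick, labels, D = random_additive_tree(10, rng)
        stree = nj_tree(D, labels)
        stree2 = read_newick(write_newick(stree))
        assert support_tree_splits(stree) == support_tree_splits(stree2)
        for side, sup in stree.support.items():
            assert stree2.clade_support(side) == pytest.approx(sup)
        l1 = sorted(
            (lf.taxon.label, lf.edge.length)
            for lf in stree.tree.leaf_node_iter()
        )
        l2 = sorted(
            (lf.taxon.label, lf.edge.length)
            for lf in stree2.tree.leaf_node_iter()
        )
        for (a, x), (b, y) in zip(l1, l2):
            assert a == b and x == pytest.approx(y, abs=1e-9)

    @pytest.mark.parametrize("bad", ["((A,B);", "(A,A);", "(A,B))C;"])
    def test_parse_errors(self, bad):
        with pytest.raises(ValueError):
            read_newick(bad)

    def test_support_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            read_newick("((A,B)150,(C,D)80);")


class TestAssignFamily:
    def test_direct_sister_assigned(self):
        st_ = read_newick("((Q:1,A1:1)90:1,(B1:1,B2:1)70:1);")
        st_.with_references({"A1": "famA", "B1": "famB", "B2": "famB"})
        a = assign_family(st_, "Q")
        assert (a.family, a.status, a.support) == ("famA", "assigned", 90.0)

    def test_low_support_marked(self):
        st_ = read_newick("((Q:1,A1:1)40:1,(B1:1,B2:1)70:1);")
        st_.with_references({"A1": "famA", "B1": "famB", "B2": "famB"})
        a = assign_family(st_, "Q")
        assert (a.family, a.status, a.support) == ("famA", "n/m*", 40.0)

    def test_multi_member_family_clade_is_nm(self):
        st_ = read_newick("((Q:1,(A1:1,A2:1)99:1)85:1,(B1:1,B2:1)70:1);")
        st_.with_references(
            {"A1": "famA", "A2": "famA", "B1": "famB", "B2": "famB"}
        )
        a = assign_family(st_, "Q")
        assert (a.family, a.status, a.support) == ("famA", "n/m", 85.0)

    def test_mixed_clade_is_orphan(self):
        st_ = read_newick("((Q:1,(A1:1,B1:1)60:1)90:1,(A2:1,B2:1)70:1);")
        st_.with_references(
            {"A1": "famA", "A2": "famA", "B1": "famB", "B2": "famB"}
        )
        assert assign_family(st_, "Q").status == "orphan"

    def test_missing_query_rejected(self):
        st_ = read_newick("((Q:1,A1:1)90:1,(B1:1,B2:1)70:1);")
        st_.with_references({"A1": "famA"})
        with pytest.raises(ValueError):
            assign_family(st_, "ZZZ")

    def test_threshold_strictness(self):
        st_ = read_newick("((Q:1,A1:1)50:1,(B1:1,B2:1)70:1);")
        st_.with_references({"A1": "famA", "B1": "famB", "B2": "famB"})
        assert assign_family(st_, "Q", threshold=50).status == "n/m*"
        assert assign_family(st_, "Q", threshold=49).status == "assigned"

    def test_outgroup_rooting(self):
        st_ = read_newick("((Q:1,A1:1)90:1,(B1:1,OUT:5)70:1);")
        st_.with_references({"A1": "famA", "B1": "famB"})
        a = assign_family(st_, "Q", outgroup="OUT")
        assert a.family == "famA"

    def test_external_tree_equals_internal_build(self):
        """Assignment depends only on (topology, support): writing the
        internally built tree to Newick and re-ingesting it gives identical
        assignments."""
        rows, truth = make_reference_panel(n_families=4, n_queries=5, seed=21)
        internal = bootstrap_support(rows, n_reps=30, seed=2)
        internal.with_references(truth.member_family)
        external = read_newick(write_newick(internal))
        external.with_references(truth.member_family)
        assert assign_all(internal) == assign_all(external)

    def test_assigned_never_below_threshold(self):
        rows, truth = make_reference_panel(n_families=4, n_queries=6, seed=33)
        stree = bootstrap_support(rows, n_reps=30, seed=5)
        stree.with_references(truth.member_family)
        for a in assign_all(stree, threshold=50):
            if a.status in ("assigned", "n/m"):
                assert a.support > 50
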