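"""Unrooted-tree data model: Newick I/O, splits, pruning, edge distances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treestab.synthdata import sample_tree
from treestab.treecore import (
    NewickParseError,
    Split,
    TreeValidationError,
    parse_newick,
    rf_distance,
)


class TestParseNewick:
    def test_root_suppression_merges_lengths(self):
        t = parse_newick("((A:1,B:1):2,(C:1,D:1):3);")
        assert t.n_leaves == 4 and len(t.edges) == 5
        (internal,) = t.internal_edges()
        assert t.edges[internal].length == pytest.approx(5.0)

    def test_internal_label_becomes_edge_support(self):
        t = parse_newick("((A:1,B:1)85:1,C:1,D:1);")
        (internal,) = t.internal_edges()
        assert t.edges[internal].support == 85.0

    @pytest.mark.parametrize("bad", ["((A,B),(C,D)", "not a tree"])
    def test_malformed_input(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)

    def test_dangling_comma_rejected(self):
        # dendropy silently drops the empty child; the 2-leaf remnant is
        # rejected at validation
        with pytest.raises((NewickParseError, TreeValidationError)):
            parse_newick("((A,B),);")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(TreeValidationError):
            parse_newick("((A:1,A:1):1,B:1,C:1);")

    def test_too_few_leaves_rejected(self):
        with pytest.raises(TreeValidationError):
            parse_newick("(A:1,B:1);")

    def test_polytomy_rejected(self):
        with pytest.raises(TreeValidationError):
            parse_newick("(A:1,B:1,C:1,D:1);")

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_topology_lengths_supports(self, seed):
        rng = np.random.default_rng(seed)
        t = sample_tree(rng.integers(4, 11), rng)
        for i, eid in enumerate(t.internal_edges()):
            t.edges[eid].support = float(10 * i + 7)
        back = parse_newick(t.to_newick())
        assert rf_distance(t, back) == 0
        sup_by_split = {t.split_of_edge(e): t.edges[e].support for e in t.internal_edges()}
        for eid in back.internal_edges():
            assert back.edges[eid].support == sup_by_split[back.split_of_edge(eid)]
        len_by_side = {frozenset(t.side_leaves(e)): t.edges[e].length for e in t.edges}
        for eid in back.edges:
            side = frozenset(back.side_leaves(eid))
            key = side if side in len_by_side else frozenset(back.leaf_labels) - side
            assert back.edges[eid].length == pytest.approx(len_by_side[key], rel=1e-9)


class TestSplits:
    def test_quartet_single_split(self, quartet):
        splits = quartet.splits()
        assert splits == {Split.from_side({"A", "B"}, "ABCD")}

    def test_split_count_matches_internal_edges(self):
        rng = np.random.default_rng(0)
        t = sample_tree(10, rng)
        assert len(t.splits()) == 7  # n - 3

    def test_three_cherry_splits(self, six_star):
        leaves = "ABCDEF"
        expected = {
            Split.from_side({"A", "B"}, leaves),
            Split.from_side({"C", "D"}, leaves),
            Split.from_side({"E", "F"}, leaves),
        }
        assert six_star.splits() == expected

    def test_split_canonical_block_excludes_smallest_label(self):
        s = Split.from_side({"A", "B"}, "ABCD")
        assert "A" not in s.block and s.block == frozenset("CD")


class TestRfDistance:
    def test_identical_trees(self, quartet):
        assert rf_distance(quartet, quartet.copy()) == 0

    def test_conflicting_quartets(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert rf_distance(t1, t2) == 2

    def test_bounded_by_twice_internal_edges(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 11))
            t1 = sample_tree(n, rng)
            t2 = sample_tree(n, rng)
            d = rf_distance(t1, t2)
            assert 0 <= d <= 2 * (n - 3)
            assert d == rf_distance(t2, t1)

    def test_leaf_set_mismatch_names_labels(self, quartet):
        other = parse_newick("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(ValueError, match="E"):
            rf_distance(quartet, other)


class TestPruneTaxon:
    def test_merged_edge_length_sum(self):
        t = parse_newick("((A:1,B:2):3,(C:4,D:5):0);")
        p = t.prune_taxon("A")
        assert p.n_leaves == 3
        # B's path through the suppressed node: 2 + 3 + 0
        lengths = {p.side_leaves(e).__len__(): p.edges[e].length for e in p.edges}
        b_edge = p.pendant_edge("B")
        assert p.edges[b_edge].length == pytest.approx(5.0)

    def test_four_leaf_prune_gives_star(self, quartet):
        p = quartet.prune_taxon("C")
        assert p.n_leaves == 3 and len(p.internal_edges()) == 0

    def test_absent_label(self, quartet):
        with pytest.raises(KeyError):
            quartet.prune_taxon("Z")

    def test_too_small_tree(self):
        t = parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(TreeValidationError):
            t.prune_taxon("A")

    @pytest.mark.parametrize("seed", range(10))
    def test_prune_commutes_with_splits(self, seed):
        """splits(prune(T, s)) equals the s-removed nontrivial splits of T."""
        rng = np.random.default_rng(seed)
        t = sample_tree(8, rng)
        s = t.leaf_labels[int(rng.integers(0, 8))]
        direct = t.prune_taxon(s).splits()
        via_removal = {
            sp.remove(s) for sp in t.splits() if not sp.remove(s).is_trivial
        }
        assert direct == via_removal

    def test_support_survives_pruning(self):
        t = parse_newick("(((A:1,B:1)90:1,C:1)80:1,(D:1,E:1)70:1);")
        p = t.prune_taxon("C")
        kept = {p.edges[e].support for e in p.internal_edges()}
        assert 90.0 in kept


class TestEdgeNodeDistance:
    def test_same_edge_is_zero(self, quartet):
        e = quartet.edge_ids()[0]
        assert quartet.edge_node_distance(e, e) == 0

    def test_adjacent_edges_are_one(self, quartet):
        ea = quartet.pendant_edge("A")
        eb = quartet.pendant_edge("B")
        assert quartet.edge_node_distance(ea, eb) == 1

    def test_pendant_to_opposite_stem(self, six_star):
        # A's pendant edge to the CD-stem: two nodes on the connecting path
        ea = six_star.pendant_edge("A")
        cd_stem = six_star.edge_for_split(Split.from_side({"C", "D"}, "ABCDEF"))
        assert six_star.edge_node_distance(ea, cd_stem) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_and_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        t = sample_tree(int(rng.integers(5, 11)), rng)
        eids = t.edge_ids()
        d = {(a, b): t.edge_node_distance(a, b) for a in eids for b in eids}
        for a in eids:
            assert d[(a, a)] == 0
            for b in eids:
                assert d[(a, b)] == d[(b, a)]
                for c in eids:
                    assert d[(a, c)] <= d[(a, b)] + d[(b, c)]

    def test_unknown_edge_rejected(self, quartet):
        with pytest.raises(KeyError):
            quartet.edge_node_distance(0, 999)


class TestStructuralInvariants:
    @pytest.mark.parametrize("n", [4, 7, 12])
    def test_edge_count_formula(self, n):
        t = sample_tree(n, np.random.default_rng(n))
        assert len(t.edges) == 2 * n - 3
        assert len(t.internal_edges()) == n - 3
        t.validate()

    def test_negative_length_rejected(self):
        with pytest.raises(TreeValidationError):
            parse_newick("((A:1,B:-0.5):1,C:1,D:1);")

    def test_attach_leaf_splits_lengths(self, quartet):
        eid = quartet.internal_edges()[0]
        L = quartet.edges[eid].length
        t2 = quartet.attach_leaf(eid, "E", 0.3 * L, 0.7)
        assert t2.n_leaves == 5 and len(t2.edges) == len(quartet.edges) + 2
        assert rf_distance(t2.prune_taxon("E"), quartet) == 0

    def test_relabel_preserves_structure(self, six_star):
        mapping = {l: l.lower() * 2 for l in six_star.leaf_labels}
        r = six_star.relabel(mapping)
        assert sorted(r.leaf_labels) == sorted(mapping.values())
        assert len(r.splits()) == len(six_star.splits())


@given(seed=st.integers(0, 10**6), n=st.integers(4, 12))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_property_newick_roundtrip_is_identity(seed, n):
    """Any sampled tree survives write-then-parse with its topology and
    branch-length multiset intact."""
    t = sample_tree(n, np.random.default_rng(seed))
    back = parse_newick(t.to_newick())
    assert rf_distance(t, back) == 0
    ours = sorted(e.length for e in t.edges.values())
    theirs = sorted(e.length for e in back.edges.values())
    assert np.allclose(ours, theirs, rtol=1e-9)


@given(seed=st.integers(0, 10**6))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_property_split_complement_is_canonical(seed):
    """A split built from either side of an edge canonicalizes identically."""
    t = sample_tree(8, np.random.default_rng(seed))
    leaves = frozenset(t.leaf_labels)
    for eid in t.internal_edges():
        side = t.side_leaves(eid)
        assert Split.from_side(side, leaves) == Split.from_side(leaves - side, leaves)
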