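"""Per-taxon summary statistics for stability prediction."""

import numpy as np
import pytest

from treestab.features import (
    FEATURE_COLUMNS,
    _sibling_clades,
    assemble_features,
    branch_features,
    insertion_distance_stats,
    insertion_height,
    nj_tii_feature,
    sequence_distance_features,
    support_features,
)
from treestab.inference import InferenceConfig, bootstrap_supports
from treestab.placement import PlacementCandidate, PlacementSet, best_placement_tree, placement_candidates
from treestab.seqmodels import Alignment, DistanceMatrix
from treestab.synthdata import sample_tree, simulate_alignment
from treestab.treecore import parse_newick


def _fake_placement(taxon, edge_ids, lwrs, pendant=0.1, distal=0.05):
    cands = [
        PlacementCandidate(e, w, pendant, distal, -100.0 + w)
        for e, w in zip(edge_ids, lwrs)
    ]
    return PlacementSet(taxon, cands, cands)


class TestInsertionSpread:
    def test_singleton_is_zero(self, six_star):
        ps = _fake_placement("q", [six_star.edge_ids()[0]], [1.0])
        assert insertion_distance_stats(ps, six_star) == (0.0, 0.0)

    def test_two_adjacent_edges(self, six_star):
        # edge-pair diameter of the three-cherry tree is 3 (pendant to
        # opposite pendant); adjacent candidates sit at distance 1
        ea = six_star.pendant_edge("A")
        eb = six_star.pendant_edge("B")
        ps = _fake_placement("q", [ea, eb], [0.6, 0.4])
        mean, sd = insertion_distance_stats(ps, six_star)
        assert mean == pytest.approx(1.0 / 3.0)
        assert sd == 0.0

    def test_invariant_under_candidate_order(self, six_star):
        edges = [six_star.pendant_edge(l) for l in "ACE"]
        a = insertion_distance_stats(_fake_placement("q", edges, [0.5, 0.3, 0.2]), six_star)
        b = insertion_distance_stats(_fake_placement("q", edges[::-1], [0.5, 0.3, 0.2]), six_star)
        assert a == b


class TestBranchFeatures:
    def test_attachment_offset_normalization(self, quartet):
        eid = quartet.internal_edges()[0]
        b = quartet.edges[eid].length
        tplus = quartet.attach_leaf(eid, "E", 0.3 * b, 0.2)
        best = PlacementCandidate(eid, 1.0, 0.2, 0.3 * b, -1.0)
        ibl, nearest, pend = branch_features(quartet, best, tplus)
        assert nearest == pytest.approx(0.3)
        mean_bl = tplus.mean_branch_length()
        assert ibl == pytest.approx(b / mean_bl)
        assert pend == pytest.approx(0.2 / mean_bl)

    def test_midpoint_is_maximal(self, quartet):
        eid = quartet.internal_edges()[0]
        b = quartet.edges[eid].length
        best = PlacementCandidate(eid, 1.0, 0.1, 0.5 * b, -1.0)
        tplus = quartet.attach_leaf(eid, "E", 0.5 * b, 0.1)
        assert branch_features(quartet, best, tplus)[1] == pytest.approx(0.5)

    def test_zero_length_branch_defines_offset_zero(self):
        t = parse_newick("((A:1,B:1):0,(C:1,D:1):0);")
        eid = t.internal_edges()[0]
        best = PlacementCandidate(eid, 1.0, 0.1, 0.0, -1.0)
        tplus = t.attach_leaf(eid, "E", 0.0, 0.1)
        assert branch_features(t, best, tplus)[1] == 0.0

    def test_rescaling_invariance(self, quartet):
        """Branch-length features are ratios: uniform rescaling cancels."""
        eid = quartet.internal_edges()[0]
        b = quartet.edges[eid].length
        best = PlacementCandidate(eid, 1.0, 0.2, 0.3 * b, -1.0)
        tplus = quartet.attach_leaf(eid, "E", 0.3 * b, 0.2)
        ref = branch_features(quartet, best, tplus)
        k = 3.7
        scaled_tree = quartet.scale_branch_lengths(k)
        scaled_best = PlacementCandidate(eid, 1.0, 0.2 * k, 0.3 * b * k, -1.0)
        scaled_tplus = tplus.scale_branch_lengths(k)
        got = branch_features(scaled_tree, scaled_best, scaled_tplus)
        assert got == pytest.approx(ref)


class TestSupportFeatures:
    def _supported(self, newick, supports):
        t = parse_newick(newick)
        for eid, s in zip(t.internal_edges(), supports):
            t.edges[eid].support = s
        return t

    def test_population_moments(self):
        t = self._supported(
            "((A:1,B:1):1,(C:1,(D:1,(E:1,F:1):1):1):1);", [100.0, 60.0, 80.0]
        )
        best = PlacementCandidate(t.internal_edges()[1], 1.0, 0.1, 0.0, -1.0)
        mean, sd, dist = support_features(t, best)
        assert mean == pytest.approx(80.0)
        assert sd == pytest.approx(16.3299, abs=1e-3)
        assert dist == 0.0  # the insertion edge itself has support 60

    def test_all_high_support_gives_one(self):
        t = self._supported("((A:1,B:1):1,(C:1,D:1):1);", [100.0])
        best = PlacementCandidate(t.pendant_edge("A"), 1.0, 0.1, 0.0, -1.0)
        assert support_features(t, best)[2] == 1.0

    def test_missing_supports_rejected(self, quartet):
        best = PlacementCandidate(quartet.pendant_edge("A"), 1.0, 0.1, 0.0, -1.0)
        with pytest.raises(ValueError):
            support_features(quartet, best)


class TestSequenceDistanceFeatures:
    def test_clocklike_data_gives_unit_ratios(self, jc):
        rng = np.random.default_rng(31)
        tree = sample_tree(6, rng)
        for e in tree.edges.values():
            e.length = max(e.length, 0.05)
        aln = simulate_alignment(tree, jc, 30000, rng)
        s = "T3"
        reduced = tree.prune_taxon(s)
        placement = placement_candidates(reduced, aln, s, jc)
        tplus = best_placement_tree(reduced, placement)
        rmean, rsd, *_ = sequence_distance_features(
            aln, s, tplus, jc, reduced, placement.best.edge_id
        )
        assert rmean == pytest.approx(1.0, abs=0.1)
        assert rsd < 0.1

    def test_sibling_statistic_with_hand_built_distances(self):
        # inferred tree on 4 taxa; best insertion edge = pendant edge of D
        # (far side from reference leaf A) so C = {D}; the near endpoint's
        # smaller subtree is the cherry's other leaf
        inferred = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        best_eid = inferred.pendant_edge("D")
        C, Cp = _sibling_clades(inferred, best_eid)
        assert C == frozenset({"D"}) and Cp == frozenset({"C"})
        tplus = inferred.attach_leaf(best_eid, "s", 0.5, 0.25)
        taxa = ["A", "B", "C", "D", "s"]
        vals = np.full((5, 5), 2.0)
        np.fill_diagonal(vals, 0.0)
        D = DistanceMatrix(taxa, vals)
        # as = d(s, C') = 2.0 and aC = mean d(D, C') = 2.0 -> ratio 1
        *_, sibling = sequence_distance_features(
            None, "s", tplus, None, inferred, best_eid, D=D
        )
        assert sibling == pytest.approx(1.0)

    def test_degenerate_tree_rejected(self):
        inferred = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        best_eid = inferred.pendant_edge("D")
        # attach at D's end of its pendant edge with a zero pendant: the new
        # taxon coincides with D
        tplus = inferred.attach_leaf(best_eid, "s", 1.0, 0.0)
        # zero patristic distance s <-> D
        vals = np.full((5, 5), 1.0)
        np.fill_diagonal(vals, 0.0)
        D = DistanceMatrix(["A", "B", "C", "D", "s"], vals)
        with pytest.raises(ValueError, match="patristic"):
            sequence_distance_features(None, "s", tplus, None, inferred, best_eid, D=D)


class TestInsertionHeight:
    def test_attachment_on_pendant_edge(self):
        t = parse_newick("((A:1,B:1):1,(C:1,X:1):1);")
        eid = t.pendant_edge("X")
        e = t.edges[eid]
        # orient distal from the internal endpoint: attachment 0.8 from the
        # junction means 0.2 from leaf X
        distal_from_u = 0.8 if not t.is_leaf(e.u) else 0.2
        tplus = t.attach_leaf(eid, "s", distal_from_u, 0.5)
        pat = tplus.leaf_distance_matrix()
        diam = max(pat.values())
        assert insertion_height(tplus, "s") == pytest.approx(0.2 / (diam / 2.0))

    def test_zero_when_coincident_with_leaf(self):
        t = parse_newick("((A:0,B:1):1,(C:1,D:1):1);")
        eid = t.pendant_edge("A")
        tplus = t.attach_leaf(eid, "s", 0.0, 0.3)
        assert insertion_height(tplus, "s") == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_bounded_by_one(self, seed):
        rng = np.random.default_rng(seed)
        t = sample_tree(8, rng)
        eids = t.edge_ids()
        eid = eids[int(rng.integers(0, len(eids)))]
        tplus = t.attach_leaf(eid, "q", t.edges[eid].length / 2, 0.05)
        assert 0.0 <= insertion_height(tplus, "q") <= 1.0


class TestNjTii:
    def test_additive_distances_are_stable_for_every_taxon(self, jc):
        rng = np.random.default_rng(13)
        tree = sample_tree(7, rng)
        for e in tree.edges.values():
            e.length = max(e.length, 0.05)
        pat = tree.leaf_distance_matrix()
        taxa = tree.leaf_labels
        D = DistanceMatrix(taxa, np.array([[pat[(a, b)] for b in taxa] for a in taxa]))
        aln = Alignment(taxa, ["ACGT"] * 7)  # distances supplied directly
        for s in taxa:
            assert nj_tii_feature(aln, s, jc, D=D) == 0.0

    def test_too_few_taxa_is_missing(self, jc):
        aln = Alignment(list("ABCD"), ["ACGT"] * 4)
        assert nj_tii_feature(aln, "A", jc) is None


class TestAssembleFeatures:
    def test_complete_row(self, gtrg):
        rng = np.random.default_rng(41)
        tree = sample_tree(8, rng)
        aln = simulate_alignment(tree, gtrg, 400, rng)
        s = "T2"
        reduced = tree.prune_taxon(s)
        cfg = InferenceConfig(backend="nj", model=gtrg, bootstrap=20, seed=5)
        reduced = bootstrap_supports(aln.drop_taxon(s), reduced, cfg)
        placement = placement_candidates(reduced, aln, s, gtrg)
        tplus = best_placement_tree(reduced, placement)
        fv = assemble_features(reduced, placement, tplus, aln, gtrg,
                               pythia_difficulty=0.42)
        row = fv.as_dict()
        assert row["taxon"] == s
        assert row["n_insertion_locations"] == len(placement)
        assert row["lwr"] == placement.best.lwr
        assert row["pythia_difficulty"] == 0.42
        for col in FEATURE_COLUMNS:
            assert row[col] is not None, col

    def test_missing_subfeature_leaves_explicit_gap(self, jc, six_star, caplog):
        # no supports on the tree: support features must stay missing
        aln = Alignment(list("ABCDEFq"), ["ACGTACGT"] * 7)
        ps = placement_candidates(six_star, aln, "q", jc)
        tplus = best_placement_tree(six_star, ps)
        with caplog.at_level("ERROR"):
            fv = assemble_features(six_star, ps, tplus, aln, jc)
        assert fv.bootstrap_mean is None and fv.dist_low_bootstrap_edge is None
        assert fv.lwr is not None
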