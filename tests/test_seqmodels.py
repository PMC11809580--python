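"""Alignments, substitution models, corrected distances, site likelihoods."""

import numpy as np
import pytest

from treestab.likelihood import LikelihoodEngine
from treestab.seqmodels import (
    Alignment,
    DistanceMatrix,
    SubstModel,
    corrected_distance_matrix,
    parse_model_string,
    site_log_likelihoods,
)
from treestab.synthdata import sample_tree, simulate_alignment
from treestab.treecore import UnrootedTree, parse_newick


class TestAlignment:
    def test_fasta_roundtrip(self, tmp_path):
        aln = Alignment(["x", "y", "z"], ["ACGT-N", "acgtrn", "TTTTTT"])
        path = tmp_path / "a.fasta"
        aln.to_fasta(path)
        back = Alignment.from_fasta(path)
        assert back.taxa == aln.taxa and back.sequences == aln.sequences

    def test_phylip_reader(self, tmp_path):
        path = tmp_path / "a.phy"
        path.write_text("3 4\nA ACGT\nB ACGA\nC AC GT\n")
        aln = Alignment.from_phylip(path)
        assert aln.sequence("C") == "ACGT"

    def test_drop_taxon_keeps_sites(self):
        aln = Alignment(["a", "b", "c"], ["ACGT", "AAAA", "CCCC"])
        red = aln.drop_taxon("b")
        assert red.n_sites == 4 and red.taxa == ["a", "c"]
        with pytest.raises(KeyError):
            aln.drop_taxon("zz")

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            Alignment(["a", "b"], ["AC!T", "ACGT"])

    def test_ragged_rows_rejected(self):
        with pytest.raises(ValueError):
            Alignment(["a", "b"], ["ACGT", "ACG"])


class TestSubstModel:
    def test_rows_of_transition_matrix_sum_to_one(self, gtrg):
        for t in (0.0, 0.01, 1.0, 9.0):
            P = gtrg.transition_matrices(t)
            assert np.allclose(P.sum(axis=2), 1.0, atol=1e-10)

    def test_stationarity(self, gtrg):
        P = gtrg.transition_matrix(5.0)
        assert np.allclose(gtrg.pi @ P, gtrg.pi, atol=1e-10)

    def test_mean_rate_scaled_to_one(self, gtrg):
        # expected substitution rate at t=0: -sum(pi_i Q_ii) == 1
        assert np.isclose(-np.sum(gtrg.pi * np.diag(gtrg._Q)), 1.0)

    def test_gamma_categories_mean_one(self):
        for alpha in (0.2, 1.0, 5.0):
            m = SubstModel.jc69(gamma_alpha=alpha)
            assert len(m.category_rates) == 4
            assert np.isclose(m.category_rates.mean(), 1.0)
            assert np.all(np.diff(m.category_rates) > 0)

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError):
            SubstModel.gtr((1, 1, 1, 1, 1, 1), (0.5, 0.5, 0.2, -0.2))

    @pytest.mark.parametrize("spec,family,alpha", [
        ("JC", "JC69", None),
        ("jc69+G{0.5}", "JC69", 0.5),
        ("K2P{3}", "K2P", None),
        ("HKY{2.5}+F{0.3,0.2,0.2,0.3}", "HKY", None),
        ("GTR{1,2,1,1,2,1}+F{0.3,0.2,0.2,0.3}+G{1.2}", "GTR", 1.2),
    ])
    def test_parse_model_string(self, spec, family, alpha):
        m = parse_model_string(spec)
        assert m.family == family and m.gamma_alpha == alpha

    def test_parse_rejects_garbage(self):
        with pytest.raises(ValueError):
            parse_model_string("WAG{1}")
        with pytest.raises(ValueError):
            parse_model_string("GTR{1,2}")


class TestCorrectedDistances:
    def test_identical_sequences_zero(self, jc):
        aln = Alignment(["a", "b"], ["ACGTACGTAC", "ACGTACGTAC"])
        assert corrected_distance_matrix(aln, jc)[("a", "b")] == 0.0

    def test_jc_closed_form(self, jc):
        # p = 0.3 -> -(3/4) ln(1 - 0.4) = 0.383119
        seq1 = "A" * 10
        seq2 = "A" * 7 + "C" * 3
        d = corrected_distance_matrix(Alignment(["a", "b"], [seq1, seq2]), jc)
        assert d[("a", "b")] == pytest.approx(0.383119, abs=1e-6)

    def test_saturation_capped_with_warning(self, jc, caplog):
        seq1 = "A" * 4
        seq2 = "CGTC"
        with caplog.at_level("WARNING"):
            d = corrected_distance_matrix(Alignment(["a", "b"], [seq1, seq2]), jc)
        assert d[("a", "b")] == 10.0
        assert any("capped" in r.message for r in caplog.records)

    def test_no_comparable_sites_names_pair(self, jc):
        aln = Alignment(["a", "b"], ["AC--", "--GT"])
        with pytest.raises(ValueError, match="a.*b"):
            corrected_distance_matrix(aln, jc)

    def test_ml_distance_matches_jc_closed_form(self):
        """The golden-section ML distance under a JC-equivalent GTR agrees
        with the analytic JC correction."""
        jc_as_gtr = SubstModel.gtr((1,) * 6, (0.25,) * 4)
        aln = Alignment(["a", "b"], ["ACGTACGTAC" * 5, "ACGTACGTTT" * 5])
        d_ml = corrected_distance_matrix(aln, jc_as_gtr)[("a", "b")]
        d_jc = corrected_distance_matrix(aln, SubstModel.jc69())[("a", "b")]
        assert d_ml == pytest.approx(d_jc, abs=1e-5)

    def test_k2p_closed_form(self):
        # 2 transitions (A<->G), 1 transversion out of 10 sites
        aln = Alignment(["a", "b"], ["AAAAAAAAAC", "GGAAAAAAAA"])
        P, Q = 0.2, 0.1
        expect = -0.5 * np.log(1 - 2 * P - Q) - 0.25 * np.log(1 - 2 * Q)
        d = corrected_distance_matrix(aln, SubstModel.k2p(2.0))
        assert d[("a", "b")] == pytest.approx(expect, abs=1e-9)

    def test_distance_converges_to_patristic(self, jc):
        """With more sites the corrected distances approach the generating
        tree's patristic distances."""
        rng = np.random.default_rng(4)
        tree = sample_tree(6, rng)
        pat = tree.leaf_distance_matrix()
        errors = []
        for L in (500, 5000, 50000):
            aln = simulate_alignment(tree, jc, L, np.random.default_rng(99))
            D = corrected_distance_matrix(aln, jc)
            errs = [abs(D[(a, b)] - pat[(a, b)])
                    for i, a in enumerate(tree.leaf_labels)
                    for b in tree.leaf_labels[i + 1:]]
            errors.append(np.median(errs))
        assert errors[2] < errors[0]

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


def _enumerated_site_lnl(tree, aln, model, site):
    """Independent oracle: sum the likelihood over every assignment of
    states to internal nodes, one site at a time."""
    import itertools

    internal = [n for n in tree.nodes() if not tree.is_leaf(n)]
    leaf_part = {
        n: aln.tip_partials(tree._leaf_label[n])[site]
        for n in tree.nodes()
        if tree.is_leaf(n)
    }
    rates = model.category_rates
    total = 0.0
    for rate in rates:
        for assign in itertools.product(range(4), repeat=len(internal)):
            states = dict(zip(internal, assign))
            lik = model.pi[states[internal[0]]]
            for eid, e in tree.edges.items():
                P = model.transition_matrix(max(e.length, 1e-9), rate)
                su = states.get(e.u)
                sv = states.get(e.v)
                if su is not None and sv is not None:
                    lik *= P[su, sv]
                elif su is not None:
                    lik *= P[su] @ leaf_part[e.v]
                else:
                    lik *= P[sv] @ leaf_part[e.u]
            total += lik / len(rates)
    return np.log(total)


class TestSiteLikelihoods:
    def test_identical_tips_zero_branches(self, jc):
        tree = UnrootedTree.star(["A", "B", "C"], [0.0, 0.0, 0.0])
        aln = Alignment(["A", "B", "C"], ["A", "A", "A"])
        lnl = site_log_likelihoods(tree, aln, jc)
        assert lnl[0] == pytest.approx(np.log(0.25), abs=1e-6)

    def test_all_gap_column_contributes_nothing(self, jc, quartet):
        aln = Alignment(list("ABCD"), ["A-", "A-", "A-", "A-"])
        lnl = site_log_likelihoods(quartet, aln, jc)
        assert lnl[1] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("model_name", ["jc", "gtrg"])
    def test_pruning_matches_state_enumeration(self, model_name, jc, gtrg, quartet):
        model = {"jc": jc, "gtrg": gtrg}[model_name]
        rng = np.random.default_rng(7)
        aln = simulate_alignment(quartet, model, 6, rng)
        got = site_log_likelihoods(quartet, aln, model)
        for site in range(6):
            want = _enumerated_site_lnl(quartet, aln, model, site)
            assert got[site] == pytest.approx(want, abs=1e-10)

    def test_ambiguity_codes_behave_as_partial_states(self, jc, quartet):
        # an N is a free sum over states: likelihood equals the marginal
        aln_n = Alignment(list("ABCD"), ["A", "C", "N", "G"])
        total = 0.0
        for ch in "ACGT":
            aln_x = Alignment(list("ABCD"), ["A", "C", ch, "G"])
            total += np.exp(site_log_likelihoods(quartet, aln_x, jc)[0])
        got = site_log_likelihoods(quartet, aln_n, jc)[0]
        assert got == pytest.approx(np.log(total), abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_total_lnl_same_from_every_edge(self, seed, gtrg):
        """Pulley principle: the likelihood does not depend on where the
        unrooted tree is evaluated."""
        rng = np.random.default_rng(seed)
        tree = sample_tree(6, rng)
        aln = simulate_alignment(tree, gtrg, 100, rng)
        engine = LikelihoodEngine(tree, aln, gtrg)
        ref = engine.log_likelihood()
        for eid in tree.edge_ids():
            f = engine.edge_lnl_function(eid)
            assert f(tree.edges[eid].length) == pytest.approx(ref, abs=1e-8)

    def test_missing_sequence_rejected(self, jc, quartet):
        aln = Alignment(["A", "B", "C"], ["A", "A", "A"])
        with pytest.raises(ValueError, match="D"):
            site_log_likelihoods(quartet, aln, jc)

    def test_likelihood_peaks_near_generating_length(self, jc):
        """On strong-signal data the single-branch likelihood decreases away
        from the generating branch length."""
        tree = parse_newick("((A:0.05,B:0.05):0.2,C:0.05,D:0.05);")
        aln = simulate_alignment(tree, jc, 20000, np.random.default_rng(3))
        engine = LikelihoodEngine(tree, aln, jc)
        (eid,) = tree.internal_edges()
        f = engine.edge_lnl_function(eid)
        near = f(0.2)
        assert near > f(0.02) and near > f(1.5)
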