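import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from picotrait.io import Alignment, parse_newick
from picotrait.selection import (
    CODONS,
    BranchSiteModel,
    CodonModel,
    SiteClassModel,
    codon_loglik,
    discrete_beta,
    f3x4_frequencies,
    fit_branch_site,
    fit_site_models,
    gy94_generator,
    nei_gojobori_dnds,
    transition_matrix,
)
from picotrait.simulate import simulate_codon_alignment, simulate_yule_tree

UNIFORM_PI = np.full(61, 1 / 61)


class TestF3x4:
    def test_sums_to_one(self):
        aln = Alignment(ids=["a", "b"], seqs=["ATGAAACCC", "ATGAAAGGG"])
        pi = f3x4_frequencies(aln)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_two_codons(self):
        # single sequence AAA TTT: position frequencies are A/T half-half at
        # every codon position, so pi(AAA) = pi(TTT) = ... = (1/2)^3 per
        # A/T-only codon, renormalized over the sense subset
        aln = Alignment(ids=["a"], seqs=["AAATTT"])
        pi = f3x4_frequencies(aln)
        at_codons = [c for c in CODONS if set(c) <= {"A", "T"}]
        # TAA is a stop, so 7 of the 8 A/T combinations remain and each
        # carries equal F3x4 mass after renormalization
        assert len(at_codons) == 7
        for c in at_codons:
            assert pi[CODONS.index(c)] == pytest.approx(1 / 7, abs=1e-4)

    def test_in_frame_stop_rejected_with_position(self):
        aln = Alignment(ids=["a", "b"], seqs=["ATGTAACCC", "ATGAAACCC"])
        with pytest.raises(ValueError, match="position 4"):
            f3x4_frequencies(aln)


class TestGY94Generator:
    def test_rows_sum_to_zero_and_reversible(self):
        Q = gy94_generator(2.5, 0.3, UNIFORM_PI)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        flux = UNIFORM_PI[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        kappa=st.floats(0.2, 10.0),
        omega=st.floats(0.0, 5.0),
        seed=st.integers(0, 10_000),
    )
    def test_reversibility_random_parameters(self, kappa, omega, seed):
        rng = np.random.default_rng(seed)
        pi = rng.dirichlet(np.ones(61))
        Q = gy94_generator(kappa, omega, pi)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-10)
        flux = pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-10)

    def test_omega_zero_kills_nonsynonymous_rates(self):
        from picotrait.selection import _SINGLE_STEP

        Q = gy94_generator(2.0, 0.0, UNIFORM_PI)
        for (i, j), (_, is_syn) in _SINGLE_STEP.items():
            if not is_syn:
                assert Q[i, j] == 0.0

    def test_single_nucleotide_neighbors_only(self):
        Q = gy94_generator(2.0, 0.5, UNIFORM_PI)
        for i, ci in enumerate(CODONS):
            for j, cj in enumerate(CODONS):
                if i == j:
                    continue
                ndiff = sum(a != b for a, b in zip(ci, cj))
                if ndiff > 1:
                    assert Q[i, j] == 0.0
                else:
                    # hand enumeration: rate = pi_j * kappa^[ti] * omega^[nonsyn]
                    k = next(p for p in range(3) if ci[p] != cj[p])
                    is_ti = {ci[k], cj[k]} in ({"A", "G"}, {"C", "T"})
                    from Bio.Data.CodonTable import unambiguous_dna_by_id

                    fwd = unambiguous_dna_by_id[1].forward_table
                    is_syn = fwd[ci] == fwd[cj]
                    expected = (1 / 61) * (2.0 if is_ti else 1.0) * (
                        1.0 if is_syn else 0.5
                    )
                    # compare up to the global scaling constant
                    base = Q[i, j] / expected
                    assert base == pytest.approx(
                        Q[0, [m for m in range(61) if Q[0, m] > 0][0]]
                        / _first_expected(), rel=1e-9,
                    )


def _first_expected():
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    fwd = unambiguous_dna_by_id[1].forward_table
    ci = CODONS[0]
    j = next(m for m in range(61) if m != 0 and sum(
        a != b for a, b in zip(ci, CODONS[m])
    ) == 1)
    cj = CODONS[j]
    k = next(p for p in range(3) if ci[p] != cj[p])
    is_ti = {ci[k], cj[k]} in ({"A", "G"}, {"C", "T"})
    is_syn = fwd[ci] == fwd[cj]
    return (1 / 61) * (2.0 if is_ti else 1.0) * (1.0 if is_syn else 0.5)


class TestCodonLoglik:
    def test_two_leaf_single_codon_direct_sum(self):
        tree = parse_newick("(x:0.3,y:0.7);")
        tree.is_rooted = True
        aln = Alignment(ids=["x", "y"], seqs=["ATG", "ATA"])
        model = CodonModel(2.0, 0.4, UNIFORM_PI)
        lnl = codon_loglik(tree, aln, model)
        Q = gy94_generator(2.0, 0.4, UNIFORM_PI)
        P1 = transition_matrix(Q, UNIFORM_PI, 0.3)
        P2 = transition_matrix(Q, UNIFORM_PI, 0.7)
        i, j = CODONS.index("ATG"), CODONS.index("ATA")
        direct = sum(
            UNIFORM_PI[r] * P1[r, i] * P2[r, j] for r in range(61)
        )
        assert lnl == pytest.approx(math.log(direct), abs=1e-9)

    def test_all_gap_column_leaves_loglik_unchanged(self):
        tree = parse_newick("((x:0.2,y:0.3):0.1,z:0.4);")
        tree.is_rooted = True
        aln1 = Alignment(ids=["x", "y", "z"], seqs=["ATGAAA", "ATAAAA", "ATGAAG"])
        aln2 = Alignment(
            ids=["x", "y", "z"],
            seqs=["ATGAAA---", "ATAAAA---", "ATGAAG---"],
        )
        model = CodonModel(2.0, 0.4, UNIFORM_PI)
        assert codon_loglik(tree, aln1, model) == pytest.approx(
            codon_loglik(tree, aln2, model), abs=1e-9
        )

    def test_m2_with_empty_positive_class_reduces_to_m1(self):
        tree = simulate_yule_tree(5, 1.0, seed=30)
        aln = simulate_codon_alignment(tree, 2.0, [(1.0, 0.2)], 60, seed=31)
        m1 = SiteClassModel(2.0, [(0.8, 0.1), (0.2, 1.0)], UNIFORM_PI)
        m2 = SiteClassModel(2.0, [(0.8, 0.1), (0.2, 1.0), (0.0, 3.0)], UNIFORM_PI)
        assert codon_loglik(tree, aln, m1) == pytest.approx(
            codon_loglik(tree, aln, m2), abs=1e-12
        )

    def test_branch_site_reduces_to_site_mixture_without_foreground(self):
        tree = simulate_yule_tree(5, 1.0, seed=32)
        aln = simulate_codon_alignment(tree, 2.0, [(1.0, 0.2)], 60, seed=33)
        # no branch matches the foreground clade, so classes 2a/2b behave as
        # background everywhere: (p0 + p2a -> omega0, p1 + p2b -> 1)
        mdl = BranchSiteModel(
            2.0, 0.8, 0.1, 0.2, 5.0, {frozenset({"no-such-leaf"})}, UNIFORM_PI
        )
        site = SiteClassModel(
            2.0,
            [(0.8 + 0.1 * 8 / 9, 0.2), (0.1 + 0.1 * 1 / 9, 1.0)],
            UNIFORM_PI,
        )
        assert codon_loglik(tree, aln, mdl) == pytest.approx(
            codon_loglik(tree, aln, site), abs=1e-9
        )

    def test_branch_site_h0_structure_is_h1_with_omega2_fixed(self):
        tree = simulate_yule_tree(5, 1.0, seed=32)
        aln = simulate_codon_alignment(tree, 2.0, [(1.0, 0.2)], 60, seed=33)
        fg = frozenset(
            l.taxon.label for l in tree.seed_node.child_nodes()[0].leaf_iter()
        )
        h0 = BranchSiteModel(2.0, 0.8, 0.1, 0.2, 1.0, {fg}, UNIFORM_PI)
        h1_pinned = BranchSiteModel(2.0, 0.8, 0.1, 0.2, 1.0 + 1e-12, {fg}, UNIFORM_PI)
        assert codon_loglik(tree, aln, h0) == pytest.approx(
            codon_loglik(tree, aln, h1_pinned), abs=1e-6
        )


class TestDiscreteBeta:
    def test_category_means_average_to_beta_mean(self):
        for p, q in [(0.5, 2.0), (2.0, 2.0), (0.2, 0.3)]:
            classes = discrete_beta(p, q, 10)
            mean = sum(pr * w for pr, w in classes)
            assert mean == pytest.approx(p / (p + q), abs=1e-6)
            assert sum(pr for pr, _ in classes) == pytest.approx(1.0)

    def test_means_monotone(self):
        classes = discrete_beta(1.5, 3.0, 10)
        omegas = [w for _, w in classes]
        assert omegas == sorted(omegas)


class TestSiteModelFits:
    @pytest.fixture(scope="class")
    @staticmethod
    def simulated_purifying():
        tree = simulate_yule_tree(8, 1.0, seed=40)
        for edge in tree.preorder_edge_iter():
            if edge.length:
                edge.length *= 0.5
        aln = simulate_codon_alignment(tree, 2.0, [(1.0, 0.1)], 200, seed=41)
        return tree, aln

    def test_m0_recovers_omega_and_nesting_holds(self, simulated_purifying):
        tree, aln = simulated_purifying
        fits = fit_site_models(tree, aln, models=("M0", "M1", "M2"))
        omega = fits["M0"].params["omega"]
        assert 0.05 <= omega <= 0.2
        assert fits["M1"].lnl >= fits["M0"].lnl - 1e-3
        assert fits["M2"].lnl >= fits["M1"].lnl - 1e-9

    def test_m7_m8_nesting(self, simulated_purifying):
        tree, aln = simulated_purifying
        fits = fit_site_models(tree, aln, models=("M7", "M8"), K=6)
        assert fits["M8"].lnl >= fits["M7"].lnl - 1e-9

    def test_m8_detects_positive_selection_class(self):
        tree = simulate_yule_tree(8, 1.0, seed=42)
        aln = simulate_codon_alignment(
            tree, 2.0, [(0.9, 0.1), (0.1, 3.0)], 300, seed=43
        )
        fits = fit_site_models(tree, aln, models=("M7", "M8"), K=6)
        lrt = 2 * (fits["M8"].lnl - fits["M7"].lnl)
        assert lrt > 5.99  # chi2_2 95th percentile
        assert fits["M8"].params["omega_s"] > 1.5


class TestBranchSiteFits:
    def test_no_signal_gives_tiny_lrt(self):
        tree = simulate_yule_tree(6, 1.0, seed=44)
        aln = simulate_codon_alignment(tree, 2.0, [(1.0, 0.1)], 150, seed=45)
        fg = frozenset(
            l.taxon.label for l in tree.seed_node.child_nodes()[0].leaf_iter()
        )
        h0 = fit_branch_site(tree, aln, {fg}, "H0")
        h1 = fit_branch_site(tree, aln, {fg}, "H1", _seed_params=h0.params)
        lrt = 2 * (h1.lnl - h0.lnl)
        assert -1e-6 <= lrt < 3.84


class TestNeiGojobori:
    def test_only_synonymous_differences(self):
        # two synonymous third-position changes (Leu TTA->TTG, Ser TCA->TCG)
        # padded with identical codons so the JC correction stays in range
        pad = "GGTGAAATTCCGAAA" * 2
        aln = Alignment(ids=["a", "b"], seqs=[pad + "TTATCA", pad + "TTGTCG"])
        table = nei_gojobori_dnds(aln)
        assert table.loc[0, "dN"] == 0.0
        assert table.loc[0, "dS"] > 0.0

    def test_identical_sequences_flagged_undefined(self):
        aln = Alignment(ids=["a", "b"], seqs=["ATGGCT", "ATGGCT"])
        table = nei_gojobori_dnds(aln)
        assert table.loc[0, "dN"] == 0.0 and table.loc[0, "dS"] == 0.0
        assert bool(table.loc[0, "undefined"])

    def test_purifying_simulation_low_ratio(self):
        tree = simulate_yule_tree(6, 1.0, seed=46)
        aln = simulate_codon_alignment(tree, 2.0, [(1.0, 0.1)], 300, seed=47)
        table = nei_gojobori_dnds(aln)
        ratios = table["dN_dS"].dropna()
        assert len(ratios) > 0
        assert ratios.median() < 0.5
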