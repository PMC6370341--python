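import math

import numpy as np
import pandas as pd
import pytest

from picotrait.genecontent import GenePresenceTable
from picotrait.io import newick_string, tree_depths
from picotrait.recombination import realized_rm_from_log
from picotrait.selection import nei_gojobori_dnds
from picotrait.simulate import (
    simulate_binary_trait,
    simulate_clonalframe_alignment,
    simulate_codon_alignment,
    simulate_partial_genomes,
    simulate_two_population_tree,
    simulate_yule_tree,
)


class TestYuleTree:
    def test_two_taxa_cherry_equal_depths(self):
        tree = simulate_yule_tree(2, 1.0, seed=1)
        depths = tree_depths(tree)
        assert len(depths) == 2
        a, b = depths.values()
        assert a == pytest.approx(b, abs=1e-12)

    def test_ultrametric(self):
        tree = simulate_yule_tree(20, 2.0, seed=2)
        depths = list(tree_depths(tree).values())
        assert max(depths) - min(depths) < 1e-9

    def test_seed_reproducibility(self):
        t1 = simulate_yule_tree(9, 1.5, seed=33)
        t2 = simulate_yule_tree(9, 1.5, seed=33)
        assert newick_string(t1) == newick_string(t2)

    def test_split_waiting_times_match_yule_expectation(self):
        # with k lineages the wait to the next event is Exp(birth_rate * k);
        # root-to-tip depth excludes the single-lineage wait, so its mean is
        # sum_{k=2}^{n-1} 1/(b k) (splits) + 1/(b n) (extension to present)
        b, n = 2.0, 8
        depths = [
            max(tree_depths(simulate_yule_tree(n, b, seed=s)).values())
            for s in range(400)
        ]
        expected = sum(1.0 / (b * k) for k in range(2, n)) + 1.0 / (b * n)
        se = np.std(depths) / math.sqrt(len(depths))
        assert abs(np.mean(depths) - expected) < 4 * se + 0.02

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(1, 1.0, seed=0)


class TestBinaryTrait:
    def test_zero_gain_rate_keeps_all_zero(self):
        tree = simulate_yule_tree(12, 1.0, seed=3)
        hist = simulate_binary_trait(tree, q01=0.0, q10=1.0, root_state=0, seed=4)
        assert all(s == 0 for s in hist.tips.states.values())

    def test_stationary_tip_frequency(self):
        # long star-like branches: tip state frequency converges to the
        # stationary probability q01 / (q01 + q10)
        import dendropy

        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.is_rooted = True
        for i in range(300):
            leaf = dendropy.Node()
            tree.seed_node.add_child(leaf)
            leaf.edge.length = 50.0
            leaf.taxon = taxa.new_taxon(label=f"t{i}")
        q01, q10 = 0.6, 1.4
        freqs = []
        for s in range(30):
            hist = simulate_binary_trait(tree, q01, q10, seed=s)
            freqs.append(np.mean(list(hist.tips.states.values())))
        assert np.mean(freqs) == pytest.approx(q01 / (q01 + q10), abs=0.02)

    def test_internal_history_returned_and_consistent(self):
        tree = simulate_yule_tree(10, 1.0, seed=5)
        hist = simulate_binary_trait(tree, 0.5, 0.5, seed=6)
        assert len(hist.node_states) == len(list(tree.preorder_node_iter()))
        for leaf in tree.leaf_node_iter():
            assert hist.node_states[leaf] == hist.tips.states[leaf.taxon.label]

    def test_seed_reproducibility(self):
        tree = simulate_yule_tree(10, 1.0, seed=7)
        h1 = simulate_binary_trait(tree, 0.3, 0.9, seed=8)
        h2 = simulate_binary_trait(tree, 0.3, 0.9, seed=8)
        assert h1.tips.states == h2.tips.states


class TestPartialGenomes:
    def full_table(self, n_genomes=5, n_genes=2000):
        mat = pd.DataFrame(
            np.ones((n_genomes, n_genes), dtype=int),
            index=[f"g{i}" for i in range(n_genomes)],
            columns=[f"c{j}" for j in range(n_genes)],
        )
        rec = pd.Series(1.0, index=mat.index)
        return GenePresenceTable(matrix=mat, recovery=rec)

    def test_full_recovery_is_identity(self):
        table = self.full_table()
        rec = pd.Series(1.0, index=table.matrix.index)
        out = simulate_partial_genomes(table, rec, seed=1)
        assert (out.matrix.to_numpy() == table.matrix.to_numpy()).all()

    def test_retained_count_within_binomial_bounds(self):
        from scipy.stats import binom

        table = self.full_table()
        rec = pd.Series(0.8, index=table.matrix.index)
        out = simulate_partial_genomes(table, rec, seed=2)
        lo, hi = binom.ppf([0.0005, 0.9995], 2000, 0.8)
        counts = out.matrix.sum(axis=1)
        assert ((counts >= lo) & (counts <= hi)).all()

    def test_absent_genes_stay_absent(self):
        table = self.full_table(n_genes=50)
        table.matrix.iloc[:, :25] = 0
        rec = pd.Series(0.5, index=table.matrix.index)
        out = simulate_partial_genomes(table, rec, seed=3)
        assert (out.matrix.iloc[:, :25].to_numpy() == 0).all()

    def test_invalid_fraction(self):
        table = self.full_table(n_genes=10)
        rec = pd.Series(1.2, index=table.matrix.index)
        with pytest.raises(ValueError):
            simulate_partial_genomes(table, rec, seed=4)


class TestClonalFrame:
    def test_no_imports_when_rate_zero(self):
        tree = simulate_yule_tree(4, 1.0, seed=9)
        _, log = simulate_clonalframe_alignment(
            tree, theta=0.02, R_over_theta=0.0, delta=50, nu=0.1, L=5000, seed=10
        )
        assert (log["event"] == "mutation").all()

    def test_mean_tract_length_near_delta(self):
        tree = simulate_yule_tree(6, 1.0, seed=11)
        delta = 40.0
        _, log = simulate_clonalframe_alignment(
            tree, theta=0.01, R_over_theta=2.0, delta=delta, nu=0.05,
            L=200_000, seed=12,
        )
        imports = log[log["event"] == "import"]
        assert len(imports) > 500
        # truncation at the sequence end only trims a delta/L sliver
        assert imports["tract_length"].mean() == pytest.approx(delta, rel=0.1)

    def test_realized_rm_near_expected(self):
        tree = simulate_yule_tree(6, 1.0, seed=13)
        R, delta, nu = 1.0, 100.0, 0.05
        _, log = simulate_clonalframe_alignment(
            tree, theta=0.02, R_over_theta=R, delta=delta, nu=nu,
            L=300_000, seed=14,
        )
        assert realized_rm_from_log(log) == pytest.approx(R * delta * nu, rel=0.15)

    def test_seed_reproducibility(self):
        tree = simulate_yule_tree(4, 1.0, seed=15)
        a1, l1 = simulate_clonalframe_alignment(tree, 0.01, 1.0, 30, 0.1, 2000, seed=16)
        a2, l2 = simulate_clonalframe_alignment(tree, 0.01, 1.0, 30, 0.1, 2000, seed=16)
        assert a1.seqs == a2.seqs and l1.equals(l2)

    def test_delta_validation(self):
        tree = simulate_yule_tree(4, 1.0, seed=17)
        with pytest.raises(ValueError, match="delta"):
            simulate_clonalframe_alignment(tree, 0.01, 1.0, 0.5, 0.1, 100, seed=18)


class TestCodonAlignment:
    def test_omega_zero_preserves_protein_sequence(self):
        # every substitution is synonymous, so all taxa share one protein
        from Bio.Seq import Seq

        tree = simulate_yule_tree(6, 1.0, seed=19)
        aln = simulate_codon_alignment(tree, 2.0, [(1.0, 0.0)], 150, seed=20)
        proteins = {str(Seq(s).translate()) for s in aln.seqs}
        assert len(proteins) == 1

    def test_transition_transversion_balance(self):
        # kappa = 1 and neutral omega: transitions happen at 1/2 the rate of
        # transversions (one transition partner vs two transversion targets)
        import dendropy

        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.is_rooted = True
        for label in ("x", "y"):
            leaf = dendropy.Node()
            tree.seed_node.add_child(leaf)
            leaf.edge.length = 0.02
            leaf.taxon = taxa.new_taxon(label=label)
        transitions = transversions = 0
        pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        for s in range(40):
            aln = simulate_codon_alignment(tree, 1.0, [(1.0, 1.0)], 400, seed=s)
            for a, b in zip(aln.seqs[0], aln.seqs[1]):
                if a != b:
                    if (a, b) in pairs:
                        transitions += 1
                    else:
                        transversions += 1
        ratio = transitions / transversions
        assert ratio == pytest.approx(0.5, abs=0.1)

    def test_proportions_validated(self):
        tree = simulate_yule_tree(4, 1.0, seed=21)
        with pytest.raises(ValueError, match="proportions"):
            simulate_codon_alignment(tree, 2.0, [(0.5, 0.1), (0.4, 1.0)], 10, seed=22)

    def test_seed_reproducibility_and_no_stops(self):
        from picotrait.selection import STOP_CODONS

        tree = simulate_yule_tree(5, 1.0, seed=23)
        a1 = simulate_codon_alignment(tree, 2.0, [(0.7, 0.1), (0.3, 1.5)], 80, seed=24)
        a2 = simulate_codon_alignment(tree, 2.0, [(0.7, 0.1), (0.3, 1.5)], 80, seed=24)
        assert a1.seqs == a2.seqs
        for seq in a1.seqs:
            for k in range(0, len(seq), 3):
                assert seq[k : k + 3] not in STOP_CODONS


class TestTwoPopulationTree:
    def test_complete_segregation_structure(self):
        from picotrait.divergence import p_test, unweighted_unifrac

        tree, pops = simulate_two_population_tree(9, "complete", seed=25)
        assert sorted(set(pops.values())) == ["popA", "popB"]
        assert p_test(tree, pops) == 1
        assert unweighted_unifrac(tree, pops) == pytest.approx(1.0)

    def test_no_segregation_label_counts(self):
        tree, pops = simulate_two_population_tree(7, "none", seed=26)
        labels = list(pops.values())
        assert labels.count("popA") == labels.count("popB") == 7

    def test_seed_reproducibility(self):
        t1, p1 = simulate_two_population_tree(5, "none", seed=27)
        t2, p2 = simulate_two_population_tree(5, "none", seed=27)
        assert newick_string(t1) == newick_string(t2) and p1 == p2

    def test_seed_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            simulate_two_population_tree(5, "none", seed=None)
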