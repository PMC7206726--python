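"""selection_relaxation: GY94 machinery, fits, LRTs, scans."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

from conftest import make_seven_taxon_tree
from holoplast import selection_relaxation as sr
from holoplast import synthetic_data as sd
from holoplast.genome_io import PhyloTree


@pytest.fixture(scope="module")
def pi():
    return sr.f3x4_frequencies(np.array([[0.3, 0.18, 0.2, 0.32]] * 3))


class TestRateMatrix:
    def test_rows_sum_to_zero(self, pi):
        q = sr.rate_matrix(2.0, 0.3, pi)
        assert np.abs(q.sum(axis=1)).max() < 1e-12

    def test_stationary_frequencies_are_input(self, pi):
        q = sr.rate_matrix(2.0, 0.3, pi)
        assert np.abs(pi @ q).max() < 1e-12
        # P(t) rows converge to pi for long t
        p = sr.transition_matrix(2.0, 0.3, pi, 60.0)
        assert np.abs(p - pi[np.newaxis, :]).max() < 1e-5

    def test_mean_rate_normalised_to_one(self, pi):
        q = sr.rate_matrix(1.7, 0.4, pi)
        assert -np.dot(pi, np.diag(q)) == pytest.approx(1.0)

    def test_transition_matrix_matches_direct_exponential(self, pi):
        q = sr.rate_matrix(2.5, 0.15, pi)
        for t in (0.01, 0.3, 1.7):
            assert np.abs(sr.transition_matrix(2.5, 0.15, pi, t)
                          - expm(q * t)).max() < 1e-10

    def test_f3x4_zeroes_stops_and_normalises(self):
        freqs = sr.f3x4_frequencies(np.full((3, 4), 0.25))
        assert freqs.sum() == pytest.approx(1.0)
        assert len(freqs) == 61


class TestCodonAlignment:
    def test_identical_cds_gap_free(self):
        cds = "ATGAAACCCGGGTTTTAA"
        aln = sr.build_codon_alignment({"A": cds, "B": cds})
        assert aln.n_codons == 5  # terminal stop stripped
        assert "-" not in aln.rows[0] + aln.rows[1]

    def test_internal_stop_error_names_taxon_and_codon(self):
        with pytest.raises(ValueError, match="taxB.*codon 3"):
            sr.build_codon_alignment({"taxA": "ATGAAACCCTAA",
                                      "taxB": "ATGAAATAACCCGGGTAA"})

    def test_back_translation_reproduces_protein_alignment(self):
        from Bio.Seq import Seq
        cds = {"A": "ATGAAACCCGGGTTTCATTAA", "B": "ATGAAAGGGTTTCATTAA",
               "C": "ATGAAACCCGGGTTTCATTAA"}
        aln = sr.build_codon_alignment(cds)
        for taxon, row in zip(aln.taxa, aln.rows):
            prot = "".join(
                "-" if row[i:i + 3] == "---"
                else str(Seq(row[i:i + 3]).translate(table=11))
                for i in range(0, len(row), 3))
            # ungapping the aligned protein row gives the original protein
            original = str(Seq(cds[taxon][:-3]).translate(table=11))
            assert prot.replace("-", "") == original


class TestLikelihood:
    def test_two_taxon_toy_matches_brute_force(self, pi):
        aln = sr.CodonAlignment(["A", "B"], ["ATGAAACCC", "ATGAAGCCA"])
        tree = PhyloTree.from_newick_string("(A:0.1,B:0.2);")
        lik = sr._Likelihood(aln, tree, "M0")
        got = lik.lnl(np.array([0.1, 0.2]), 2.0, np.array([0.3]))
        p_a = expm(sr.rate_matrix(2.0, 0.3, lik.pi) * 0.1)
        p_b = expm(sr.rate_matrix(2.0, 0.3, lik.pi) * 0.2)
        brute = 0.0
        for c in range(3):
            ca = sr.CODON_INDEX[aln.rows[0][3 * c:3 * c + 3]]
            cb = sr.CODON_INDEX[aln.rows[1][3 * c:3 * c + 3]]
            site = sum(lik.pi[r] * p_a[r, ca] * p_b[r, cb] for r in range(61))
            brute += np.log(site)
        assert got == pytest.approx(brute, abs=1e-6)

    def test_rerooting_invariance(self):
        # same unrooted 3-taxon tree, two rootings
        aln = sr.CodonAlignment(["A", "B", "C"],
                                ["ATGAAACCCTTT", "ATGAAGCCATTC", "ATGCAACCCTAT"])
        t1 = PhyloTree.from_newick_string("((A:0.1,B:0.2):0.12,C:0.18);")
        t2 = PhyloTree.from_newick_string("((A:0.1,C:0.3):0.0,B:0.2);")
        l1 = sr._Likelihood(aln, t1, "M0").lnl(np.array([0.1, 0.2, 0.12, 0.18]),
                                               2.0, np.array([0.3]))
        # postorder branch order differs; map by leafset labels
        lik2 = sr._Likelihood(aln, t2, "M0")
        lengths = {"A": 0.1, "C": 0.3, "B": 0.2, "A|C": 0.0}
        bl2 = np.array([lengths[lik2.tidx.branch_label(n)]
                        for n in lik2.tidx.branch_nodes])
        l2 = lik2.lnl(bl2, 2.0, np.array([0.3]))
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_gap_codons_marginalised(self):
        aln = sr.CodonAlignment(["A", "B"], ["ATGAAA---", "ATGAAGCCA"])
        tree = PhyloTree.from_newick_string("(A:0.1,B:0.2);")
        lik = sr._Likelihood(aln, tree, "M0")
        val = lik.lnl(np.array([0.1, 0.2]), 2.0, np.array([0.4]))
        assert np.isfinite(val)


class TestFitsAndLRT:
    def test_m2_constrained_equals_m0(self, seven_taxon_tree):
        spec = sd.CodonSimSpec(n_codons=150)
        aln, _ = sd.simulate_codon_alignment(seven_taxon_tree, spec, seed=21)
        m0 = sr.fit_branch_model(aln, seven_taxon_tree, "M0", n_restarts=1)
        # evaluating the M2 likelihood at the M0 solution reproduces its lnL
        lik2 = sr._Likelihood(aln, seven_taxon_tree, "M2")
        bl = np.array([m0.branch_lengths[lik2.tidx.branch_label(n)]
                       for n in lik2.tidx.branch_nodes])
        l2 = lik2.lnl(bl, m0.kappa, np.array([m0.omega[0], m0.omega[0]]))
        assert l2 == pytest.approx(m0.lnl, abs=1e-4)

    def test_nesting_chain_never_decreases(self, seven_taxon_tree):
        spec = sd.CodonSimSpec(n_codons=200)
        aln, _ = sd.simulate_codon_alignment(seven_taxon_tree, spec, seed=22)
        m0 = sr.fit_branch_model(aln, seven_taxon_tree, "M0", n_restarts=1)
        m2 = sr.fit_branch_model(aln, seven_taxon_tree, "M2", n_restarts=1,
                                 init=m0)
        m3 = sr.fit_branch_model(aln, seven_taxon_tree, "M3", n_restarts=1,
                                 init=m2)
        assert m0.lnl <= m2.lnl + 1e-4
        assert m2.lnl <= m3.lnl + 1e-4
        assert m2.n_free_params - m0.n_free_params == 1
        assert m3.n_free_params - m2.n_free_params == 1

    def test_lrt_analytic_values(self):
        def fit(lnl, nparams):
            return sr.BranchModelFit("M0", lnl, 2.0, {0: 0.2}, {0: "all"},
                                     np.ones(61) / 61, {}, nparams, True,
                                     {0: True})
        res = sr.likelihood_ratio_test(fit(-100.0, 10), fit(-100.0, 11))
        assert res.p_value == pytest.approx(1.0)
        res2 = sr.likelihood_ratio_test(fit(-100.0, 10),
                                        fit(-100.0 + 3.841 / 2, 11))
        assert res2.p_value == pytest.approx(0.05, abs=5e-4)
        assert res2.p_value == pytest.approx(chi2.sf(3.841, 1), abs=1e-12)

    def test_lrt_negative_statistic_errors(self):
        def fit(lnl, nparams):
            return sr.BranchModelFit("M0", lnl, 2.0, {0: 0.2}, {0: "all"},
                                     np.ones(61) / 61, {}, nparams, True,
                                     {0: True})
        with pytest.raises(RuntimeError, match="optimiser failure"):
            sr.likelihood_ratio_test(fit(-100.0, 10), fit(-101.0, 11))


class TestScan:
    def test_empty_panel_empty_table(self, seven_taxon_tree):
        table = sr.relaxation_scan({}, seven_taxon_tree)
        assert len(table) == 0

    def test_relaxed_genes_flagged_with_power(self):
        # parasitic omega raised 0.1 -> 0.6 on half the genes
        tree = make_seven_taxon_tree()
        null_spec = sd.CodonSimSpec(
            n_codons=400, omega_by_class={"autotrophic": 0.1,
                                          "hemiparasitic": 0.1,
                                          "holoparasitic": 0.1})
        relaxed_spec = sd.CodonSimSpec(
            n_codons=400, omega_by_class={"autotrophic": 0.1,
                                          "hemiparasitic": 0.6,
                                          "holoparasitic": 0.6})
        genes = {}
        for i in range(3):
            genes[f"null{i}"], _ = sd.simulate_codon_alignment(
                tree, null_spec, seed=300 + i)
            genes[f"relaxed{i}"], _ = sd.simulate_codon_alignment(
                tree, relaxed_spec, seed=400 + i)
        table = sr.relaxation_scan(genes, tree, seed=1).set_index("gene")
        relaxed_flags = [bool(table.loc[f"relaxed{i}", "significant_M0_M2"])
                         for i in range(3)]
        assert sum(relaxed_flags) >= 2  # >= 80% power at this effect size
        # estimated parasitic omega exceeds background on relaxed genes
        for i in range(3):
            row = table.loc[f"relaxed{i}"]
            assert row["omega_parasitic_M2"] > row["omega_background_M2"]

    def test_gene_missing_taxon_skipped_with_warning(self, seven_taxon_tree):
        aln = sr.CodonAlignment(["Aindica", "Rglutinosa"],
                                ["ATGAAACCC", "ATGAAGCCA"])
        with pytest.warns(UserWarning, match="missing taxa"):
            table = sr.relaxation_scan({"short": aln}, seven_taxon_tree)
        assert len(table) == 0
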