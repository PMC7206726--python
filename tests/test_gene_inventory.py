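"""gene_inventory: status classification, matrices, pathways, qPCR."""

import numpy as np
import pandas as pd
import pytest

from holoplast import gene_inventory as gi
from holoplast import synthetic_data as sd
from holoplast.genome_io import revcomp


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture()
def reference_cds():
    rng = np.random.default_rng(0)
    return sd._random_cds(rng, 300)  # 100 codons


def _embed(rng, gene_seq, flank=400):
    return _rand_seq(rng, flank) + gene_seq + _rand_seq(rng, flank)


class TestClassifyGeneStatus:
    def test_reference_vs_itself_intact(self, reference_cds):
        status = gi.classify_gene_status(reference_cds, reference_cds)
        assert status.status == "intact"
        assert status.reason == "none" and status.codon_index == 0
        assert status.reference_coverage == pytest.approx(1.0)
        assert status.identity == pytest.approx(100.0)

    def test_minus_strand_hit_found(self, reference_cds):
        rng = np.random.default_rng(1)
        region = _embed(rng, revcomp(reference_cds))
        assert gi.classify_gene_status(region, reference_cds).status == "intact"

    def test_engineered_premature_stop(self, reference_cds):
        rng = np.random.default_rng(2)
        mutated = reference_cds[:3 * 19] + "TAA" + reference_cds[3 * 20:]
        status = gi.classify_gene_status(_embed(rng, mutated), reference_cds)
        assert (status.status, status.reason) == ("pseudogene", "premature_stop")
        assert status.codon_index == 20

    def test_engineered_frameshift_at_codon_10(self, reference_cds):
        rng = np.random.default_rng(3)
        p, actual = sd._pin_frameshift_position(reference_cds, 10)
        mutated = reference_cds[:p] + reference_cds[p + 1:]
        status = gi.classify_gene_status(_embed(rng, mutated), reference_cds)
        assert (status.status, status.reason) == ("pseudogene", "frameshift")
        assert status.codon_index == actual
        assert abs(actual - 10) <= 1

    def test_engineered_truncation(self, reference_cds):
        rng = np.random.default_rng(4)
        mutated = reference_cds[:3 * 54]  # gene ends at codon 54
        status = gi.classify_gene_status(_embed(rng, mutated), reference_cds)
        assert (status.status, status.reason) == ("pseudogene", "truncation")
        assert status.codon_index == 55

    def test_absent_gene_is_lost(self, reference_cds):
        rng = np.random.default_rng(5)
        status = gi.classify_gene_status(_rand_seq(rng, 3000), reference_cds)
        assert status.status == "lost"

    def test_terminal_stop_drift_ignored(self, reference_cds):
        rng = np.random.default_rng(6)
        # stop in the final 5% of codons (codon 98 of 100) is tolerated
        mutated = reference_cds[:3 * 97] + "TAA" + reference_cds[3 * 98:]
        status = gi.classify_gene_status(_embed(rng, mutated), reference_cds)
        assert status.status == "intact"

    def test_invalid_reference_with_internal_stop(self):
        bad = "ATG" + "TAA" + "AAA" * 8 + "TAA"
        with pytest.raises(gi.InvalidReferenceCDS, match="internal stop"):
            gi.classify_gene_status("ACGT" * 100, bad)

    def test_rna_gene_uses_identity_only(self):
        rng = np.random.default_rng(7)
        trna = _rand_seq(rng, 80)
        region = _embed(rng, trna, flank=200)
        status = gi.classify_gene_status(region, trna, kind="tRNA")
        assert status.status == "intact"
        half = gi.classify_gene_status(_embed(rng, trna[:40], flank=200),
                                       trna, kind="tRNA")
        assert half.status in ("pseudogene", "lost")


class TestGeneContentMatrix:
    def test_reference_vs_itself_all_present(self, degraded_sim):
        _, _, truth = degraded_sim
        ref = truth.reference
        panel = [f.name for f in ref.features if f.kind == "CDS"][:8]
        matrix = gi.build_gene_content_matrix([ref], ref, panel=panel)
        assert (matrix.table.loc[ref.id] == "present").all()

    def test_degraded_row_matches_simulator_truth(self, degraded_sim):
        _, degraded, truth = degraded_sim
        ref = truth.reference
        panel = ["psbA", "psaA", "rbcL", "atpI", "atpA", "accD", "rps2",
                 "matK", "clpP", "ndhB"]
        matrix = gi.build_gene_content_matrix([degraded], ref, panel=panel)
        code = {"intact": "present", "pseudogene": "pseudogene",
                "lost": "absent"}
        for gene in panel:
            expected = code[truth.gene_status[gene][0]]
            assert matrix.cell(degraded.id, gene) == expected, gene

    def test_row_content_independent_of_genome_order(self, degraded_sim):
        _, degraded, truth = degraded_sim
        ref = truth.reference
        panel = ["psbA", "accD", "rps2"]
        m1 = gi.build_gene_content_matrix([degraded, ref], ref, panel=panel)
        m2 = gi.build_gene_content_matrix([ref, degraded], ref, panel=panel)
        assert m1.table.loc[degraded.id].equals(m2.table.loc[degraded.id])
        assert m1.table.loc[ref.id].equals(m2.table.loc[ref.id])

    def test_duplicate_species_ids_rejected(self, degraded_sim):
        _, degraded, truth = degraded_sim
        with pytest.raises(ValueError, match="duplicate"):
            gi.build_gene_content_matrix([degraded, degraded], truth.reference,
                                         panel=["accD"])


def photosynthesis_map():
    """63-component pathway: 30 plastid + 33 nuclear genes (ko00195-like)."""
    rows = [("ko00195", f"plastid_gene_{i}", "plastid") for i in range(30)]
    rows += [("ko00195", f"nuclear_gene_{i}", "nuclear") for i in range(33)]
    return pd.DataFrame(rows, columns=["pathway", "gene", "compartment"])


class TestPathwayAudit:
    def test_63_component_map_with_14_expressed(self):
        expressed = [f"nuclear_gene_{i}" for i in range(14)]
        (audit,) = gi.pathway_audit(photosynthesis_map(), expressed)
        assert len(audit.components) == 63
        assert len(audit.expressed) == 14
        assert len(audit.missing) == 49
        counts = audit.counts_by_compartment().set_index("compartment")
        assert counts.loc["plastid", "total"] == 30
        assert counts.loc["nuclear", "expressed"] == 14

    def test_empty_expressed_set(self):
        (audit,) = gi.pathway_audit(photosynthesis_map(), [])
        assert audit.expressed == set() and len(audit.missing) == 63

    def test_random_subsets_match_set_arithmetic(self):
        rng = np.random.default_rng(8)
        pmap = photosynthesis_map()
        genes = list(pmap["gene"])
        for _ in range(10):
            chosen = set(rng.choice(genes, size=rng.integers(0, 40),
                                    replace=False))
            (audit,) = gi.pathway_audit(pmap, chosen)
            assert audit.expressed == chosen
            assert audit.missing == set(genes) - chosen
            assert audit.expressed | audit.missing == set(genes)
            assert not (audit.expressed & audit.missing)

    def test_unknown_expressed_ids_warn_and_are_ignored(self):
        with pytest.warns(UserWarning, match="absent"):
            (audit,) = gi.pathway_audit(photosynthesis_map(), ["nope"])
        assert audit.expressed == set()


def _ct_tables():
    ct = pd.DataFrame([
        ("g1", "cal", 20.0), ("g1", "s1", 21.0), ("g1", "s2", 22.0),
        ("g2", "cal", 18.0), ("g2", "s1", 17.0), ("g2", "s2", 16.0),
        ("actin", "cal", 15.0), ("actin", "s1", 15.0), ("actin", "s2", 15.0),
    ], columns=["gene", "sample", "ct"])
    # TPM exactly proportional to 2^-ddCt
    rows = []
    for gene, base in (("g1", 50.0), ("g2", 80.0)):
        g = ct[ct["gene"] == gene].set_index("sample")["ct"]
        a = ct[ct["gene"] == "actin"].set_index("sample")["ct"]
        dct = g - a
        ddct = dct - dct["cal"]
        for sample, v in ddct.items():
            rows.append((gene, sample, base * 2.0 ** (-v)))
    tpm = pd.DataFrame(rows, columns=["gene", "sample", "tpm"])
    return ct, tpm


class TestQpcr:
    def test_known_fold_changes(self):
        ct, tpm = _ct_tables()
        folds, _ = gi.qpcr_crosscheck(ct, tpm, "actin", "cal")
        f = folds.set_index(["gene", "sample"])["fold_change"]
        assert f[("g1", "cal")] == pytest.approx(1.0)   # ddCt = 0
        assert f[("g1", "s1")] == pytest.approx(0.5)    # ddCt = 1
        assert f[("g2", "s2")] == pytest.approx(4.0)    # ddCt = -2

    def test_proportional_tables_give_r_squared_one(self):
        ct, tpm = _ct_tables()
        _, r2 = gi.qpcr_crosscheck(ct, tpm, "actin", "cal")
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_fold_change_strictly_decreasing_in_ddct(self):
        ddct = np.linspace(-3, 3, 13)
        folds = 2.0 ** (-ddct)
        assert np.all(np.diff(folds) < 0)

    def test_replicates_averaged_first(self):
        ct, tpm = _ct_tables()
        ct_rep = pd.concat([ct, ct.assign(ct=ct["ct"] + 0.0)])
        f1, _ = gi.qpcr_crosscheck(ct, tpm, "actin", "cal")
        f2, _ = gi.qpcr_crosscheck(ct_rep, tpm, "actin", "cal")
        assert f1["fold_change"].tolist() == f2["fold_change"].tolist()

    def test_missing_reference_gene_errors(self):
        ct, tpm = _ct_tables()
        with pytest.raises(ValueError, match="reference gene"):
            gi.qpcr_crosscheck(ct, tpm, "gapdh", "cal")
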