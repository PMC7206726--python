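"""igt_locator: extraction, assembly, filtering, annotation, depth logic."""

import numpy as np
import pytest

from holoplast import igt_locator as il
from holoplast import synthetic_data as sd
from holoplast.genome_io import AnnotatedGenome, ReadPair, revcomp


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _pair(id_, seq1, seq2=None):
    seq2 = seq2 or revcomp(seq1)
    return ReadPair(id_, seq1, seq2, "I" * len(seq1), "I" * len(seq2))


def _tiling_pairs(template, read_len=150, step=5, label="t"):
    """Error-free read pairs tiling a template (both mates informative)."""
    pairs = []
    n = len(template)
    i = 0
    idx = 0
    while i + read_len <= n:
        j = min(n, i + 2 * read_len)
        r1 = template[i:i + read_len]
        r2 = revcomp(template[max(0, j - read_len):j])
        pairs.append(_pair(f"{label}{idx}", r1, r2))
        i += step
        idx += 1
    return pairs


class TestExtraction:
    def test_exact_substring_read_retained(self):
        rng = np.random.default_rng(0)
        bait = _rand_seq(rng, 2000)
        read = bait[100:250]
        kept = il.extract_baitlike_reads([_pair("a", read)], [bait])
        assert len(kept) == 1

    def test_random_read_discarded(self):
        rng = np.random.default_rng(1)
        bait = _rand_seq(rng, 2000)
        read = _rand_seq(rng, 150)
        assert il.extract_baitlike_reads([_pair("a", read)], [bait]) == []

    def test_either_mate_suffices(self):
        rng = np.random.default_rng(2)
        bait = _rand_seq(rng, 2000)
        pair = _pair("a", _rand_seq(rng, 150), revcomp(bait[0:150]))
        assert len(il.extract_baitlike_reads([pair], [bait])) == 1

    def test_empty_bait_panel_errors(self):
        with pytest.raises(ValueError, match="empty bait panel"):
            il.extract_baitlike_reads([], [])


class TestAssembly:
    def test_single_template_single_contig(self):
        rng = np.random.default_rng(3)
        template = _rand_seq(rng, 1000)
        contigs = il.assemble_contigs(_tiling_pairs(template))
        assert len(contigs) == 1
        got = contigs[0].sequence
        assert got in (template, revcomp(template))

    def test_template_below_min_contig_len_dropped(self):
        rng = np.random.default_rng(4)
        template = _rand_seq(rng, 120)
        pairs = [_pair("a", template[:60], revcomp(template[60:]))]
        assert il.assemble_contigs(pairs, k=31, min_contig_len=150) == []

    def test_two_disjoint_templates_two_contigs(self):
        rng = np.random.default_rng(5)
        t1, t2 = _rand_seq(rng, 800), _rand_seq(rng, 700)
        pairs = _tiling_pairs(t1, label="a") + _tiling_pairs(t2, label="b")
        contigs = il.assemble_contigs(pairs)
        assert len(contigs) == 2
        seqs = {min(c.sequence, revcomp(c.sequence)) for c in contigs}
        assert seqs == {min(t1, revcomp(t1)), min(t2, revcomp(t2))}

    def test_no_reads_empty(self):
        assert il.assemble_contigs([]) == []

    def test_even_k_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            il.assemble_contigs([_pair("a", "ACGT" * 40)], k=30)


class TestPlastomeAlignmentAndFilter:
    def test_exact_substring_contig_full_identity(self):
        rng = np.random.default_rng(6)
        plastome = _rand_seq(rng, 5000)
        contig = il.Contig("c", plastome[1000:1400], np.ones(400))
        hit = il.align_to_plastome(contig, plastome)
        assert hit.identity == pytest.approx(100.0)
        assert hit.alignment_length == 400

    def test_seeded_substitutions_identity_matches_mutation_count(self):
        rng = np.random.default_rng(7)
        plastome = _rand_seq(rng, 5000)
        segment = plastome[2000:2400]
        mutated = sd._mutate(segment, 40, np.random.default_rng(8))  # 10%
        contig = il.Contig("c", mutated, np.ones(400))
        hit = il.align_to_plastome(contig, plastome)
        assert hit is not None
        assert abs(hit.identity - 90.0) <= 1.0

    def test_random_contig_no_hit(self):
        rng = np.random.default_rng(9)
        plastome = _rand_seq(rng, 5000)
        contig = il.Contig("c", _rand_seq(rng, 300), np.ones(300))
        assert il.align_to_plastome(contig, plastome) is None

    @pytest.mark.parametrize("identity,alen,clen,kept", [
        (85.0, 400, 400, True),    # low identity, full length
        (99.0, 400, 400, False),   # plastome-resident
        (90.0, 400, 400, True),    # boundary: <= is inclusive
        (99.0, 300, 400, True),    # alignment shorter than contig
    ])
    def test_filter_rule(self, identity, alen, clen, kept):
        contig = il.Contig("c", "A" * clen, np.ones(clen))
        hit = il.PlastomeHit("c", identity, alen, (0, alen), (0, alen), "+")
        cands, resident = il.filter_transfer_candidates([contig], {"c": hit})
        assert (len(cands) == 1) is kept

    def test_no_hit_contig_never_discarded(self):
        contig = il.Contig("c", "A" * 200, np.ones(200))
        cands, _ = il.filter_transfer_candidates([contig], {"c": None})
        assert cands == [contig]


class TestTranslatedAnnotation:
    @pytest.fixture()
    def proteome(self, degraded_sim):
        _, _, truth = degraded_sim
        return truth.reference, il.reference_proteome(truth.reference)

    def test_cds_contig_assigned_to_its_gene(self, proteome):
        reference, proteins = proteome
        cds = reference.feature_sequence(reference.feature_by_name("psbA"))
        contig = il.Contig("c", cds, np.ones(len(cds)))
        asg = il.annotate_candidates_translated([contig], proteins)
        assert asg["c"].gene == "psbA"
        assert asg["c"].evalue < 1e-5

    def test_reverse_complement_same_assignment(self, proteome):
        reference, proteins = proteome
        cds = reference.feature_sequence(reference.feature_by_name("psbA"))
        contig = il.Contig("c", revcomp(cds), np.ones(len(cds)))
        asg = il.annotate_candidates_translated([contig], proteins)
        assert asg["c"].gene == "psbA"
        assert asg["c"].frame < 0

    def test_evalue_matches_standalone_karlin_altschul(self):
        # independent recomputation of E = K m n exp(-lambda S)
        score, m, n = 100.0, 120, 9000
        expected = 0.041 * m * n * np.exp(-0.267 * score)
        assert il.karlin_altschul_evalue(score, m, n) == pytest.approx(expected)

    def test_tiny_contig_skipped_with_warning(self, proteome):
        _, proteins = proteome
        contig = il.Contig("c", "AC", np.ones(2))
        with pytest.warns(UserWarning, match="shorter than one codon"):
            asg = il.annotate_candidates_translated([contig], proteins)
        assert asg == {}


class TestDepth:
    def test_uniform_depth_empty_mask(self):
        contig = il.Contig("c", "ACGT" * 10, np.full(40, 10.0))
        assert il.masked_depth(contig, []) == pytest.approx(10.0)

    def test_hand_arithmetic_mask(self):
        contig = il.Contig("c", "ACGT", np.array([4.0, 4.0, 8.0, 8.0]))
        assert il.masked_depth(contig, [(0, 2)]) == pytest.approx(8.0)

    def test_full_mask_raises_ambiguous(self):
        contig = il.Contig("c", "ACGT", np.ones(4))
        with pytest.raises(il.AmbiguousDepth):
            il.masked_depth(contig, [(0, 4)])

    def test_baselines_from_trimodal_depths(self):
        rng = np.random.default_rng(10)
        contigs = []
        for i, depth in enumerate([500.0] * 6 + [50.0] * 8 + [5.0] * 8):
            noisy = depth * 10 ** rng.normal(0, 0.05)
            contigs.append(il.Contig(f"c{i}", "ACGT" * 100,
                                     np.full(400, noisy)))
        b = il.estimate_baselines(contigs)
        assert abs(b.plastid - 500) / 500 < 0.2
        assert abs(b.mitochondrial - 50) / 50 < 0.2
        assert abs(b.nuclear - 5) / 5 < 0.2

    def test_unimodal_depths_error(self):
        contigs = [il.Contig(f"c{i}", "ACGT" * 50, np.full(200, 20.0 + i))
                   for i in range(10)]
        with pytest.raises(ValueError, match="multimodal|separable"):
            il.estimate_baselines(contigs)

    def test_explicit_baselines_pass_through(self):
        b = il.DepthBaselines(500.0, 50.0, 1.0)
        assert (b.plastid, b.mitochondrial, b.nuclear) == (500.0, 50.0, 1.0)

    def test_inverted_baseline_ordering_rejected(self):
        with pytest.raises(ValueError, match="plastid >= mitochondrial"):
            il.DepthBaselines(5.0, 50.0, 500.0)


class TestCompartment:
    def test_nearest_in_log_space(self):
        b = il.DepthBaselines(500.0, 50.0, 1.0)
        assert il.assign_compartment(40.0, b) == "mitochondrial"
        assert il.assign_compartment(1.2, b) == "nuclear"
        assert il.assign_compartment(450.0, b) == "plastid"

    def test_ambiguous_between_close_baselines(self):
        b = il.DepthBaselines(500.0, 10.0, 5.0)
        assert il.assign_compartment(7.0, b) == "ambiguous"

    def test_non_positive_depth_errors(self):
        b = il.DepthBaselines(500.0, 50.0, 1.0)
        with pytest.raises(ValueError):
            il.assign_compartment(0.0, b)

    def test_simulated_fragment_depths_recovered(self):
        # 200 fragment-level depth draws with contig-scale noise
        rng = np.random.default_rng(11)
        b = il.DepthBaselines(500.0, 50.0, 5.0)
        truth = rng.choice(["mitochondrial", "nuclear"], size=200)
        base = np.where(truth == "mitochondrial", 50.0, 5.0)
        depths = base * 10 ** rng.normal(0.0, 0.15, size=200)
        got = [il.assign_compartment(d, b) for d in depths]
        acc = np.mean([g == t for g, t in zip(got, truth)])
        assert acc >= 0.95


class TestExpression:
    def test_verbatim_fragment_expressed(self):
        rng = np.random.default_rng(12)
        frag = _rand_seq(rng, 200)
        tx = _rand_seq(rng, 100) + frag + _rand_seq(rng, 100)
        flags = il.check_expression({"f": frag}, [("t", tx)])
        assert flags["f"] is True

    def test_absent_fragment_not_expressed(self):
        rng = np.random.default_rng(13)
        flags = il.check_expression({"f": _rand_seq(rng, 200)},
                                    [("t", _rand_seq(rng, 500))])
        assert flags["f"] is False

    def test_identity_thresholds_around_98(self):
        rng = np.random.default_rng(14)
        frag = _rand_seq(rng, 300)
        at_99 = sd._mutate(frag, 3, np.random.default_rng(15))
        at_90 = sd._mutate(frag, 30, np.random.default_rng(16))
        flags = il.check_expression(
            {"hi": frag, "lo": frag},
            [("t99", at_99)])
        assert flags["hi"] is True
        flags_lo = il.check_expression({"f": frag}, [("t90", at_90)])
        assert flags_lo["f"] is False

    def test_empty_transcripts_warns_all_false(self):
        with pytest.warns(UserWarning, match="empty transcript"):
            flags = il.check_expression({"f": "ACGT" * 50}, [])
        assert flags == {"f": False}
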