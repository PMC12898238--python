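"""Splice-site location, cryptic-acceptor scanning, frame/PTC/NMD analysis."""

import numpy as np
import pytest

from splicecase import synthetic_data as sd
from splicecase.genome_io import GeneModel, GenomeSequence, ModelError, Variant
from splicecase.splice_engine import (
    STOP_CODONS,
    analyze_frame,
    classify_splice_variant,
    locate_splice_sites,
    peptide_mass,
    predict_nmd,
    reconstruct_transcript,
    scan_cryptic_acceptor,
    splice_consequence_for_variant,
    stop_map,
)


class TestLocateSpliceSites:
    def test_two_exon_gene_has_one_donor_one_acceptor(self, toy_two_exon):
        genome, gene = toy_two_exon
        sites = locate_splice_sites(gene, genome)
        donors = [s for s in sites if s.kind == "donor"]
        acceptors = [s for s in sites if s.kind == "acceptor"]
        assert len(donors) == len(acceptors) == 1
        assert donors[0].dinucleotide_pos == (160, 161)
        assert acceptors[0].dinucleotide_pos == (188, 189)
        assert acceptors[0].first_exonic_pos == 190
        assert all(s.canonical for s in sites)

    def test_non_gt_donor_flagged_not_failed(self, toy_two_exon):
        genome, gene = toy_two_exon
        mutated = genome.with_variant(Variant("chrT", 161, "T", "C"))  # GT -> GC
        sites = locate_splice_sites(gene, mutated)
        donor = next(s for s in sites if s.kind == "donor")
        acceptor = next(s for s in sites if s.kind == "acceptor")
        assert not donor.canonical
        assert acceptor.canonical

    def test_site_counts_match_intron_count_on_random_genes(self):
        for seed in range(10):
            case = sd.make_splice_case(n_exons=3 + seed % 4, seed=seed)
            sites = locate_splice_sites(case.gene, case.genome)
            n_introns = case.gene.n_exons - 1
            assert sum(s.kind == "donor" for s in sites) == n_introns
            assert sum(s.kind == "acceptor" for s in sites) == n_introns
            assert all(s.canonical for s in sites)


class TestClassifyVariant:
    def test_acceptor_minus_two(self, nf1_case):
        label, intron = classify_splice_variant(
            nf1_case.variant, nf1_case.gene, nf1_case.genome)
        assert (label, intron) == ("acceptor-2", 1)

    @pytest.mark.parametrize(
        "pos,expected",
        [(160, "donor+1"), (161, "donor+2"), (188, "acceptor-2"),
         (189, "acceptor-1"), (240, "exonic"), (170, "deep_intronic")],
    )
    def test_each_position_class(self, toy_two_exon, pos, expected):
        genome, gene = toy_two_exon
        ref = genome.base(pos)
        alt = "A" if ref != "A" else "C"
        label, _ = classify_splice_variant(Variant("chrT", pos, ref, alt),
                                           gene, genome)
        assert label == expected

    def test_outside_gene_span_errors(self, toy_two_exon):
        from splicecase.genome_io import CoordinateError

        genome, gene = toy_two_exon
        with pytest.raises(CoordinateError):
            classify_splice_variant(Variant("chrT", 50, genome.base(50), "A"),
                                    gene, genome)


def _acceptor(gene, genome, intron=1):
    return next(s for s in locate_splice_sites(gene, genome)
                if s.kind == "acceptor" and s.intron_index == intron)


class TestCrypticScan:
    def test_nearest_ag_rule_exon_starting_ag(self, toy_two_exon):
        genome, gene = toy_two_exon
        # exon2 begins CTT...; plant AG at exonic positions 1-2
        g = genome.with_variant(Variant("chrT", 190, "C", "A"))
        g = g.with_variant(Variant("chrT", 191, "T", "G"))
        var = Variant("chrT", 188, "A", "G")
        g = g.with_variant(var)
        call = scan_cryptic_acceptor(g, _acceptor(gene, genome), variant_pos=var.pos)
        assert call.found and call.deletion_length == 2
        assert call.distance_from_variant == 4

    def test_no_ag_within_scan_returns_not_found(self, toy_two_exon):
        genome, gene = toy_two_exon
        var = Variant("chrT", 188, "A", "G")
        g = genome.with_variant(var)
        # wild exon2 = (CTT)*19 TAA: its only AG... none at all
        call = scan_cryptic_acceptor(g, _acceptor(gene, genome),
                                     max_scan_nt=100, variant_pos=var.pos,
                                     exon_length=gene.exon_length(2))
        assert not call.found
        assert call.deletion_length is None

    def test_planted_offset_16_gives_16_and_18(self, nf1_case):
        g = nf1_case.genome.with_variant(nf1_case.variant)
        call = scan_cryptic_acceptor(g, _acceptor(nf1_case.gene, nf1_case.genome),
                                     variant_pos=nf1_case.variant.pos)
        assert call.deletion_length == 16
        assert call.distance_from_variant == 18

    def test_ag_spanning_intron_boundary_found_at_offset_one(self):
        # acceptor-1 G>A turns ...AG| into ...AA|; the canonical pair at
        # intron (-2,-1) is excluded, but the new AG formed by intron -1
        # plus exon position 1 is a valid cryptic acceptor of offset 1
        case = sd.make_splice_case(cryptic_offset=1, seed=11)
        g = case.genome.with_variant(case.variant)
        call = scan_cryptic_acceptor(g, _acceptor(case.gene, case.genome),
                                     variant_pos=case.variant.pos)
        assert call.deletion_length == 1

    def test_upstream_intronic_option_reports_retention_offset(self, toy_two_exon):
        genome, gene = toy_two_exon
        # plant an intronic AG 5 nt upstream of the canonical acceptor
        g = genome.with_variant(Variant("chrT", 183, "T", "A"))
        g = g.with_variant(Variant("chrT", 184, "T", "G"))
        var = Variant("chrT", 188, "A", "G")
        g = g.with_variant(var)
        call = scan_cryptic_acceptor(g, _acceptor(gene, genome),
                                     variant_pos=var.pos,
                                     include_upstream_intronic=True)
        assert call.upstream_intronic_offset == 4


class TestReconstruct:
    def test_none_reproduces_wild_type(self, nf1_case):
        mrna, cds = reconstruct_transcript(nf1_case.gene, nf1_case.genome, None)
        assert cds.startswith("ATG") and len(cds) % 3 == 0
        assert mrna == cds  # this model is CDS-only

    def test_length_conservation(self, nf1_case):
        res = splice_consequence_for_variant(nf1_case.genome, nf1_case.gene,
                                             nf1_case.variant)
        assert len(res["mutant_cds"]) == len(res["wild_cds"]) - 16

    def test_minus_strand_equals_revcomp_construction(self):
        plus = sd.make_splice_case(seed=21)
        minus = sd.make_splice_case(seed=21, strand="-")
        _, cds_p = reconstruct_transcript(plus.gene, plus.genome)
        _, cds_m = reconstruct_transcript(minus.gene, minus.genome)
        assert cds_p == cds_m
        res_p = splice_consequence_for_variant(plus.genome, plus.gene, plus.variant)
        res_m = splice_consequence_for_variant(minus.genome, minus.gene, minus.variant)
        assert res_p["mutant_cds"] == res_m["mutant_cds"]

    def test_deletion_consuming_exon_errors(self, toy_two_exon):
        from splicecase.splice_engine import CrypticAcceptorCall

        genome, gene = toy_two_exon
        call = CrypticAcceptorCall(found=True, intron_index=1,
                                   offset_exonic=60, deletion_length=60,
                                   distance_from_variant=62)
        with pytest.raises(ModelError):
            reconstruct_transcript(gene, genome, call)


class TestAnalyzeFrame:
    def test_in_frame_deletion(self):
        wild = "ATG" + "CTG" * 10 + "TAA"
        mutant = "ATG" + "CTG" * 5 + "TAA"  # 15 nt deleted
        q = analyze_frame(wild, mutant, (4, len(wild)))
        assert not q.is_frameshift
        assert q.frame_offset == 0
        assert q.novel_aa_count == 0
        assert q.deletion_length_nt == 15

    def test_frameshift_detection_mod_three(self, nf1_case):
        res = splice_consequence_for_variant(nf1_case.genome, nf1_case.gene,
                                             nf1_case.variant)
        q = res["consequence"]
        assert q.deletion_length_nt == 16
        assert q.frame_offset == 1
        assert q.is_frameshift

    def test_planted_17_novel_26_truncated(self, nf1_case):
        res = splice_consequence_for_variant(nf1_case.genome, nf1_case.gene,
                                             nf1_case.variant)
        q = res["consequence"]
        # brute-force codon-by-codon oracle on the mutant CDS
        mutant = res["mutant_cds"]
        stops = [i for i in range(0, len(mutant) - 2, 3)
                 if mutant[i:i + 3] in STOP_CODONS]
        first_stop_codon = stops[0] // 3 + 1
        assert q.ptc_cds_pos == stops[0] + 1
        assert q.novel_aa_count == first_stop_codon - 1 - 20 == 17
        assert q.wildtype_exon_aa_lost_after_ptc == 26
        assert len(q.peptide) == 37
        assert "*" not in q.peptide

    def test_missing_start_codon_rejected(self):
        with pytest.raises(ValueError):
            analyze_frame("CTGCTGTAA", "CTGTAA", (1, 9))

    def test_no_stop_flagged_peptide_to_end(self):
        wild = "ATG" + "CTG" * 4 + "TAA"
        mutant = wild[:-4] + wild[-3:]  # delete 1 nt: frameshift kills the stop
        q = analyze_frame(wild, mutant, (4, len(wild)))
        assert not q.has_stop
        assert q.ptc_cds_pos is None
        assert len(q.peptide) == len(mutant) // 3

    def test_stop_map_equals_naive_three_frame_scan(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            cds = "".join(rng.choice(list("ACGT"), size=int(rng.integers(9, 120))))
            got = stop_map(cds)
            for frame in range(3):
                naive = [i + 1 for i in range(frame, len(cds) - 2, 3)
                         if cds[i:i + 3] in STOP_CODONS]
                assert got[frame] == naive


class TestNmd:
    def _consequence(self, ptc_cds_pos):
        from splicecase.splice_engine import SpliceConsequence

        return SpliceConsequence(
            deletion_length_nt=1, frame_offset=1, is_frameshift=True,
            novel_aa_count=0, ptc_cds_pos=ptc_cds_pos,
            wildtype_exon_aa_lost_after_ptc=0, nmd_predicted=None,
            rule_detail="", peptide="", peptide_mass_kda=0.018)

    def _gene(self, exon_lengths):
        exons, pos = [], 100
        for L in exon_lengths:
            exons.append((pos, pos + L - 1))
            pos += L + 30
        return GeneModel("g", "t", "c", "+", tuple(exons),
                         exons[0][0], exons[-1][1])

    def test_ptc_in_early_exon_of_long_gene_is_positive(self):
        gene = self._gene([60, 150] + [30] * 10)
        positive, rule = predict_nmd(self._consequence(100), gene)
        assert positive and "junction" in rule

    def test_ptc_in_last_exon_negative(self):
        gene = self._gene([60, 60, 60])
        positive, _ = predict_nmd(self._consequence(140), gene)
        assert not positive

    def test_55nt_boundary_exact(self):
        # junction after exon1+exon2 = 120; PTC at tx position p:
        # distance = 120 - p; rule fires iff distance >= 55
        gene = self._gene([60, 60, 200])
        at_boundary, _ = predict_nmd(self._consequence(120 - 55), gene)
        inside, _ = predict_nmd(self._consequence(120 - 54), gene)
        assert at_boundary
        assert not inside

    def test_ptc_10nt_upstream_of_final_junction_negative(self):
        gene = self._gene([60, 60, 200])
        positive, _ = predict_nmd(self._consequence(110), gene)
        assert not positive

    def test_single_intron_last_exon_ptc_reports_rule(self):
        gene = self._gene([60, 300])
        positive, _ = predict_nmd(self._consequence(100), gene)
        assert not positive  # PTC downstream of the only junction


class TestPeptideMass:
    def test_empty_peptide_is_one_water(self):
        assert peptide_mass("") == pytest.approx(0.0180, abs=1e-4)

    def test_glycine(self):
        assert peptide_mass("G") == pytest.approx(0.07507, abs=1e-4)

    def test_matches_biopython_average_masses(self):
        from Bio.SeqUtils import molecular_weight

        rng = np.random.default_rng(5)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            pep = "".join(rng.choice(letters, size=37))
            expected = molecular_weight(pep, seq_type="protein") / 1000.0
            assert peptide_mass(pep) == pytest.approx(expected, abs=1e-3)

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError):
            peptide_mass("GXZ")
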