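"""Nuclease catalog, PAM scanning, bystander hazards and prime design."""

import numpy as np
import pytest

from splicecase import synthetic_data as sd
from splicecase.editing_feasibility import (
    CHEMISTRY,
    IUPAC,
    CatalogError,
    NucleaseSpec,
    catalog_hash,
    classify_bystanders,
    design_prime_edit,
    iter_motif_matches,
    load_nuclease_catalog,
    rank_strategies,
    read_pathogenic_table,
    scan_editor_sites,
    write_nuclease_catalog,
)
from splicecase.genome_io import GenomeSequence, Variant, complement_base, revcomp


class TestCatalog:
    def test_default_catalog_loads_at_least_three_specs(self, catalog):
        assert len(catalog) >= 3
        names = {s.name for s in catalog}
        assert {"Cas12a-CBE", "SpCas9-ABE", "SpCas9-CBE"} <= names
        cas12a = next(s for s in catalog if s.name == "Cas12a-CBE")
        assert cas12a.motif == "TTTV" and cas12a.window == (8, 14)

    def test_inverted_window_rejected(self):
        with pytest.raises(CatalogError):
            NucleaseSpec("bad", "NGG", "3prime_of_protospacer", 20, (9, 8), "CBE")

    @pytest.mark.parametrize("field,value", [
        ("motif", "TTQV"), ("motif_side", "left"), ("chemistry", "XYZ"),
    ])
    def test_schema_violations_rejected(self, field, value):
        kwargs = dict(name="x", motif="NGG", motif_side="3prime_of_protospacer",
                      spacer_length=20, window=(4, 8), chemistry="CBE")
        kwargs[field] = value
        with pytest.raises(CatalogError):
            NucleaseSpec(**kwargs)

    @pytest.mark.parametrize("ext", ["json", "yaml"])
    def test_round_trip_identity(self, catalog, tmp_path, ext):
        p = tmp_path / f"cat.{ext}"
        write_nuclease_catalog(catalog, str(p))
        again = load_nuclease_catalog(str(p))
        assert again == catalog
        assert catalog_hash(again) == catalog_hash(catalog)


def brute_force_motif_hits(seq, motif):
    """Oracle: expand the IUPAC motif into concrete k-mers and string-search."""
    from itertools import product

    kmers = {"".join(c) for c in product(*[IUPAC[ch] for ch in motif])}
    return sorted(i for i in range(len(seq) - len(motif) + 1)
                  if seq[i:i + len(motif)] in kmers)


class TestMotifScan:
    @pytest.mark.parametrize("motif", ["TTTV", "NGG", "BAAA", "YRN"])
    def test_matches_expansion_oracle(self, motif):
        rng = np.random.default_rng(77)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            assert sorted(iter_motif_matches(seq, motif)) == \
                brute_force_motif_hits(seq, motif)

    def test_scan_symmetry_under_revcomp(self, catalog):
        # scanning S equals scanning revcomp(S) with strands swapped and
        # coordinates mirrored
        rng = np.random.default_rng(42)
        for trial in range(25):
            seq = "".join(rng.choice(list("ACGT"), size=61))
            pos = 31
            ref = seq[pos - 1]
            alt = "G" if ref != "G" else "A"
            g = GenomeSequence("c", seq)
            var = Variant("c", pos, ref, alt)
            L = len(seq)
            g2 = GenomeSequence("c", revcomp(seq))
            var2 = Variant("c", L - pos + 1, complement_base(ref),
                           complement_base(alt))
            fwd = scan_editor_sites(g, var, catalog)
            rev = scan_editor_sites(g2, var2, catalog)
            key = lambda c, L=None: (c.nuclease,
                                     c.strand if L is None
                                     else ("+" if c.strand == "-" else "-"),
                                     c.target_distance_to_pam,
                                     len(c.bystanders))
            assert sorted(key(c) for c in fwd) == \
                sorted(key(c, L) for c in rev), trial


class TestScanEditorSites:
    def test_single_cas12a_site_nine_bases_downstream(self, nf1_case, catalog):
        cands = scan_editor_sites(nf1_case.genome, nf1_case.variant, catalog)
        cas12a = [c for c in cands if c.nuclease == "Cas12a-CBE"]
        assert len(cas12a) == 1
        c = cas12a[0]
        assert c.strand == "-"
        assert c.pam_plus_strand == "TAAA"  # BAAA on the displayed strand
        assert c.target_distance_to_pam == 9
        assert c.target_window_position == 9
        assert [b.pos for b in c.bystanders] == [31155982]
        assert c.bystanders[0].substitution == "G>A"

    def test_window_of_all_a_has_no_ngg_placements(self, catalog):
        g = GenomeSequence("c", "A" * 61)
        var = Variant("c", 31, "G", "A")  # correction A>G: ABE on plus
        cands = scan_editor_sites(g, var, catalog)
        assert [c for c in cands if "SpCas9" in c.nuclease] == []

    def test_planted_cases_recover_exact_truth(self):
        catalog = load_nuclease_catalog()
        for seed in range(25):
            n_b = seed % 4
            case = sd.make_editing_case(pam_offset=8 + seed % 7,
                                        n_bystanders=n_b,
                                        hazardous=bool(seed % 2), seed=seed)
            cands = scan_editor_sites(case.genome, case.target, catalog)
            counts = {n: sum(c.nuclease == n for c in cands)
                      for n in case.truth["n_candidates_per_nuclease"]}
            assert counts == case.truth["n_candidates_per_nuclease"]
            cas12a = next(c for c in cands if c.nuclease == "Cas12a-CBE")
            assert sorted(b.pos for b in cas12a.bystanders) == \
                case.truth["bystander_positions"]
            assert cas12a.target_distance_to_pam == case.truth["pam_distance_nt"]

    def test_bystander_edits_never_touch_target(self, catalog):
        rng = np.random.default_rng(55)
        for seed in range(20):
            case = sd.make_editing_case(n_bystanders=int(rng.integers(0, 7)),
                                        seed=seed)
            for c in scan_editor_sites(case.genome, case.target, catalog):
                for b in c.bystanders:
                    assert b.pos != case.target.pos
                    ref, alt = b.substitution.split(">")
                    assert case.genome.base(b.pos) == ref and ref != alt


class TestClassifyBystanders:
    def test_pathogenic_match_makes_hazardous(self, nf1_case, catalog):
        cands = scan_editor_sites(nf1_case.genome, nf1_case.variant, catalog)
        cas12a = next(c for c in cands if c.nuclease == "Cas12a-CBE")
        annotated, verdict = classify_bystanders(
            cas12a.bystanders, nf1_case.pathogenic_table, "chr17")
        assert verdict == "hazardous"
        assert annotated[0].classification == "pathogenic"
        assert annotated[0].matched_id == "rs1263745475"

    def test_empty_bystanders_clean(self):
        annotated, verdict = classify_bystanders([], None, "c")
        assert annotated == [] and verdict == "clean"

    def test_unannotated_bystander_stays_clean(self, nf1_case, catalog):
        cands = scan_editor_sites(nf1_case.genome, nf1_case.variant, catalog)
        cas12a = next(c for c in cands if c.nuclease == "Cas12a-CBE")
        annotated, verdict = classify_bystanders(cas12a.bystanders, None, "chr17")
        assert verdict == "clean"
        assert annotated[0].classification == "unannotated"

    def test_malformed_table_row_named(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("contig\tpos\tref\talt\tid\tsignificance\n"
                     "chr1\t5\tAT\tG\trs1\tPathogenic\n")
        with pytest.raises(ValueError, match="row 2"):
            read_pathogenic_table(str(p))


class TestPrimeDesign:
    def test_hand_constructed_nick_distance_and_rtt(self):
        # one NGG on plus strand placing the nick 5 nt from the target:
        # PAM at p = t - 2 means nick_to_edit = t - (p - 20 + 17) = 5
        t = 40
        seq = ["T"] * 80
        seq[t - 1] = "G"          # target alt base
        seq[t - 2] = "G"          # second G of the PAM "NGG" at p = t - 2
        g = GenomeSequence("c", "".join(seq))
        var = Variant("c", t, "A", "G")
        cands = design_prime_edit(g, var)
        assert len(cands) == 1
        c = cands[0]
        assert (c.strand, c.nick_to_edit_nt) == ("+", 5)
        assert c.rtt_length == 5 + 1 + 10
        assert c.pbs_length == 13
        assert len(c.spacer) == 20

    def test_no_g_context_yields_nothing(self):
        g = GenomeSequence("c", "AT" * 40)
        cands = design_prime_edit(g, Variant("c", 40, "T", "A"))
        assert cands == []

    def test_count_equals_brute_force_ngg_scan(self):
        rng = np.random.default_rng(88)
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), size=90))
            t = 45
            var = Variant("c", t, "A" if seq[t - 1] != "A" else "C", seq[t - 1])
            g = GenomeSequence("c", seq)
            got = design_prime_edit(g, var)
            # oracle: enumerate NGG PAMs on both strands with the distance rule
            expected = 0
            for i in range(len(seq) - 2):
                p = i + 1
                if seq[i + 1] == "G" and seq[i + 2] == "G" and p - 20 >= 1:
                    if 0 <= t - (p - 3) <= 30:
                        expected += 1
                if seq[i] == "C" and seq[i + 1] == "C" and p + 22 <= len(seq):
                    if 0 <= (p + 5) - t <= 30:
                        expected += 1
            assert len(got) == expected

    def test_sorted_by_nick_distance(self, nf1_case):
        cands = design_prime_edit(nf1_case.genome, nf1_case.variant)
        dists = [c.nick_to_edit_nt for c in cands]
        assert dists == sorted(dists)


class TestRankStrategies:
    def test_hazardous_base_demoted_below_prime(self, nf1_case, catalog):
        cands = scan_editor_sites(nf1_case.genome, nf1_case.variant, catalog)
        pairs = [(c, classify_bystanders(c.bystanders,
                                         nf1_case.pathogenic_table,
                                         "chr17")[1]) for c in cands]
        primes = design_prime_edit(nf1_case.genome, nf1_case.variant)
        report = rank_strategies(pairs, primes)
        assert report["strategies"][0]["type"] == "prime_editing"
        types = [s["type"] for s in report["strategies"]]
        assert types[-1] == "base_editing"  # the demoted hazardous candidate

    def test_clean_base_first_without_prime(self):
        case = sd.make_editing_case(n_bystanders=0, hazardous=False, seed=6)
        cands = scan_editor_sites(case.genome, case.target,
                                  load_nuclease_catalog())
        pairs = [(c, "clean") for c in cands]
        report = rank_strategies(pairs, [])
        assert report["strategies"][0]["type"] == "base_editing"

    def test_empty_inputs_report_no_strategy(self):
        assert rank_strategies([], [])["summary"] == "no in-silico strategy"
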