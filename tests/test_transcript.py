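"""Gene models, HGVS coordinates, splice-outcome building and consequences."""

import pytest

from splicecall import (
    CVariant,
    CVariantPosition,
    GeneModel,
    enumerate_splice_patterns,
    translate_and_call,
)
from splicecall.cryptic import CrypticCandidate
from splicecall.transcript import GeneModelError, SpliceOutcome

from conftest import oracle_translate


@pytest.fixture(scope="module")
def model():
    """Tiny two-exon model: 6 nt 5'UTR, 12+15 nt CDS split across the exons."""
    exon1 = "TTTTTT" + "ATGGCTGCTAAG"        # UTR + M A A K
    intron = "GTAAGT" + "C" * 20 + "AG"
    exon2 = "GAAGCTGCTGCTTAA" + "TTTT"       # E A A A * + UTR
    seq = exon1 + intron + exon2
    return GeneModel(
        sequence=seq,
        exons=[(1, len(exon1)), (len(exon1) + len(intron) + 1, len(seq))],
        cds_start=7,
        cds_end=7 + 27 - 1,
    )


class TestHgvsParsing:
    @pytest.mark.parametrize(
        "text, cds_base, offset",
        [("c.1", 1, 0), ("c.28+5", 28, 5), ("c.29-3", 29, -3), ("106", 106, 0)],
    )
    def test_position_parse_and_render(self, text, cds_base, offset):
        pos = CVariantPosition.parse(text)
        assert (pos.cds_base, pos.intron_offset) == (cds_base, offset)
        if text.startswith("c."):
            assert str(pos) == text

    @pytest.mark.parametrize(
        "text, kind, ref, alt",
        [
            ("c.28+5G>A", "sub", "G", "A"),
            ("c.261delG", "del", "G", ""),
            ("c.1061delC", "del", "C", ""),
            ("c.10insAT", "ins", "", "AT"),
        ],
    )
    def test_variant_parse(self, text, kind, ref, alt):
        var = CVariant.parse(text)
        assert (var.kind, var.ref, var.alt) == (kind, ref, alt)

    def test_unparseable_rejected(self):
        with pytest.raises(ValueError):
            CVariant.parse("g.123A>T")


class TestCoordinateMap:
    def test_c1_is_first_cds_base(self, model):
        g = model.c_to_genomic(CVariantPosition(1))
        assert model.sequence[g - 1:g + 2] == "ATG"

    def test_plus_offset_enters_the_intron(self, model):
        # exon 1 carries 12 coding bases, so c.12+1 is the intron's first base
        g = model.c_to_genomic(CVariantPosition.parse("c.12+1"))
        assert g == model.intron_interval(1)[0]
        assert model.sequence[g - 1] == "G"

    def test_minus_offset_enters_from_the_right(self, model):
        g = model.c_to_genomic(CVariantPosition.parse("c.13-1"))
        assert g == model.intron_interval(1)[1]
        assert model.sequence[g - 1] == "G"  # ...AG acceptor

    def test_offset_beyond_intron_is_an_error(self, model):
        with pytest.raises(GeneModelError, match="exceeds intron length"):
            model.c_to_genomic(CVariantPosition.parse("c.12+999"))

    def test_offset_from_internal_base_is_an_error(self, model):
        with pytest.raises(GeneModelError, match="last base"):
            model.c_to_genomic(CVariantPosition.parse("c.5+1"))

    def test_round_trip_over_the_whole_locus(self, abo_fixture):
        model = abo_fixture.model
        cds_len = model.cds_end - model.cds_start + 1
        probes = [CVariantPosition(b) for b in range(1, cds_len + 1, 13)]
        probes += [
            CVariantPosition(28, off) for off in (1, 5, 100, 167, 500)
        ]
        probes += [CVariantPosition(29, -off) for off in (1, 10, 400)]
        for pos in probes:
            g = model.c_to_genomic(pos)
            assert model.genomic_to_c(g) == pos

    def test_reference_mismatch_detected_on_substitution(self, model):
        g = model.c_to_genomic(CVariantPosition(1))
        with pytest.raises(GeneModelError, match="reference mismatch"):
            model.with_substitution(g, "C", "T")


class TestGeneModelValidation:
    def test_cds_not_multiple_of_three_rejected(self):
        with pytest.raises(GeneModelError, match="multiple of 3"):
            GeneModel(sequence="ATGAAATTT", exons=[(1, 9)], cds_start=1, cds_end=5)

    def test_overlapping_exons_rejected(self):
        with pytest.raises(GeneModelError):
            GeneModel(
                sequence="A" * 30, exons=[(1, 10), (5, 20)], cds_start=1, cds_end=3
            )

    def test_canonical_splice_flags(self, model):
        assert model.canonical_splice_flags() == [True]


class TestEnumerateSplicePatterns:
    def test_three_outcomes_with_a_cryptic_candidate(self, model):
        cryptic = CrypticCandidate(9, "AAGGTAAGT", sd=-2.0, ri=8.0)
        outcomes = enumerate_splice_patterns(model, 1, cryptic)
        assert [o.pattern for o in outcomes] == [
            "retention_to_cryptic", "normal", "exon_skip"
        ]

    def test_two_outcomes_without_cryptic(self, model):
        outcomes = enumerate_splice_patterns(model, 1, None)
        assert [o.pattern for o in outcomes] == ["normal", "exon_skip"]

    def test_normal_mrna_is_exact_exon_concatenation(self, model):
        normal = next(
            o for o in enumerate_splice_patterns(model, 1, None)
            if o.pattern == "normal"
        )
        assert normal.mrna == model.exon_seq(1) + model.exon_seq(2)

    @pytest.mark.parametrize("offset", [3, 9, 14, 20])
    def test_retention_length_arithmetic(self, model, offset):
        cryptic = CrypticCandidate(offset, "AAGGTAAGT", sd=-2.0, ri=8.0)
        outcomes = enumerate_splice_patterns(model, 1, cryptic)
        retention, normal = outcomes[0], outcomes[1]
        assert len(retention.mrna) - len(normal.mrna) == offset
        assert retention.retained_length == offset
        # the retained bases are the intron's first ``offset`` bases
        e1 = len(model.exon_seq(1))
        assert retention.mrna[e1:e1 + offset] == model.intron_seq(1)[:offset]

    def test_exon_skip_length_arithmetic(self, model):
        skip = enumerate_splice_patterns(model, 1, None)[-1]
        assert len(skip.mrna) == len(model.transcript_seq()) - len(model.exon_seq(1))
        assert skip.skipped_exon == 1

    def test_skipping_the_start_exon_is_flagged(self, model):
        skip = enumerate_splice_patterns(model, 1, None)[-1]
        assert skip.non_coding_start and skip.cds_start is None

    def test_invalid_intron_index(self, model):
        with pytest.raises(GeneModelError):
            enumerate_splice_patterns(model, 2, None)


class TestTranslateAndCall:
    def test_identical_protein_is_no_change(self, model):
        normal = enumerate_splice_patterns(model, 1, None)[0]
        cons = translate_and_call(normal, model.protein())
        assert cons.kind == "no_change" and cons.hgvs_p == "p.(=)"

    def test_fixture_retention_matches_manual_codon_walk(self, abo_fixture):
        """The surrogate's 167 bp retention yields p.Lys11Glufs*66, checked
        against an independent codon-walk over a manually assembled mRNA."""
        model = abo_fixture.model
        gpos = model.c_to_genomic(CVariantPosition.parse("c.28+5"))
        mut = model.with_substitution(gpos, "G", "A")
        cryptic = CrypticCandidate(167, "AAGGTAAGT", sd=-1.7, ri=10.0)
        retention = enumerate_splice_patterns(mut, 1, cryptic)[0]
        cons = translate_and_call(retention, model.protein())
        # ---- independent oracle: hand-assembled mutant mRNA, own codon table
        manual_mrna = (
            mut.exon_seq(1) + mut.intron_seq(1)[:167] + mut.exon_seq(2)
        )
        manual_cds = manual_mrna[mut.cds_start - 1:]
        mut_protein, stop_found = oracle_translate(manual_cds)
        wt_protein, _ = oracle_translate(model.cds_seq())
        assert stop_found
        first_diff = next(
            i for i, (a, b) in enumerate(zip(mut_protein, wt_protein)) if a != b
        )
        oracle_stop_offset = len(mut_protein) - first_diff + 1
        # ---- the implementation agrees with the oracle
        assert retention.protein == mut_protein
        assert cons.first_changed_codon == first_diff + 1 == 11
        assert cons.stop_offset == oracle_stop_offset == 66
        assert cons.hgvs_p == "p.Lys11Glufs*66"
        assert cons.kind == "frameshift"

    def test_one_base_insertion_frameshift_matches_manual_walk(self):
        """A 1 bp insertion mid-CDS: frameshift parameters equal a manual
        codon walk of the shifted message."""
        wt_cds = "ATG" + "GCTAAGGAAGCT" + "TGTTGA"  # M A K E A C *
        mut_cds = wt_cds[:6] + "C" + wt_cds[6:]     # +C after codon 2
        wt_protein, _ = oracle_translate(wt_cds)
        outcome = SpliceOutcome(pattern="retention_to_cryptic",
                                mrna=mut_cds, cds_start=1, retained_length=1)
        cons = translate_and_call(outcome, wt_protein)
        mut_protein, stop_found = oracle_translate(mut_cds)
        assert outcome.protein == mut_protein
        first_diff = next(
            i for i, (a, b) in enumerate(zip(mut_protein, wt_protein)) if a != b
        )
        assert cons.kind == "frameshift"
        assert cons.first_changed_codon == first_diff + 1
        if stop_found:
            assert cons.stop_offset == len(mut_protein) - first_diff + 1

    def test_unresolved_stop_is_flagged(self):
        outcome = SpliceOutcome(pattern="retention_to_cryptic",
                                mrna="ATGGCTAAGGCTGC", cds_start=1, retained_length=2)
        cons = translate_and_call(outcome, "MAK")
        assert cons.kind == "frameshift"
        assert cons.stop_offset is None
        assert cons.hgvs_p.endswith("fs*?")

    def test_nonsense_when_protein_truncates_in_frame(self):
        outcome = SpliceOutcome(pattern="normal", mrna="ATGGCTTAAGAAGCT", cds_start=1)
        cons = translate_and_call(outcome, "MAEA")
        assert cons.kind == "nonsense"
        assert cons.first_changed_codon == 3
        assert cons.hgvs_p == "p.Glu3Ter"

    def test_missense_single_substitution(self):
        outcome = SpliceOutcome(pattern="normal", mrna="ATGGATAAGTAA", cds_start=1)
        cons = translate_and_call(outcome, "MAK")
        assert cons.kind == "missense"
        assert cons.hgvs_p == "p.Ala2Asp"

    @pytest.mark.parametrize("offset", [1, 2, 4, 5, 7, 8, 10, 167])
    def test_non_triplet_retention_never_missense(self, abo_fixture, offset):
        """Retained lengths not divisible by 3 shift the frame: the call is
        frameshift or nonsense, never missense/synonymous."""
        model = abo_fixture.model
        cryptic = CrypticCandidate(offset, "AAGGTAAGT", sd=-1.7, ri=10.0)
        retention = enumerate_splice_patterns(model, 1, cryptic)[0]
        cons = translate_and_call(retention, model.protein())
        assert offset % 3 != 0
        assert cons.kind in ("frameshift", "nonsense")

    def test_hgvs_stop_offset_arithmetic(self, abo_fixture):
        """mutant length + 2 − first changed codon == stop offset."""
        model = abo_fixture.model
        cryptic = CrypticCandidate(167, "AAGGTAAGT", sd=-1.7, ri=10.0)
        retention = enumerate_splice_patterns(model, 1, cryptic)[0]
        cons = translate_and_call(retention, model.protein())
        assert (
            len(cons.mutant_protein) + 2 - cons.first_changed_codon
            == cons.stop_offset
        )
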