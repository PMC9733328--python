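"""Generators: determinism, planted truth, and closure with the analysis stages."""

import numpy as np
import pytest

from polyframe.cds_inference import FIRST_AUG, cds_report, find_orf, splice_transcript
from polyframe.duplication_decomposition import self_alignment_blocks
from polyframe.ltr_profile import motif_cooccurrence
from polyframe.repeat_frames import aa_composition, translate_cds
from polyframe.synthetic_data import (
    MotifPlan,
    gen_ltr_family,
    gen_planted_duplication,
    gen_repeat_cds,
    gen_transcript_locus,
)


class TestDeterminism:
    def test_ltr_family_regenerates_byte_identical(self):
        plan = MotifPlan(window_a_start=5, window_b_start=8)
        a = gen_ltr_family(100, 40, 0.1, 0.01, plan, seed=6)
        b = gen_ltr_family(100, 40, 0.1, 0.01, plan, seed=6)
        assert a.alignment == b.alignment
        assert a.copy_classes.equals(b.copy_classes)

    def test_repeat_cds_regenerates_byte_identical(self):
        a = gen_repeat_cds(50, 0.15, "polyS", [(30, 30)], seed=8)
        b = gen_repeat_cds(50, 0.15, "polyS", [(30, 30)], seed=8)
        assert a.cds == b.cds and a.erosions == b.erosions

    def test_transcript_locus_regenerates_byte_identical(self):
        a = gen_transcript_locus(3, [40, 50], seed=21)
        b = gen_transcript_locus(3, [40, 50], seed=21)
        assert a.genome == b.genome and a.exon_model == b.exon_model

    def test_different_seeds_differ(self):
        assert gen_planted_duplication(200, 30, seed=0).seq != \
            gen_planted_duplication(200, 30, seed=1).seq


class TestLtrFamily:
    def test_zero_rates_zero_indels_copies_equal_consensus(self):
        b = gen_ltr_family(80, 10, 0.0, 0.0, seed=3)
        assert all(c == b.alignment.consensus for c in b.alignment.copies)

    def test_exact_fraction_census_closure(self):
        plan = MotifPlan(window_a_start=10, window_b_start=13)
        b = gen_ltr_family(150, 100, 0.1, motif_plan=plan, seed=5)
        cc = motif_cooccurrence(b.alignment, ("ATG", 10), ("ATG", 13))
        assert (cc.a_only, cc.b_only, cc.both) == (0.14, 0.29, 0.15)
        assert cc.at_least_one == pytest.approx(0.58)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            MotifPlan(window_a_start=0, window_b_start=3,
                      f_a_only=0.6, f_b_only=0.5, f_both=0.2)

    def test_sampled_mode_roughly_matches_fractions(self):
        plan = MotifPlan(window_a_start=10, window_b_start=13)
        b = gen_ltr_family(60, 400, 0.05, motif_plan=plan, seed=14,
                           exact_fractions=False)
        counts = b.copy_classes.carrier_class.value_counts(normalize=True)
        assert abs(counts.get("a_only", 0) - 0.14) < 0.06
        assert abs(counts.get("b_only", 0) - 0.29) < 0.07


class TestRepeatCds:
    def test_zero_erosion_translates_to_pure_homopolymer(self):
        for frame, aa in [("polyS", "S"), ("polyQ", "Q"), ("polyA", "A")]:
            b = gen_repeat_cds(30, 0.0, frame, seed=1)
            prot = translate_cds(b.cds)
            assert prot == "M" + aa * 30 + "*"

    def test_eroded_serine_cds_stays_open_with_lower_serine_fraction(self):
        b = gen_repeat_cds(100, 0.1, "polyS", seed=12)
        prot = translate_cds(b.cds)
        assert "*" not in prot[:-1] and prot[-1] == "*"
        assert 0.5 < aa_composition(prot).serine < 1.0
        assert len(b.erosions) > 0

    def test_eroded_polyq_cds_avoids_stops_by_rejection(self):
        b = gen_repeat_cds(100, 0.3, "polyQ", seed=13)
        assert "*" not in translate_cds(b.cds)[:-1]

    def test_planted_duplication_recovered_downstream(self):
        # In quasi-periodic sequence a tandem duplication's breakpoints are only
        # defined up to the repeat period, so recovery is asserted on the
        # diagonal (copy distance) and the overlap with the source segment.
        b = gen_repeat_cds(40, 0.25, "polyS", [(30, 60)], seed=4)
        blocks = self_alignment_blocks(b.cds, min_len=24, min_identity=0.9,
                                       mask_unit="AGC")
        truth = b.duplications[0]
        assert any(
            x.diagonal == truth["length"]
            and x.length >= truth["length"] - 6
            and x.a_start < truth["src_end"]
            and x.a_end > truth["src_start"]
            for x in blocks
        ), "planted duplication not recovered"

    def test_misaligned_duplication_rejected(self):
        with pytest.raises(ValueError):
            gen_repeat_cds(20, 0.0, "polyS", [(1, 30)], seed=0)


class TestTranscriptLocus:
    def test_canonical_splice_flags_all_true(self):
        b = gen_transcript_locus(3, [30, 44], canonical_splice=True, seed=2)
        tx = splice_transcript(b.genome, b.exon_model)
        assert tx.splice_flags == (True, True)
        assert tx.residues == b.transcript

    def test_noncanonical_splice_flags_all_false(self):
        b = gen_transcript_locus(2, [30], canonical_splice=False, seed=2)
        tx = splice_transcript(b.genome, b.exon_model)
        assert tx.splice_flags == (False,)

    def test_planted_tandem_start_found_by_first_aug(self):
        b = gen_transcript_locus(2, [30], seed=19)
        orf = find_orf(b.transcript, FIRST_AUG)
        assert orf.start == b.orf_start == 0
        assert b.transcript.startswith("ATGATG")

    def test_single_exon_transcript_equals_gene_body(self):
        b = gen_transcript_locus(1, [], seed=7)
        assert b.genome.residues == b.transcript

    def test_minus_strand_locus_round_trips(self):
        b = gen_transcript_locus(2, [40], seed=23, strand="-")
        tx = splice_transcript(b.genome, b.exon_model)
        assert tx.residues == b.transcript
        assert tx.splice_flags == (True,)

    def test_truth_orf_matches_inference(self):
        for seed in range(5):
            b = gen_transcript_locus(2, [30], seed=seed)
            orf = find_orf(b.transcript, FIRST_AUG)
            assert orf.start == b.orf_start
            assert orf.stop == b.orf_end

    def test_pipeline_closure_cds_report(self):
        b = gen_transcript_locus(2, [30], seed=31)
        tx = splice_transcript(b.genome, b.exon_model)
        rep = cds_report(tx, FIRST_AUG)
        assert rep.orf.start == b.orf_start
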