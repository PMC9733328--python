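"""Tract detection, frame classification and per-register stop counting."""

import numpy as np
import pytest

from polyframe.codon_space import STANDARD_CODE, STOP
from polyframe.repeat_frames import (
    aa_composition,
    canonical_unit,
    classify_codon_frames,
    find_repeat_tracts,
    register_frame_labels,
    repeat_frame_report,
    translate_cds,
)


class TestTracts:
    def test_pure_tract(self):
        (t,) = find_repeat_tracts("CAGCAGCAGCAG", "CAG", 3, 0.0)
        assert (t.start, t.end, t.n_units, t.purity) == (0, 12, 4, 1.0)
        assert t.unit == canonical_unit("CAG") == "AGC"

    def test_eroded_tract_spans_internal_mismatch(self):
        (t,) = find_repeat_tracts("CAGCAGTAGCAGCAG", "CAG", 3, 0.2)
        assert (t.start, t.end) == (0, 15)
        assert t.purity == pytest.approx(4 / 5)

    def test_no_tract_in_unrelated_sequence(self):
        assert find_repeat_tracts("ACGTACGTACGT", "CAG", 3, 0.0) == []

    def test_tract_found_at_any_phase_and_position(self):
        seq = "TTTT" + "AGC" * 5 + "GGGG"
        (t,) = find_repeat_tracts(seq, "CAG", 3, 0.0)
        assert (t.start, t.end, t.phase) == (4, 19, 0)

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            find_repeat_tracts("CAGCAX", "CAG", 2, 0.0)

    def test_reported_tracts_never_overlap(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=120)) + "CAG" * 8
            tracts = find_repeat_tracts(seq, "CAG", 2, 0.1)
            for a, b in zip(tracts, tracts[1:]):
                assert a.end <= b.start

    def test_planted_eroded_tract_recovered_within_one_unit(self, rng):
        """Erosion <= 0.2 per unit must not displace boundaries by more than one unit."""
        n_units, hits = 20, 0
        for rep in range(200):
            codons = ["CAG"] * n_units
            for i in range(n_units):
                if rng.random() < 0.2 and 1 <= i < n_units - 1:
                    pos = int(rng.integers(3))
                    alts = [b for b in "ACGT" if b != "CAG"[pos]]
                    codons[i] = "CAG"[:pos] + alts[int(rng.integers(3))] + "CAG"[pos + 1 :]
            left = "".join(rng.choice(list("TG"), size=30))
            seq = left + "".join(codons) + "".join(rng.choice(list("TC"), size=30))
            tracts = find_repeat_tracts(seq, "CAG", 3, 0.25)
            best = max(tracts, key=lambda t: t.end - t.start, default=None)
            if best and abs(best.start - 30) <= 3 and abs(best.end - (30 + 3 * n_units)) <= 3:
                hits += 1
        assert hits >= 190


class TestFrameClassification:
    def test_pure_serine_frame(self):
        seg = classify_codon_frames("AGCAGCAGC")
        assert seg.codon_labels == ("polyS",) * 3
        assert seg.n_switches == 0

    def test_frameshift_between_serine_and_alanine_runs(self):
        seg = classify_codon_frames("AGCAGCGCAGCA")
        assert seg.codon_labels == ("polyS", "polyS", "polyA", "polyA")
        assert seg.runs == ((0, 2, "polyS"), (2, 4, "polyA"))
        assert seg.n_switches == 1

    def test_non_repeat_codons_are_other(self):
        seg = classify_codon_frames("ATGGATTTT")
        assert seg.codon_labels == ("other",) * 3
        assert seg.n_switches == 0

    def test_n_codons_are_undetermined(self):
        seg = classify_codon_frames("CAGCNGCAG")
        assert seg.codon_labels == ("polyQ", "undetermined", "polyQ")

    def test_single_mutation_erosion_keeps_frame_label(self):
        # one point mutation per codon is within the Hamming <= 1 rule
        seg = classify_codon_frames("AGTAGCACC")
        assert seg.codon_labels == ("polyS", "polyS", "polyS")

    def test_trailing_partial_codon_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            seg = classify_codon_frames("AGCAGCAG")
        assert len(seg.codon_labels) == 2

    def test_runs_partition_codons(self, rng):
        for _ in range(20):
            cds = "".join(rng.choice(list("ACGT"), size=90))
            seg = classify_codon_frames(cds)
            assert seg.runs[0][0] == 0 and seg.runs[-1][1] == 30
            for a, b in zip(seg.runs, seg.runs[1:]):
                assert a[1] == b[0] and a[2] != b[2]

    def test_invariant_to_flanks_outside_classified_codons(self):
        core = "AGCAGCAGC"
        assert (
            classify_codon_frames(core).codon_labels
            == classify_codon_frames(core + "TTTTTT").codon_labels[:3]
        )


class TestComposition:
    def test_pure_serine(self):
        assert aa_composition("SSSS").fractions == {"S": 1.0}
        assert aa_composition(translate_cds("AGC" * 10)).serine == 1.0

    def test_equal_mix(self):
        comp = aa_composition("SQAD")
        assert comp.fractions == {"A": 0.25, "D": 0.25, "Q": 0.25, "S": 0.25}

    def test_fractions_sum_to_one_ignoring_stops(self, rng):
        prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY*"), size=200))
        comp = aa_composition(prot)
        assert sum(comp.fractions.values()) == pytest.approx(1.0)

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            aa_composition("")


class TestReport:
    def test_pure_repeat_has_no_stops_in_any_register(self):
        rep = repeat_frame_report("CAG" * 20)
        assert rep.stops_per_register == {0: 0, 1: 0, 2: 0}
        assert rep.frame_labels == {0: "polyQ", 1: "polyS", 2: "polyA"}

    def test_planted_tag_is_a_stop_only_in_the_q_register(self):
        rep = repeat_frame_report("CAG" * 5 + "TAG" + "CAG" * 5)
        assert rep.stops_per_frame == {"polyQ": 1, "polyS": 0, "polyA": 0}

    def test_register_stop_counts_match_translation_oracle(self, rng):
        for _ in range(10):
            cds = "".join(rng.choice(list("ACGT"), size=300))
            rep = repeat_frame_report(cds)
            for r in range(3):
                body = cds[r:]
                body = body[: len(body) - len(body) % 3]
                oracle = sum(
                    STANDARD_CODE.translate(body[i : i + 3]) == STOP
                    for i in range(0, len(body), 3)
                )
                assert rep.stops_per_register[r] == oracle

    def test_single_mutations_of_pure_repeat_only_hit_the_q_frame(self):
        """Exhaustive single-point mutants of (CAG)10: stop counts can rise only
        in the polyQ register, and only via C->T at codon position 1."""
        base = "CAG" * 10
        stop_makers = []
        for p in range(len(base)):
            for b in "ACGT":
                if b == base[p]:
                    continue
                mutant = base[:p] + b + base[p + 1 :]
                rep = repeat_frame_report(mutant)
                assert rep.stops_per_register[1] == 0
                assert rep.stops_per_register[2] == 0
                if rep.stops_per_register[0] > 0:
                    assert rep.stops_per_register[0] == 1
                    stop_makers.append((p, base[p], b))
        assert stop_makers == [(3 * i, "C", "T") for i in range(10)]

    def test_register_labels_from_any_starting_phase(self):
        assert register_frame_labels("AGC" * 10) == {0: "polyS", 1: "polyA", 2: "polyQ"}
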