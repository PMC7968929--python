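"""Enumeration, flipping and labelling of the TU cassette arrangements."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from grncontext.arrangements import (
    FORWARD,
    REVERSE,
    Arrangement,
    LabelError,
    TerminatorSpec,
    enumerate_arrangements,
    enumerate_slot_assignments,
    flip_arrangement,
    format_label,
    orientation_pairs,
    pair_id,
    parse_label,
)


class TestEnumeration:
    def test_counts(self):
        assert len(enumerate_arrangements(allow_reverse=True)) == 48
        assert len(enumerate_arrangements(allow_reverse=False)) == 6

    def test_all_distinct_and_sorted(self):
        labels = [a.label for a in enumerate_arrangements()]
        assert len(set(labels)) == 48
        assert labels == sorted(labels)

    def test_every_gene_in_every_slot(self):
        arrs = enumerate_arrangements()
        for slot in range(3):
            genes = {a.slots[slot][0] for a in arrs}
            assert genes == {"lacI", "tetR", "cI"}

    def test_generalized_helper_single_gene(self):
        assert len(enumerate_slot_assignments(["lacI"], allow_reverse=True)) == 2


class TestFlip:
    def test_flip_is_involution(self, all48):
        for a in all48:
            assert flip_arrangement(flip_arrangement(a)) == a

    def test_flip_example(self):
        a = parse_label("TLC")
        assert flip_arrangement(a).slots == (
            ("cI", REVERSE),
            ("lacI", REVERSE),
            ("tetR", REVERSE),
        )

    def test_no_fixed_points(self, all48):
        assert all(flip_arrangement(a) != a for a in all48)

    def test_flip_reverses_junctions(self):
        a = parse_label("TLC").with_junction(0, TerminatorSpec("Tcrp", 0.8, 0))
        b = flip_arrangement(a)
        assert b.junctions[1].name == "Tcrp"


class TestOrientationPairs:
    def test_partition_into_24(self, all48):
        pairs = orientation_pairs(all48)
        assert len(pairs) == 24
        members = [a.label for p in pairs for a in p]
        assert sorted(members) == sorted(a.label for a in all48)

    def test_all_forward_pairs_with_all_reverse(self):
        pairs = orientation_pairs(enumerate_arrangements())
        by_id = {pair_id(p[0]): p for p in pairs}
        tlc = parse_label("TLC")
        pair = by_id[pair_id(tlc)]
        labels = {a.label for a in pair}
        assert labels == {"TLC", "C_rL_rT_r"}

    def test_not_closed_raises(self, all48):
        with pytest.raises(ValueError, match="not closed"):
            orientation_pairs(all48[:5])


class TestLabels:
    @pytest.mark.parametrize(
        "label, slots",
        [
            ("TLC", (("tetR", FORWARD), ("lacI", FORWARD), ("cI", FORWARD))),
            ("LT_rC_r", (("lacI", FORWARD), ("tetR", REVERSE), ("cI", REVERSE))),
            ("CTL_r", (("cI", FORWARD), ("tetR", FORWARD), ("lacI", REVERSE))),
        ],
    )
    def test_parse_examples(self, label, slots):
        assert parse_label(label).slots == slots

    def test_roundtrip_over_full_enumeration(self, all48):
        for a in all48:
            assert parse_label(format_label(a)) == a

    @pytest.mark.parametrize(
        "bad, token",
        [("XLT", "'X'"), ("TTL", "'T'"), ("TL", "exactly 3"), ("TLCC", "'C'")],
    )
    def test_malformed_labels_name_the_token(self, bad, token):
        with pytest.raises(LabelError, match=token):
            parse_label(bad)


class TestTerminatorSpec:
    def test_rate_tracks_model_mu(self):
        assert TerminatorSpec("T1").rate(0.6) == pytest.approx(0.6)
        assert TerminatorSpec("T1T2", mu_power=2).rate(0.6) == pytest.approx(0.36)
        assert TerminatorSpec("Tcrp", 0.8, 0).rate(0.6) == pytest.approx(0.8)

    def test_combined_multiplies(self):
        half = TerminatorSpec("A", 0.5, 0)
        double = half.combined(TerminatorSpec("B", 0.5, 0))
        assert double.rate(0.9) == pytest.approx(0.25)
        mixed = half.combined(TerminatorSpec("T1"))
        assert mixed.rate(0.6) == pytest.approx(0.3)

    @given(st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
    def test_combined_never_exceeds_weaker_part(self, r1, r2):
        a = TerminatorSpec("A", r1, 0)
        b = TerminatorSpec("B", r2, 0)
        assert a.combined(b).rate(1.0) <= min(r1, r2) + 1e-12

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            TerminatorSpec("bad", 1.5, 0)


class TestArrangementValidation:
    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError):
            Arrangement((("lacI", FORWARD), ("lacI", FORWARD), ("cI", FORWARD)))

    def test_junction_count_enforced(self):
        with pytest.raises(ValueError):
            Arrangement(
                (("lacI", FORWARD), ("tetR", FORWARD), ("cI", FORWARD)),
                junctions=(TerminatorSpec("T1"),),
            )
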