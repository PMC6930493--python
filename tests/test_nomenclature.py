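"""Grammar, composition codes and candidate enumeration."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, strategies as st

from hepseq.nomenclature import (
    CompositionCode,
    EnumerationCapError,
    EnumerationConstraints,
    GAGSequence,
    ParseError,
    Residue,
    ResidueClass,
    composition_of,
    enumerate_sequences,
    format_code,
    format_sequence,
    parse_code,
    parse_sequence,
)

from conftest import gag_sequences


class TestSequenceGrammar:
    @pytest.mark.parametrize(
        "text, n, first_epimer, first_sulfated",
        [
            ("G–ANS3S6S–I2S–ANS6S–I2S–ANS6S–I2S–aM.ol6S", 8, "G", False),
            ("ΔU2S–ANS6S", 2, None, True),
            ("I2S-ANS6S-I2S-aM.ol6S", 4, "I", True),  # ASCII hyphens accepted
        ],
    )
    def test_parse_examples(self, text, n, first_epimer, first_sulfated):
        seq = parse_sequence(text)
        assert len(seq) == n
        first = seq.residues[0]
        if first_epimer is not None:
            assert first.epimer == first_epimer
        assert first.sulfo_2O is first_sulfated

    def test_bare_u_has_unknown_epimer(self):
        assert parse_sequence("U–ANS").residues[0].epimer == "unknown"

    @pytest.mark.parametrize(
        "text, fragment",
        [
            ("G–G", "alternation"),
            ("G–ANS–ΔU–ANS", "ΔU"),
            ("aM.ol–I2S", "aM.ol"),
            ("G–AXX", "AXX"),
            ("", "empty"),
        ],
    )
    def test_parse_errors_name_the_problem(self, text, fragment):
        with pytest.raises(ParseError, match=fragment):
            parse_sequence(text)

    @given(gag_sequences())
    def test_format_parse_round_trip(self, seq):
        assert parse_sequence(format_sequence(seq)) == seq


class TestCompositionCodes:
    @pytest.mark.parametrize(
        "seq_text, code_text",
        [
            ("G–ANS3S6S–I2S–ANS6S–I2S–ANS6S–I2S–aM.ol6S", "U8,11,0–aM.ol"),
            ("ΔU–ANAc6S–G–ANS3S", "ΔU4,3,1"),
            ("G", "U1,0,0"),
            ("ANS3S6S–I2S–ANS6S–I2S–ANS6S–I2S–aM.ol6S", "A7,11,0–aM.ol"),
        ],
    )
    def test_composition_of(self, seq_text, code_text):
        assert str(composition_of(parse_sequence(seq_text))) == code_text

    def test_parse_code_with_rc_and_label(self):
        code = parse_code("U8,10,0,Rc–aM.ol")
        assert (code.nre_class, code.n_residues, code.n_sulfates, code.n_acetyls) == ("U", 8, 10, 0)
        assert code.has_rc and code.has_amol
        labelled = parse_code("ΔU4,5,0 (2)")
        assert labelled.label == "2"
        # the label is annotation, never identity
        assert labelled == parse_code("ΔU4,5,0")

    def test_format_examples(self):
        assert format_code(CompositionCode("ΔU", 4, 6, 0)) == "ΔU4,6,0"
        assert format_code(parse_code("U8,10,0,Rc–aM.ol")) == "U8,10,0,Rc–aM.ol"

    def test_malformed_code(self):
        with pytest.raises(ParseError):
            parse_code("X4,5,0")
        with pytest.raises(ParseError):
            parse_code("ΔU4,5")

    @given(
        st.sampled_from(["ΔU", "U", "A"]),
        st.integers(1, 12),
        st.integers(0, 20),
        st.integers(0, 4),
        st.booleans(),
        st.sampled_from([None, "1", "2", "3"]),
    )
    def test_code_round_trip(self, nre, n, s, a, rc, label):
        code = CompositionCode(nre, n, s, a, has_amol=False, has_rc=rc, label=label)
        back = parse_code(format_code(code))
        assert back == code and back.label == label

    @given(gag_sequences())
    def test_sequence_round_trips_through_its_code_mass_invariants(self, seq):
        code = composition_of(seq)
        assert code.n_sulfates == sum(r.sulfate_count for r in seq)
        assert code.n_acetyls == sum(1 for r in seq if r.is_acetylated)


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------


def _brute_force_count(code: CompositionCode, c: EnumerationConstraints) -> int:
    """Independent oracle: full cartesian product over substituent options,
    filtered by an independently written constraint checker."""
    from hepseq.nomenclature import _class_skeletons  # layout only

    total = 0
    for skel in _class_skeletons(code):
        slot_opts = []
        for cls in skel:
            if cls is ResidueClass.DELTA_URONIC:
                slot_opts.append([("d", None, s2, None, False, False) for s2 in (False, True)])
            elif cls is ResidueClass.URONIC:
                slot_opts.append(
                    [("u", e, s2, None, False, False) for e in ("I", "G") for s2 in (False, True)]
                )
            elif cls is ResidueClass.HEXOSAMINE:
                slot_opts.append(
                    [
                        ("h", None, False, ns, s3, s6)
                        for ns in ("NS", "NAc", "NH2")
                        for s3 in (False, True)
                        for s6 in (False, True)
                    ]
                )
            elif cls is ResidueClass.ANHYDROMANNITOL:
                slot_opts.append([("m", None, False, None, False, s6) for s6 in (False, True)])
            else:
                slot_opts.append([("r", None, False, None, False, False)])
        for combo in itertools.product(*slot_opts):
            n_s = sum(
                int(s2) + int(s3) + int(s6) + int(ns == "NS") for _, _, s2, ns, s3, s6 in combo
            )
            n_a = sum(1 for _, _, _, ns, _, _ in combo if ns == "NAc")
            if n_s != code.n_sulfates or n_a != code.n_acetyls:
                continue
            ok = True
            n_s3 = 0
            for i, (kind, e, s2, ns, s3, s6) in enumerate(combo):
                if kind == "u" and s2 and c.iduronic_if_2S and e != "I":
                    ok = False
                if ns == "NH2" and not c.allow_nh2:
                    ok = False
                if s3:
                    n_s3 += 1
                    if c.sulfo3_requires_ns and ns != "NS":
                        ok = False
                    if c.sulfo3_requires_g_context and i > 0:
                        pk, pe, ps2, *_ = combo[i - 1]
                        if ps2 or (pk == "u" and pe != "G"):
                            ok = False
                if not ok:
                    break
            if ok and (c.max_sulfo3 is None or n_s3 <= c.max_sulfo3):
                total += 1
    return total


class TestEnumeration:
    def test_contains_printed_disaccharide(self):
        seqs = enumerate_sequences(parse_code("ΔU2,3,0"))
        assert parse_sequence("ΔU2S–ANS6S") in seqs

    def test_contains_all_three_pentasulfated_tetrasaccharides(self):
        seqs = enumerate_sequences(parse_code("ΔU4,5,0"))
        for text in (
            "ΔU–ANS6S–G–ANS3S6S",
            "ΔU2S–ANS–G–ANS3S6S",
            "ΔU2S–ANS6S–G–ANS3S",
        ):
            assert parse_sequence(text) in seqs

    def test_monosaccharide_epimer_count(self):
        assert len(enumerate_sequences(parse_code("U1,0,0"))) == 2

    def test_every_member_matches_the_code(self):
        code = parse_code("ΔU4,4,1")
        for seq in enumerate_sequences(code):
            assert composition_of(seq) == code

    def test_infeasible_code_gives_empty_set(self):
        assert enumerate_sequences(parse_code("U2,9,0")) == set()

    def test_cap_exceeded_raises(self):
        with pytest.raises(EnumerationCapError):
            enumerate_sequences(parse_code("U12,10,0"))

    @pytest.mark.parametrize(
        "code_text",
        ["U1,0,0", "ΔU2,3,0", "U2,3,0", "U3,3,0", "ΔU4,5,0", "ΔU4,4,1", "A3,5,0–aM.ol", "U4,4,0,Rc"],
    )
    def test_count_matches_brute_force_oracle(self, code_text):
        code = parse_code(code_text)
        c = EnumerationConstraints()
        assert len(enumerate_sequences(code, c)) == _brute_force_count(code, c)

    def test_count_matches_oracle_with_lifted_constraints(self):
        c = EnumerationConstraints(
            allow_nh2=True, sulfo3_requires_g_context=False, max_sulfo3=None
        )
        for code_text in ("U2,4,0", "ΔU4,6,0"):
            code = parse_code(code_text)
            assert len(enumerate_sequences(code, c)) == _brute_force_count(code, c)
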