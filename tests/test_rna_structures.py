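import numpy as np
import pytest

import shaperefine as sr
from shaperefine.rna_structures import (
    MotifSignature,
    SecondaryStructure,
    StructureParseError,
    extract_loops,
    motif_of,
    parse_ct,
    parse_dotbracket,
    parse_shape,
    pattern_positions,
    read_dotbracket_file,
    write_ct,
    write_dotbracket,
    write_dotbracket_file,
)

from _oracles import brute_force_loops, random_dotbracket, random_sequence


def _seq(n):
    return "A" * n


class TestDotBracketParsing:
    def test_fully_nested(self):
        s = parse_dotbracket("((((....))))", "GGGGAAAACCCC")
        assert s.pairs == {(1, 12), (2, 11), (3, 10), (4, 9)}
        assert s.pk_pairs == frozenset()

    def test_unpaired(self):
        s = parse_dotbracket(".....", "AAAAA")
        assert s.pairs == frozenset()

    def test_square_brackets_are_pseudoknots(self):
        s = parse_dotbracket("((..[[..))..]]", _seq(14))
        assert s.pk_pairs == {(5, 14), (6, 13)}
        assert s.nested_pairs == {(1, 10), (2, 9)}

    def test_unbalanced_raises_with_position(self):
        with pytest.raises(StructureParseError, match="position"):
            parse_dotbracket("((..)", _seq(5))
        with pytest.raises(StructureParseError, match="position"):
            parse_dotbracket(".))..", _seq(5))

    def test_length_mismatch(self):
        with pytest.raises(StructureParseError, match="length"):
            parse_dotbracket("....", _seq(5))

    @pytest.mark.parametrize("seed", range(10))
    def test_roundtrip_random_nested(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            db = random_dotbracket(rng, int(rng.integers(20, 70)))
            s = parse_dotbracket(db, random_sequence(rng, db))
            assert write_dotbracket(s) == db

    def test_roundtrip_with_pseudoknot_layers(self):
        db = "((..[[..))..]]"
        s = parse_dotbracket(db, _seq(14))
        assert write_dotbracket(s) == db


class TestCtFormat:
    def test_ct_row_pairing(self):
        text = "10 test\n" + "\n".join(
            f"{i} A {i - 1} {i + 1 if i < 10 else 0} {p} {i}"
            for i, p in zip(range(1, 11), [10, 9, 0, 0, 0, 0, 0, 0, 2, 1])
        )
        s = parse_ct(text)
        assert (5, 10) not in s.pairs
        assert {(1, 10), (2, 9)} == set(s.pairs)

    def test_ct_roundtrip(self, rng):
        for _ in range(20):
            db = random_dotbracket(rng, 50)
            s = parse_dotbracket(db, random_sequence(rng, db))
            assert parse_ct(write_ct(s)).pairs == s.pairs

    def test_duplicate_index_raises(self):
        text = "2 x\n1 A 0 2 0 1\n1 A 0 2 0 1"
        with pytest.raises(StructureParseError, match="line 3"):
            parse_ct(text)

    def test_non_numeric_raises(self):
        with pytest.raises(StructureParseError, match="line 2"):
            parse_ct("1 x\nq A 0 0 0 1")

    def test_out_of_range_partner(self):
        with pytest.raises(StructureParseError):
            parse_ct("2 x\n1 A 0 2 9 1\n2 A 1 0 0 2")


class TestShapeFormat:
    def test_sentinel_and_values(self):
        profile = parse_shape("1 0.8\n2 -999\n")
        assert profile.reactivity(1) == pytest.approx(0.8)
        assert profile.is_missing(2)

    def test_absent_index_is_missing(self):
        profile = parse_shape("1 0.5\n3 0.2\n")
        assert profile.is_missing(2)
        assert len(profile) == 3

    def test_duplicate_raises(self):
        with pytest.raises(StructureParseError, match="line 2"):
            parse_shape("1 0.5\n1 0.7\n")

    def test_non_numeric_raises(self):
        with pytest.raises(StructureParseError, match="line 1"):
            parse_shape("1 abc\n")

    def test_roundtrip(self):
        profile = parse_shape("1 0.8\n2 -999\n3 1.25\n")
        again = parse_shape(sr.write_shape(profile))
        assert np.allclose(again.values, profile.values, equal_nan=True)


class TestMultiStructureFiles:
    def test_sequence_optional_after_first(self):
        text = ">a\nGGGGAAAACCCC\n((((....))))\n>b\n((((...))))."
        structs = read_dotbracket_file(text)
        assert len(structs) == 2
        assert structs[0].sequence == structs[1].sequence
        assert structs[1].name == "b"

    def test_roundtrip(self, rng):
        db = random_dotbracket(rng, 40)
        seq = random_sequence(rng, db)
        structs = [
            SecondaryStructure(seq, parse_dotbracket(db, seq).pairs, name="x"),
            SecondaryStructure(seq, frozenset(), name="y"),
        ]
        again = read_dotbracket_file(write_dotbracket_file(structs))
        assert [s.pairs for s in again] == [s.pairs for s in structs]

    def test_missing_header_raises(self):
        with pytest.raises(StructureParseError):
            read_dotbracket_file("GGGG\n....")


class TestStructureInvariants:
    def test_index_in_two_pairs_rejected(self):
        with pytest.raises(ValueError, match="more than one pair"):
            SecondaryStructure(_seq(10), frozenset({(1, 5), (5, 9)}))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SecondaryStructure(_seq(4), frozenset({(1, 5)}))

    def test_crossing_pairs_auto_flagged(self):
        # from a CT-style pair list, crossing pairs get split out
        s = SecondaryStructure(_seq(20), frozenset({(1, 10), (5, 15)}))
        assert s.pk_pairs == {(5, 15)}
        assert s.nested_pairs == {(1, 10)}


class TestLoopExtraction:
    def test_single_hairpin(self):
        s = parse_dotbracket("((((....))))", "GGGGAAAACCCC")
        loops = extract_loops(s)
        assert len(loops) == 1
        (loop,) = loops
        assert loop.loop_type == "hairpin"
        assert loop.sides == ((5, 6, 7, 8),)
        assert loop.closing_pairs == ((4, 9),)
        assert loop.flanking_pairs == ((3, 10),)

    def test_internal_plus_hairpin(self):
        s = parse_dotbracket("((.((....)).))", _seq(14))
        kinds = {(l.loop_type, l.sides) for l in extract_loops(s)}
        assert ("internal", ((3,), (12,))) in kinds
        assert ("hairpin", ((6, 7, 8, 9),)) in kinds
        internal = next(l for l in extract_loops(s) if l.loop_type == "internal")
        assert internal.closing_pairs == ((2, 13), (4, 11))

    def test_bulge_plus_hairpin(self):
        s = parse_dotbracket("((.((....))))", _seq(13))
        kinds = {(l.loop_type, l.sides) for l in extract_loops(s)}
        assert ("bulge", ((3,),)) in kinds
        assert ("hairpin", ((6, 7, 8, 9),)) in kinds

    def test_single_flank_helix_dropped(self):
        # hairpin closed by a lone pair: no second stacked pair, ineligible
        s = parse_dotbracket("(....)", _seq(6))
        assert extract_loops(s) == []
        assert len(extract_loops(s, require_stacked=False)) == 1

    def test_pseudoknotted_hairpin_removed(self):
        # hairpin residues pair into a pseudoknot: loop must be dropped
        db = "((((..[[))))..]]"
        s = parse_dotbracket(db, _seq(16))
        assert all(l.loop_type != "hairpin" or 7 not in l.positions
                   for l in extract_loops(s))
        with_pk = extract_loops(s, drop_pseudoknot=False)
        without = extract_loops(s)
        assert len(with_pk) == len(without) + 1

    def test_multibranch_extracted(self):
        db = "..(((..((....))((....))..))).."
        s = parse_dotbracket(db, _seq(30))
        loops = extract_loops(s, require_stacked=False)
        mb = [l for l in loops if l.loop_type == "multibranch"]
        assert len(mb) == 1
        assert len(mb[0].closing_pairs) == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        for _ in range(20):
            db = random_dotbracket(rng, int(rng.integers(30, 81)))
            s = parse_dotbracket(db, random_sequence(rng, db))
            got = {(l.loop_type, l.sides, l.closing_pairs) for l in extract_loops(s)}
            expected = brute_force_loops(set(s.pairs), len(s))
            assert got == expected

    def test_position_conservation(self, rng):
        # unpaired side positions + paired positions + exterior unpaired
        # tile the sequence exactly once on fully nested structures
        for _ in range(20):
            db = random_dotbracket(rng, 60)
            s = parse_dotbracket(db, random_sequence(rng, db))
            loops = extract_loops(s, require_stacked=False)
            loop_positions = [p for l in loops for p in l.positions]
            assert len(loop_positions) == len(set(loop_positions))
            paired = {p for pr in s.pairs for p in pr}
            enclosed_unpaired = {
                x for x in range(1, len(s) + 1)
                if x not in paired and any(i < x < j for i, j in s.pairs)
            }
            assert set(loop_positions) == enclosed_unpaired


class TestMotifs:
    def test_hairpin_and_bulge_motifs(self):
        s = parse_dotbracket("((.((....))))", _seq(13))
        motifs = {str(l.motif) for l in extract_loops(s)}
        assert motifs == {"bulge-1", "hairpin-4"}

    def test_internal_canonicalization_min_side_first(self):
        assert MotifSignature("internal", (2, 1)) == MotifSignature("internal", (1, 2))
        assert str(MotifSignature("internal", (2, 1))) == "internal-1x2"

    def test_asymmetric_internal_enumerates_shorter_side_first(self):
        # 5' side has 2 nt, 3' side 1 nt: enumeration starts on the 3' side
        s = parse_dotbracket("((..((....)).))", _seq(15))
        loop = next(l for l in extract_loops(s) if l.loop_type == "internal")
        assert loop.sides == ((3, 4), (13,))
        assert pattern_positions(loop) == (13, 3, 4)
        assert str(loop.motif) == "internal-1x2"

    def test_motif_string_roundtrip(self):
        for m in (MotifSignature("hairpin", (5,)), MotifSignature("bulge", (2,)),
                  MotifSignature("internal", (3, 6))):
            assert MotifSignature.from_string(str(m)) == m

    def test_unknown_motif_string_raises(self):
        with pytest.raises(StructureParseError):
            MotifSignature.from_string("stemloop-4")

    def test_motif_of_agrees_with_loop_motif(self, rng):
        db = random_dotbracket(rng, 70)
        s = parse_dotbracket(db, random_sequence(rng, db))
        for loop in extract_loops(s):
            assert motif_of(loop) == loop.motif
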