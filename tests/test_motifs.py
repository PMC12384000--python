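"""Motif enumeration, subsumption, IQ scanning and fingerprint algebra.

The independent oracles here are built on the stdlib ``re`` engine
(lookahead patterns for overlapping hits), whereas the library enumerates
positions explicitly — the two routes share no code.
"""

import itertools
import re

import pytest
from hypothesis import given, strategies as st

from camscan.motifs import (
    CORE_ANCHORS,
    DEFAULT_CLASSES,
    EXTENDED_ANCHORS,
    MOTIF_CLASSES,
    AnchorSet,
    MotifClass,
    apply_subsumption,
    compare_fingerprints,
    enumerate_matches,
    fingerprint_table,
    scan_iq,
    scan_motifs,
)
from camscan.sequences import ProteinSequence

# ---------------------------------------------------------------- oracles

def regex_motif_oracle(seq, classes=DEFAULT_CLASSES, anchors=CORE_ANCHORS):
    """Enumerate (class, anchor positions) with the re engine."""
    letters = "".join(sorted(anchors.letters))
    hits = []
    for cls in classes:
        pat = ""
        prev = None
        for o in cls.anchor_offsets:
            if prev is not None:
                pat += f".{{{o - prev - 1}}}"
            pat += f"[{letters}]"
            prev = o
        for m in re.finditer(rf"(?=({pat}))", seq.residues):
            i0 = m.start()
            hits.append((cls.name, tuple(seq.offset + i0 + o for o in cls.anchor_offsets)))
    return sorted(hits)


IQ_REGEX = re.compile(r"(?=([FILV]Q.{3}[RK]G.{3}[RK].{2}[FILVWY]))")


def regex_iq_oracle(seq):
    return [(seq.offset + m.start(), m.group(1)) for m in IQ_REGEX.finditer(seq.residues)]


def _as_pairs(matches):
    return sorted((m.class_name, m.anchor_positions) for m in matches)


# ------------------------------------------------------------ enumeration

class TestEnumerate:
    def test_no_anchor_residues(self):
        assert enumerate_matches(ProteinSequence("g", "G" * 16)) == []

    def test_camkii_1_5_10(self):
        seq = ProteinSequence("camkiia", "RRKLKGAILTTMLATR", offset=296)
        matches = enumerate_matches(seq, classes=[MOTIF_CLASSES["1-5-10"]])
        assert len(matches) == 1
        m = matches[0]
        assert m.anchor_positions == (299, 303, 308)
        assert m.fingerprint == "LIL"
        assert (m.span_start, m.span_end) == (299, 308)

    def test_rock1_raw_exactly_two(self):
        seq = ProteinSequence("rock1", "AFGEVQLVRHKSTRKVYAM", offset=86)
        assert _as_pairs(enumerate_matches(seq)) == [
            ("1-10", (92, 101)),
            ("1-12", (90, 101)),
        ]
        fps = {m.class_name: m.fingerprint for m in enumerate_matches(seq)}
        assert fps == {"1-12": "VV", "1-10": "LV"}

    def test_sorted_by_span_start_then_span_then_name(self):
        seq = ProteinSequence("tgm2", "KSINRSLIVGLKISTKSVGR", offset=414)
        matches = enumerate_matches(seq)
        keys = [(m.span_start, m.span, m.class_name) for m in matches]
        assert keys == sorted(keys)

    def test_empty_class_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            enumerate_matches(ProteinSequence("x", "ALLILV"), classes=[])

    def test_x_never_matches_anchor(self):
        seq = ProteinSequence("x", "XGGGGGGGGX")
        assert enumerate_matches(seq) == []


class TestMotifClassInvariants:
    def test_builtin_names_agree_with_offsets(self):
        for cls in DEFAULT_CLASSES:
            named = tuple(int(p) for p in cls.name.split("-"))
            assert named == tuple(o + 1 for o in cls.anchor_offsets)
            assert cls.span == cls.anchor_offsets[-1] + 1

    def test_parent_links(self):
        assert MOTIF_CLASSES["1-5-10"].parent == "1-10"
        assert MOTIF_CLASSES["1-8-14"].parent == "1-14"
        assert MOTIF_CLASSES["1-8-13"].parent is None

    def test_bad_class_rejected(self):
        with pytest.raises(ValueError):
            MotifClass("1-10", (1, 9))
        with pytest.raises(ValueError):
            MotifClass("1-5-10", (0, 4, 10))

    def test_anchor_set_validation(self):
        with pytest.raises(ValueError):
            AnchorSet("bad", frozenset())
        with pytest.raises(ValueError):
            AnchorSet("bad", frozenset("FX"))


# ------------------------------------------------------------ subsumption

class TestSubsumption:
    def test_camkii_curated_single_motif(self):
        seq = ProteinSequence("camkiia", "RRKLKGAILTTMLATR", offset=296)
        raw = enumerate_matches(seq)
        assert _as_pairs(raw) == [("1-10", (299, 308)), ("1-5-10", (299, 303, 308))]
        curated = apply_subsumption(raw, seq, CORE_ANCHORS)
        assert _as_pairs(curated) == [("1-5-10", (299, 303, 308))]

    def test_tgm2_cambd1_curated_three(self):
        seq = ProteinSequence("tgm2", "KSINRSLIVGLKISTKSVGR", offset=414)
        raw = enumerate_matches(seq)
        assert _as_pairs(raw) == [
            ("1-10", (422, 431)),
            ("1-12", (420, 431)),
            ("1-16", (416, 431)),
            ("1-5-10", (422, 426, 431)),
        ]
        curated = apply_subsumption(raw)
        assert sorted(m.class_name for m in curated) == ["1-12", "1-16", "1-5-10"]

    def test_passthrough_without_three_anchor_matches(self):
        seq = ProteinSequence("rock1", "AFGEVQLVRHKSTRKVYAM", offset=86)
        raw = enumerate_matches(seq)
        assert apply_subsumption(raw) == raw

    def test_non_coterminal_two_anchor_survives(self):
        # 1-8-13 is three-anchor but refines nothing; it must suppress nothing
        seq = ProteinSequence("gsk3b", "LVAIKKVLQDKRFKNRELQI", offset=81)
        curated = scan_motifs(seq)
        assert ("1-8-13", (81, 88, 93)) in _as_pairs(curated)
        assert ("1-12", (82, 93)) in _as_pairs(curated)


# ---------------------------------------------------------------- IQ scan

class TestIQ:
    def test_instantiated_pattern(self):
        matches = scan_iq(ProteinSequence("iq", "IQAAARGAAARAAF"))
        assert [(m.start, m.matched) for m in matches] == [(1, "IQAAARGAAARAAF")]

    def test_no_match_on_homopolymer(self):
        assert scan_iq(ProteinSequence("g", "G" * 14)) == []

    def test_x_never_matches_bracketed_class(self):
        assert scan_iq(ProteinSequence("x", "XQAAARGAAARAAF")) == []
        # but X may occupy a wildcard slot
        assert len(scan_iq(ProteinSequence("x", "IQXAARGAAARAAF"))) == 1

    def test_spliced_window_in_random_background(self):
        import numpy as np

        rng = np.random.default_rng(7)
        bg = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        spliced = bg[:100] + "IQAAARGAAARAAF" + bg[114:]
        seq = ProteinSequence("synthetic-iq", spliced)
        matches = scan_iq(seq)
        assert 101 in [m.start for m in matches]
        assert [(m.start, m.matched) for m in matches] == regex_iq_oracle(seq)


# ------------------------------------------------------------ fingerprints

class TestFingerprints:
    def test_gsk3b_cambd1_table(self):
        seq = ProteinSequence("gsk3b", "LVAIKKVLQDKRFKNRELQI", offset=81)
        table = fingerprint_table(scan_motifs(seq))
        assert table["1-5-10"] == {"ILF"}
        assert "VF" in table["1-12"]

    def test_camkii_table(self):
        seq = ProteinSequence("camkiia", "RRKLKGAILTTMLATR", offset=296)
        assert fingerprint_table(scan_motifs(seq)) == {"1-5-10": {"LIL"}}

    def test_empty(self):
        assert fingerprint_table([]) == {}

    def test_camkii_vs_gsk3b_no_overlap(self):
        cmp = compare_fingerprints({"1-5-10": {"LIL"}}, {"1-5-10": {"ILF"}})
        assert cmp["1-5-10"].shared == frozenset()
        assert cmp["1-5-10"].only_a == {"LIL"}
        assert cmp["1-5-10"].only_b == {"ILF"}

    def test_identity(self):
        table = {"1-12": {"VI", "VF"}, "1-10": {"LV"}}
        cmp = compare_fingerprints(table, table)
        for diff in cmp.values():
            assert diff.only_a == diff.only_b == frozenset()

    def test_set_algebra(self):
        cmp = compare_fingerprints({"1-12": {"VI", "VF"}}, {"1-12": {"VF"}})
        assert cmp["1-12"].shared == {"VF"}
        assert cmp["1-12"].only_a == {"VI"}
        assert cmp["1-12"].only_b == frozenset()

    def test_class_absent_from_one_table(self):
        cmp = compare_fingerprints({"1-10": {"LL"}}, {})
        assert cmp["1-10"].only_a == {"LL"}
        assert cmp["1-10"].shared == frozenset()


# ------------------------------------------------------------- properties

seqs_5letter = st.text(alphabet="GALIF", min_size=1, max_size=30)


class TestProperties:
    @given(seqs_5letter)
    def test_enumeration_equals_regex_oracle(self, residues):
        seq = ProteinSequence("p", residues)
        assert _as_pairs(enumerate_matches(seq)) == regex_motif_oracle(seq)

    def test_enumeration_exhaustive_two_letter_sweep(self):
        # every sequence over {G, L} up to length 12, against the re oracle
        for n in range(1, 13):
            for combo in itertools.product("GL", repeat=n):
                seq = ProteinSequence("p", "".join(combo))
                assert _as_pairs(enumerate_matches(seq)) == regex_motif_oracle(seq)

    @given(seqs_5letter, st.integers(min_value=0, max_value=10))
    def test_shift_covariance(self, residues, k):
        base = ProteinSequence("p", residues)
        shifted = ProteinSequence("p", "G" * k + residues)
        base_pairs = _as_pairs(enumerate_matches(base))
        shifted_pairs = sorted(
            (name, tuple(p - k for p in pos))
            for name, pos in _as_pairs(enumerate_matches(shifted))
        )
        assert shifted_pairs == base_pairs

    @given(seqs_5letter.map(lambda s: s.replace("A", "M")))
    def test_anchor_set_monotonicity(self, residues):
        seq = ProteinSequence("p", residues)
        core = set(_as_pairs(enumerate_matches(seq, anchors=CORE_ANCHORS)))
        extended = set(_as_pairs(enumerate_matches(seq, anchors=EXTENDED_ANCHORS)))
        assert core <= extended

    @given(seqs_5letter)
    def test_curated_subset_of_raw_and_removal_rule(self, residues):
        seq = ProteinSequence("p", residues)
        raw = enumerate_matches(seq)
        curated = apply_subsumption(raw)
        assert set(curated) <= set(raw)
        removed = set(raw) - set(curated)
        three_anchor_terminals = {
            (MOTIF_CLASSES[m.class_name].parent, m.anchor_positions[0], m.anchor_positions[-1])
            for m in raw
            if MOTIF_CLASSES[m.class_name].parent is not None
        }
        for m in removed:
            assert len(m.anchor_positions) == 2
            key = (m.class_name, m.anchor_positions[0], m.anchor_positions[-1])
            assert key in three_anchor_terminals

    @given(seqs_5letter)
    def test_anchor_soundness(self, residues):
        seq = ProteinSequence("p", residues)
        for m in enumerate_matches(seq):
            assert set(m.fingerprint) <= CORE_ANCHORS.letters
            assert len(m.fingerprint) == len(m.anchor_positions)
            assert m.span == MOTIF_CLASSES[m.class_name].span

    @given(st.text(alphabet="IQARGKFVX", min_size=1, max_size=40))
    def test_iq_scan_equals_regex_oracle(self, residues):
        seq = ProteinSequence("p", residues)
        assert [(m.start, m.matched) for m in scan_iq(seq)] == regex_iq_oracle(seq)
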