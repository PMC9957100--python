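"""Motif engine: anchors, gap grammar, greedy assembly, bracketing."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from garfinder import (
    ProteinRecord,
    assemble_motifs,
    bracket_sequence,
    find_anchors,
    is_valid_gap,
    make_synthetic_record,
)

from conftest import oracle_gap_valid, oracle_motifs, random_sequence, record

ZEBRAFISH_FBL_1 = "PRGGGGRGGFGGRGRGGGDRGGRGGFRGGRGG"
ZEBRAFISH_FBL_2 = "GGFRGRGGGRGTPRGRGGGRGGGRGGFRGG"
HUMAN_NCL = "GGRGGGRGGFGGRGGGRGGRGGFGGRGRGGFGGRGGFRGGRGG"
ZNF579 = "HRGRGRGRGRGRGRGRGRGRGG"


class TestFindAnchors:
    def test_minimal_pair(self):
        anchors = find_anchors("RGRG")
        assert [(a.r_position, a.g_run) for a in anchors] == [(1, 1), (3, 1)]

    def test_no_anchor_without_following_g(self):
        assert find_anchors("ARRA") == []

    def test_bare_r_before_anchor(self):
        # in RRGG only the second R is an anchor
        anchors = find_anchors("RRGG")
        assert [(a.r_position, a.g_run) for a in anchors] == [(2, 2)]

    def test_g_run_measured_on_full_sequence(self):
        (a,) = find_anchors("ARGGGGGA")
        assert (a.r_position, a.g_run, a.unit_class) == (2, 5, "RGG")


class TestGapGrammar:
    @pytest.mark.parametrize("segment, valid", [
        ("G", True),                      # minimal gap -> RGRG
        ("GG", True),
        ("G" * 13, True),                 # longest straight polyG tract
        ("G" * 14, True),                 # literal grammar bound (final X = G)
        ("G" * 15, False),
        ("GGFGGGFKSPGGEGGF", False),      # 16 residues: splits a real domain
        ("GAAAAAAG", False),              # 6 non-G cannot split as <=5 then <=1
        ("GAAAAAG", True),                # 5 then 1 around the empty G slots
        ("GKADEG", True),
        ("GRAGYSQ", True),                # bare R absorbed by a wildcard slot
        ("", False),                      # gap must start with >=1 G
        ("AG", False),
    ])
    def test_examples(self, segment, valid):
        assert is_valid_gap(segment) is valid
        assert oracle_gap_valid(segment) is valid

    def test_agrees_with_enumeration_oracle(self, rng):
        for _ in range(3000):
            seg = "".join(rng.choices("GA", k=rng.randint(0, 16)))
            assert is_valid_gap(seg) == oracle_gap_valid(seg), seg


class TestAssembly:
    def test_isolated_motif_covers_itself(self):
        (m,) = assemble_motifs(record(HUMAN_NCL))
        assert (m.start, m.end) == (1, len(HUMAN_NCL))
        assert m.motif_sequence == HUMAN_NCL

    def test_split_domain_yields_two_motifs(self):
        syn = make_synthetic_record([
            ("pad", "MKTEAS"),
            ("motif", ZEBRAFISH_FBL_1),
            ("spacer", "FGGGFKSPGGE"),
            ("motif", ZEBRAFISH_FBL_2),
        ])
        motifs = assemble_motifs(syn.record)
        assert [(m.start, m.end) for m in motifs] == [(7, 38), (50, 79)]
        assert [(m.start, m.end) for m in motifs] == list(syn.expected_spans)

    def test_single_anchor_is_not_a_motif(self):
        assert assemble_motifs(record("MARGGAAAA")) == []

    def test_leading_wildcard_included(self):
        (m,) = assemble_motifs(record(ZNF579))
        assert (m.start, m.end) == (1, 22)
        assert m.motif_sequence.startswith("H")

    def test_trailing_g_capped_at_two(self):
        (m,) = assemble_motifs(record("RGRGGGGGA"))
        assert m.motif_sequence == "RGRGG"
        assert m.anchors[-1].unit_class == "RGG"

    def test_motifs_disjoint_and_sorted(self, rng):
        for _ in range(200):
            seq = random_sequence(rng)
            motifs = assemble_motifs(record(seq))
            prev_end = 0
            for m in motifs:
                assert m.start > prev_end
                assert m.end >= m.start
                assert len(m.anchors) >= 2
                prev_end = m.end

    def test_splitting_by_long_insert(self, rng):
        # 15 consecutive non-G residues inside an inter-anchor region always
        # break the motif in two (or leave a discarded single anchor)
        base = "RGGFRGGARGGRGG"
        for cut in range(4, 11):
            seq = base[:cut] + "A" * 15 + base[cut:]
            motifs = assemble_motifs(record(seq))
            assert all(
                not (m.start <= cut and m.end > cut + 15) for m in motifs
            )
            assert len(motifs) <= 2


class TestOracleEquivalence:
    def test_random_sequences_match_brute_force(self):
        rng = random.Random(99)
        for _ in range(300):
            seq = random_sequence(rng, max_len=120)
            got = [(m.start, m.end,
                    [(a.r_position, a.g_run) for a in m.anchors])
                   for m in assemble_motifs(record(seq))]
            want = [(s, e, list(chain)) for s, e, chain in oracle_motifs(seq)]
            assert got == want, seq


class TestBracketing:
    def test_no_motifs_unchanged(self):
        rec = record("AAAA")
        assert bracket_sequence(rec, []) == "AAAA"

    def test_single_span_direct_construction(self):
        from garfinder.engine import GarMotif
        rec = record("AARGRGAA")
        m = GarMotif("test", 3, 6, "RGRG", ())
        assert bracket_sequence(rec, [m]) == "AA[RGRG]AA"

    def test_leading_wildcard_absorbs_one_preceding_residue(self):
        # assembly itself claims one arbitrary residue adjacent to the R
        rec = record("AARGRGAA")
        (m,) = assemble_motifs(rec)
        assert bracket_sequence(rec, [m]) == "A[ARGRG]AA"

    def test_round_trip_strip(self, rng):
        for _ in range(100):
            seq = random_sequence(rng)
            rec = record(seq)
            echoed = bracket_sequence(rec, assemble_motifs(rec))
            assert echoed.replace("[", "").replace("]", "") == seq

    def test_inconsistent_coordinates_rejected(self):
        from garfinder.engine import GarMotif
        rec = record("AAAA")
        bogus = GarMotif("test", 2, 9, "AAA", ())
        with pytest.raises(ValueError):
            bracket_sequence(rec, [bogus])


@settings(max_examples=200, deadline=None)
@given(st.text(alphabet="GRAFSPD", min_size=0, max_size=80))
def test_idempotence_on_extracted_motifs(seq):
    # any motif found in any sequence, re-scanned alone, is found whole
    for m in assemble_motifs(record(seq)):
        (again,) = assemble_motifs(record(m.motif_sequence))
        assert (again.start, again.end) == (1, len(m.motif_sequence))
        assert [a.unit_class for a in again.anchors] == \
            [a.unit_class for a in m.anchors]


def test_idempotence_on_all_golden_strings(golden):
    for row in golden:
        (m,) = assemble_motifs(
            ProteinRecord(row.accession, "", row.motif_sequence))
        assert (m.start, m.end) == (1, row.length)
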