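"""Shared fixtures and the independent brute-force motif oracle.

The oracle re-derives motifs from first principles, sharing no code with the
engine: anchors are marked by direct inspection, each inter-anchor gap is
validated by exhaustive enumeration of every slot assignment of the grammar
G(1,2)-G(0,3)-X(0,5)-G(0,3)-X(0,1), chains are maximal runs of pairwise
valid anchors, and the leading/trailing rules are applied by enumeration.
"""

from __future__ import annotations

import random
from typing import List, Tuple

import pytest

from garfinder import ProteinRecord, all_golden_rows


def oracle_gap_valid(segment: str) -> bool:
    """Exhaustive slot-assignment search for the gap grammar."""
    n = len(segment)
    for g1 in (1, 2):
        for g2 in range(4):
            for x in range(6):
                for g3 in range(4):
                    for x2 in range(2):
                        if g1 + g2 + x + g3 + x2 != n:
                            continue
                        pos = 0
                        ok = all(c == "G" for c in segment[pos:pos + g1])
                        pos += g1
                        ok = ok and all(
                            c == "G" for c in segment[pos:pos + g2])
                        pos += g2 + x
                        ok = ok and all(
                            c == "G" for c in segment[pos:pos + g3])
                        if ok:
                            return True
    return False


def oracle_motifs(sequence: str) -> List[Tuple[int, int, List[Tuple[int, int]]]]:
    """Brute-force motif finding.

    Returns (start, end, [(r_position, g_run), ...]) triples with 1-based
    inclusive coordinates.
    """
    n = len(sequence)
    anchors = []
    for i, ch in enumerate(sequence):
        if ch == "R" and i + 1 < n and sequence[i + 1] == "G":
            g = 0
            while i + 1 + g < n and sequence[i + 1 + g] == "G":
                g += 1
            anchors.append((i + 1, g))  # 1-based R position

    motifs = []
    used_end = 0
    k = 0
    while k < len(anchors):
        j = k
        while (j + 1 < len(anchors)
               and oracle_gap_valid(sequence[anchors[j][0]:
                                             anchors[j + 1][0] - 1])):
            j += 1
        if j > k:
            chain = anchors[k:j + 1]
            first_r = chain[0][0]
            # leading context: longest suffix matching G(0,3)-X(0,1),
            # found by enumerating every (g, x) split
            best = 0
            for g in range(4):
                for x in range(2):
                    length = g + x
                    lo = first_r - 1 - length
                    if lo < used_end or length > first_r - 1:
                        continue
                    frag = sequence[lo:first_r - 1]
                    if all(c == "G" for c in frag[:g]) and len(frag) == length:
                        best = max(best, length)
            last_r, last_g = chain[-1]
            end = last_r + min(2, last_g)
            motifs.append((first_r - best, end, chain))
            used_end = end
        k = j + 1
    return motifs


@pytest.fixture(scope="session")
def golden():
    return all_golden_rows()


@pytest.fixture()
def rng():
    return random.Random(1234)


def random_sequence(rng: random.Random, max_len: int = 200) -> str:
    alphabet = "GRAFSPD"
    n = rng.randint(1, max_len)
    # bias toward G/R so motifs actually occur
    weights = [6, 4, 1, 1, 1, 1, 1]
    return "".join(rng.choices(alphabet, weights=weights, k=n))


def record(seq: str, ident: str = "test") -> ProteinRecord:
    return ProteinRecord(ident, "", seq)
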