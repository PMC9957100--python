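"""GAR motif detection engine.

A GAR (glycine- and arginine-rich) motif is a maximal chain of *anchor
units* — an arginine immediately followed by at least one glycine (``RG`` if
followed by exactly one motif-internal G, ``RGG`` if by two or more) — in
which the residue segment strictly between two consecutive anchor arginines
matches the bounded gap grammar::

    G(1,2) . G(0,3) . X(0,5) . G(0,3) . X(0,1)

where ``X`` is any residue (glycine included) and the numbers in parentheses
give the minimum/maximum repeat count of each slot.  The grammar admits at
most 14 residues between two chained arginines, of which at most 6 may be
non-glycine; it therefore tolerates long polyglycine tracts as well as short
stretches of other residues between the RG/RGG units.

A motif additionally carries leading context: the longest suffix of the
residues immediately preceding the first anchor that matches
``G(0,3)-X(0,1)`` (up to three glycines plus at most one arbitrary residue
adjacent to the arginine).  The motif ends with the last anchor's arginine
followed by at most two glycines, matching the terminal ``G(1,2)`` of the
pattern.  A chain must contain at least two anchors, so the shortest
reportable motif is ``RGRG``.

Arginines *not* followed by glycine ("bare" Rs) are never anchors; they are
ordinary residues that the wildcard slots may absorb.

Assembly is greedy and leftmost-maximal: chains are seeded at the leftmost
anchor not yet covered by an emitted motif and extended anchor-by-anchor as
long as the intervening segment satisfies the gap grammar; scanning resumes
after the emitted motif's end, and leading context never overlaps a
previously emitted motif.  Motifs of one record are consequently pairwise
disjoint and sorted by start position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Sequence

from .seq_io import ProteinRecord

#: Maximum residues strictly between two chained anchor arginines (2+3+5+3+1).
MAX_GAP_LEN = 14
#: Maximum non-glycine residues in a gap (5+1).
MAX_GAP_NON_G = 6
#: Minimum number of anchor units per motif.
MIN_UNITS = 2

# Gap between consecutive anchor Rs: G(1,2) G(0,3) X(0,5) G(0,3) X(0,1).
_GAP_RE = re.compile(r"G{1,2}G{0,3}[A-Z]{0,5}G{0,3}[A-Z]?")
# Leading context before the first anchor: G(0,3) X(0,1).
_LEAD_RE = re.compile(r"G{0,3}[A-Z]?")
#: Maximum length of the leading context.
MAX_LEAD_LEN = 4


@dataclass(frozen=True)
class AnchorUnit:
    """An arginine followed by >=1 glycine.

    ``r_position`` is the 1-based index of the R in the full sequence;
    ``g_run`` the number of consecutive glycines immediately following it.
    ``unit_class`` is derived from the glycines inside the motif span: since
    trailing glycines are capped at two, a truncated run of >=2 still
    classifies as RGG, so the class reduces to ``g_run == 1`` vs ``>= 2``.
    """

    r_position: int
    g_run: int

    @property
    def unit_class(self) -> str:
        return "RG" if self.g_run == 1 else "RGG"


@dataclass(frozen=True)
class GarMotif:
    """A maximal GAR motif span (1-based inclusive coordinates)."""

    record_identifier: str
    start: int
    end: int
    motif_sequence: str
    anchors: Sequence[AnchorUnit] = field(default_factory=tuple)

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def n_units(self) -> int:
        return len(self.anchors)


def find_anchors(sequence: str) -> List[AnchorUnit]:
    """Locate every anchor unit (R immediately followed by >=1 G), in order."""
    anchors = []
    n = len(sequence)
    i = 0
    while i < n:
        if sequence[i] == "R" and i + 1 < n and sequence[i + 1] == "G":
            j = i + 1
            while j < n and sequence[j] == "G":
                j += 1
            anchors.append(AnchorUnit(r_position=i + 1, g_run=j - i - 1))
        i += 1
    return anchors


def is_valid_gap(segment: str) -> bool:
    """Whether *segment* (residues strictly between two anchor Rs) matches
    the gap grammar for some slot assignment."""
    if not 1 <= len(segment) <= MAX_GAP_LEN:
        return False
    return _GAP_RE.fullmatch(segment) is not None


def _leading_length(sequence: str, first_r: int, floor: int) -> int:
    """Length of the longest qualifying leading context before anchor at
    1-based *first_r*, not reaching at or before 1-based position *floor*."""
    lo = max(floor, first_r - 1 - MAX_LEAD_LEN)  # 0-based exclusive lower bound
    for length in range(min(MAX_LEAD_LEN, first_r - 1 - lo), -1, -1):
        candidate = sequence[first_r - 1 - length:first_r - 1]
        if _LEAD_RE.fullmatch(candidate):
            return length
    return 0


def assemble_motifs(record: ProteinRecord) -> List[GarMotif]:
    """Find all maximal GAR motifs in *record*, left to right.

    Greedy assembly: seed at the leftmost unconsumed anchor, extend while the
    inter-anchor segment is grammar-valid, keep chains of >=2 anchors,
    prepend leading context (never overlapping a previous motif), append at
    most two trailing glycines, and resume scanning after the motif end.
    """
    seq = record.sequence
    anchors = find_anchors(seq)
    motifs: List[GarMotif] = []
    last_end = 0  # 1-based end of the previously emitted motif
    i = 0
    while i < len(anchors):
        seed = anchors[i]
        j = i
        while j + 1 < len(anchors):
            gap = seq[anchors[j].r_position:anchors[j + 1].r_position - 1]
            if not is_valid_gap(gap):
                break
            j += 1
        if j > i:
            chain = anchors[i:j + 1]
            lead = _leading_length(seq, seed.r_position, last_end)
            start = seed.r_position - lead
            last = chain[-1]
            end = last.r_position + min(2, last.g_run)
            motifs.append(GarMotif(
                record_identifier=record.identifier,
                start=start,
                end=end,
                motif_sequence=seq[start - 1:end],
                anchors=tuple(chain),
            ))
            last_end = end
        i = j + 1
    return motifs


def bracket_sequence(record: ProteinRecord, motifs: Sequence[GarMotif]) -> str:
    """Echo the full sequence with ``[`` / ``]`` around each motif span.

    Removing the brackets restores the sequence exactly.
    """
    seq = record.sequence
    out = []
    pos = 0  # 0-based cursor
    for m in motifs:
        if not (1 <= m.start <= m.end <= len(seq)) or m.start - 1 < pos:
            raise ValueError(
                f"motif {m.start}..{m.end} inconsistent with sequence "
                f"of length {len(seq)}"
            )
        out.append(seq[pos:m.start - 1])
        out.append("[")
        out.append(seq[m.start - 1:m.end])
        out.append("]")
        pos = m.end
    out.append(seq[pos:])
    return "".join(out)
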