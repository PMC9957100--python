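"""Proteome-scale census of long GAR motifs and motif classification.

Long GAR domains — the rare motifs carrying many RG/RGG units — are selected
by total unit count (default threshold 10, compared with >=).  Each motif is
labelled by *richness* (more RG than RGG units, the converse, or balanced)
and each sequence by the classic literature classification based on closely
spaced repeat elements: tri-RGG ``RGG(X0-4)RGG(X0-4)RGG``, di-RGG, tri-RG,
di-RG, tested in that priority order (a tri match always contains a di
match, so priority is essential).
"""

from __future__ import annotations

import csv
import enum
from typing import IO, Iterable, List, Sequence, Tuple

from .engine import find_anchors
from .reporting import MotifHit, ScanResult, format_else, iter_hits
from .stats import MotifStats

#: Default minimum RG+RGG units for the long-motif census.
DEFAULT_MIN_UNITS = 10

#: Maximum residues between consecutive repeat elements in the
#: tri/di classification.
CLASS_MAX_SPACING = 4


class Richness(str, enum.Enum):
    RG_RICH = "RG-rich"
    RGG_RICH = "RGG-rich"
    BALANCED = "balanced"


class Thandapani(str, enum.Enum):
    TRI_RGG = "tri-RGG"
    DI_RGG = "di-RGG"
    TRI_RG = "tri-RG"
    DI_RG = "di-RG"
    NONE = "none"


def filter_long_motifs(hits: Iterable[MotifHit],
                       min_units: int = DEFAULT_MIN_UNITS) -> List[MotifHit]:
    """Keep motifs with at least *min_units* RG+RGG units, order preserved."""
    if min_units < 2:
        raise ValueError("min_units must be >= 2")
    return [h for h in hits if h.stats.n_units >= min_units]


def classify_motif(stats: MotifStats) -> Richness:
    """Label a motif by its RG vs RGG unit balance."""
    if stats.rg_count > stats.rgg_count:
        return Richness.RG_RICH
    if stats.rgg_count > stats.rg_count:
        return Richness.RGG_RICH
    return Richness.BALANCED


def _has_chain(elements: Sequence[Tuple[int, int]], n: int) -> bool:
    """Whether *n* consecutive elements (start, end 0-based half-open spans)
    occur with <= CLASS_MAX_SPACING residues between consecutive spans."""
    run = 1
    for (s0, e0), (s1, e1) in zip(elements, elements[1:]):
        run = run + 1 if s1 - e0 <= CLASS_MAX_SPACING else 1
        if run >= n:
            return True
    return n == 1 and bool(elements)


def thandapani_class(sequence: str) -> Thandapani:
    """Highest-priority tri/di repeat class present anywhere in *sequence*.

    An RGG element is an arginine followed by >=2 glycines, an RG element an
    arginine followed by exactly one; an element spans the arginine and its
    whole glycine run, elements never overlap, and consecutive elements of a
    class may be separated by 0-4 arbitrary residues.
    """
    anchors = find_anchors(sequence)
    rgg = [(a.r_position - 1, a.r_position + a.g_run)
           for a in anchors if a.g_run >= 2]
    rg = [(a.r_position - 1, a.r_position + a.g_run)
          for a in anchors if a.g_run == 1]
    if _has_chain(rgg, 3):
        return Thandapani.TRI_RGG
    if _has_chain(rgg, 2):
        return Thandapani.DI_RGG
    if _has_chain(rg, 3):
        return Thandapani.TRI_RG
    if _has_chain(rg, 2):
        return Thandapani.DI_RG
    return Thandapani.NONE


def census(results: Sequence[ScanResult],
           min_units: int = DEFAULT_MIN_UNITS) -> List[MotifHit]:
    """Long-motif census rows, sorted by units descending then accession."""
    rows = filter_long_motifs(iter_hits(results), min_units)
    return sorted(rows, key=lambda h: (-h.stats.n_units,
                                       h.record.identifier,
                                       h.motif.start))


CENSUS_HEADER = [
    "Accession", "Pattern", "Position", "RG", "RGG", "Else",
    "Total%", "G/R", "G%", "R%", "Non-GR%",
    "units", "richness", "thandapani",
]


def write_census_csv(rows: Sequence[MotifHit], sink: IO[str]) -> None:
    """Census table: the standard per-motif columns plus units, richness and
    the tri/di repeat class of the full sequence."""
    writer = csv.writer(sink, lineterminator="\n")
    writer.writerow(CENSUS_HEADER)
    for hit in rows:
        s = hit.stats
        writer.writerow([
            hit.record.identifier,
            hit.motif.motif_sequence,
            f"{hit.motif.start}..{hit.motif.end}",
            s.rg_count, s.rgg_count, format_else(s.else_counts),
            f"{s.total_pct:.1f}", f"{s.g_to_r:.1f}", f"{s.g_pct:.1f}",
            f"{s.r_pct:.1f}", f"{s.non_gr_pct:.1f}",
            s.n_units,
            classify_motif(s).value,
            thandapani_class(hit.record.sequence).value,
        ])


def group_identical_motifs(hits: Iterable[MotifHit]) -> List[Tuple[str, int]]:
    """Group census rows whose motif sequence is identical.

    Returns (motif_sequence, group_size) pairs, largest groups first.  Useful
    as a rough proxy for isoform redundancy in proteome scans, where many
    entries are splice isoforms sharing the same motif.
    """
    counts: dict = {}
    for h in hits:
        counts[h.motif.motif_sequence] = counts.get(h.motif.motif_sequence, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
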