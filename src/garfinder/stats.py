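"""Per-motif composition statistics.

For each motif the report row gives: the number of RG and RGG units; the
"else" residues (motif residues that are neither G nor R, as residue→count
in first-occurrence order); the motif's coverage of the full polypeptide
(``Total%``); the glycine-to-arginine ratio (``G/R``); and the percentages
of G, R and other residues within the motif.  All derived values are printed
to one decimal.

Bare arginines (an R not followed by G) count toward the arginine total and
``R%`` but are neither units nor "else" residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Dict, Tuple

from .engine import GarMotif, MIN_UNITS


def round1(x: float) -> float:
    """Round to one decimal, exact ties going away from zero."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), ROUND_HALF_UP))


def _round1_ratio(num: int, den: int) -> float:
    """Exact one-decimal rounding of num/den (ties away from zero)."""
    f = Fraction(num * 10, den)
    floor = f.numerator // f.denominator
    rem = f - floor
    if rem > Fraction(1, 2) or (rem == Fraction(1, 2) and f >= 0):
        floor += 1
    return floor / 10


@dataclass(frozen=True)
class MotifStats:
    """One report row for a motif."""

    rg_count: int
    rgg_count: int
    else_counts: Dict[str, int]
    total_pct: float
    g_to_r: float
    g_pct: float
    r_pct: float
    non_gr_pct: float

    @property
    def n_units(self) -> int:
        return self.rg_count + self.rgg_count


def classify_units(motif: GarMotif) -> Tuple[int, int]:
    """Tally anchors into (rg_count, rgg_count)."""
    rg = sum(1 for a in motif.anchors if a.unit_class == "RG")
    return rg, len(motif.anchors) - rg


def residue_composition(motif: GarMotif) -> Tuple[int, int, Dict[str, int]]:
    """Counts of G, R (anchored or bare) and other residues in the motif.

    ``else_counts`` keys are ordered by first occurrence in the motif.
    """
    g = r = 0
    else_counts: Dict[str, int] = {}
    for ch in motif.motif_sequence:
        if ch == "G":
            g += 1
        elif ch == "R":
            r += 1
        else:
            else_counts[ch] = else_counts.get(ch, 0) + 1
    return g, r, else_counts


def compute_stats(motif: GarMotif, full_length: int) -> MotifStats:
    """Build the report row for *motif* within a protein of *full_length*."""
    length = len(motif)
    if full_length < length:
        raise ValueError(
            f"full_length {full_length} shorter than motif length {length}"
        )
    rg, rgg = classify_units(motif)
    assert rg + rgg >= MIN_UNITS
    g, r, else_counts = residue_composition(motif)
    assert r > 0  # >=2 anchors guarantee arginines
    return MotifStats(
        rg_count=rg,
        rgg_count=rgg,
        else_counts=else_counts,
        total_pct=_round1_ratio(100 * length, full_length),
        g_to_r=_round1_ratio(g, r),
        g_pct=_round1_ratio(100 * g, length),
        r_pct=_round1_ratio(100 * r, length),
        non_gr_pct=_round1_ratio(100 * sum(else_counts.values()), length),
    )
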