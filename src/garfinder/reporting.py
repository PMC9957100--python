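"""Report generation: CSV/text exports, batch summary and chart data."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from typing import IO, Dict, Iterable, List, Sequence, Tuple

from .engine import GarMotif, assemble_motifs, bracket_sequence
from .seq_io import ProteinRecord
from .stats import MotifStats, compute_stats, round1

CSV_HEADER = [
    "Accession", "Pattern", "Position", "RG", "RGG", "Else",
    "Total%", "G/R", "G%", "R%", "Non-GR%",
]


@dataclass(frozen=True)
class MotifHit:
    """One motif together with its record and statistics."""

    record: ProteinRecord
    motif: GarMotif
    stats: MotifStats


@dataclass(frozen=True)
class ScanResult:
    """All motifs found in one record."""

    record: ProteinRecord
    hits: Tuple[MotifHit, ...]


@dataclass(frozen=True)
class BatchSummary:
    n_sequences: int
    n_with_motifs: int
    pct_with_motifs: float
    total_rg: int
    total_rgg: int
    total_non_gr: Dict[str, int]


@dataclass(frozen=True)
class ChartData:
    """Pie percentages of RG vs RGG units, and the pooled non-GR residue
    bar counts (descending by count, ties alphabetical)."""

    rg_rgg_pie: Dict[str, float]
    non_gr_bar: List[Tuple[str, int]]


def scan_record(record: ProteinRecord) -> ScanResult:
    """Run motif detection and statistics on one record."""
    motifs = assemble_motifs(record)
    hits = tuple(
        MotifHit(record, m, compute_stats(m, len(record.sequence)))
        for m in motifs
    )
    return ScanResult(record, hits)


def analyze_records(records: Iterable[ProteinRecord]) -> List[ScanResult]:
    """Scan every record, preserving input order."""
    return [scan_record(r) for r in records]


def iter_hits(results: Iterable[ScanResult]) -> List[MotifHit]:
    return [h for res in results for h in res.hits]


def format_else(else_counts: Dict[str, int]) -> str:
    """Render else counts as ``'X': n`` pairs in first-occurrence order."""
    return ", ".join(f"'{aa}': {n}" for aa, n in else_counts.items())


def _fmt1(x: float) -> str:
    return f"{x:.1f}"


def write_csv(results: Sequence[ScanResult], sink: IO[str]) -> None:
    """Write the per-motif table, one row per motif in input order."""
    writer = csv.writer(sink, lineterminator="\n")
    writer.writerow(CSV_HEADER)
    for hit in iter_hits(results):
        s = hit.stats
        writer.writerow([
            hit.record.identifier,
            hit.motif.motif_sequence,
            f"{hit.motif.start}..{hit.motif.end}",
            s.rg_count,
            s.rgg_count,
            format_else(s.else_counts),
            _fmt1(s.total_pct),
            _fmt1(s.g_to_r),
            _fmt1(s.g_pct),
            _fmt1(s.r_pct),
            _fmt1(s.non_gr_pct),
        ])


def summarize_batch(results: Sequence[ScanResult]) -> BatchSummary:
    """Batch tallies over all scanned records."""
    n_sequences = len(results)
    n_with = sum(1 for r in results if r.hits)
    total_rg = total_rgg = 0
    pooled: Dict[str, int] = {}
    for hit in iter_hits(results):
        total_rg += hit.stats.rg_count
        total_rgg += hit.stats.rgg_count
        for aa, n in hit.stats.else_counts.items():
            pooled[aa] = pooled.get(aa, 0) + n
    pct = round1(100 * n_with / n_sequences) if n_sequences else 0.0
    return BatchSummary(n_sequences, n_with, pct, total_rg, total_rgg, pooled)


def write_txt(results: Sequence[ScanResult], summary: BatchSummary,
              sink: IO[str]) -> None:
    """Write the plain-text report: per record, each motif block followed by
    the bracketed full sequence; batch totals appended for multi-record
    input."""
    for res in results:
        sink.write(f">{res.record.identifier}")
        if res.record.description:
            sink.write(f" {res.record.description}")
        sink.write("\n")
        if not res.hits:
            sink.write("no GAR motif found\n")
            sink.write(res.record.sequence + "\n\n")
            continue
        for k, hit in enumerate(res.hits, 1):
            s = hit.stats
            sink.write(f"motif {k}\n")
            sink.write(f"  position: {hit.motif.start}..{hit.motif.end}\n")
            sink.write(f"  pattern: {hit.motif.motif_sequence}\n")
            sink.write(f"  RG: {s.rg_count}  RGG: {s.rgg_count}\n")
            sink.write(f"  else: {format_else(s.else_counts)}\n")
            sink.write(
                f"  Total%: {_fmt1(s.total_pct)}  G/R: {_fmt1(s.g_to_r)}"
                f"  G%: {_fmt1(s.g_pct)}  R%: {_fmt1(s.r_pct)}"
                f"  Non-GR%: {_fmt1(s.non_gr_pct)}\n"
            )
        motifs = [h.motif for h in res.hits]
        sink.write(bracket_sequence(res.record, motifs) + "\n\n")
    if summary.n_sequences > 1:
        sink.write("total statistics\n")
        sink.write(f"  input sequences: {summary.n_sequences}\n")
        sink.write(f"  sequences with GAR motifs: {summary.n_with_motifs}"
                   f" ({_fmt1(summary.pct_with_motifs)}%)\n")
        sink.write(f"  total RG: {summary.total_rg}"
                   f"  total RGG: {summary.total_rgg}\n")
        sink.write(f"  non-GR residues: {format_else(summary.total_non_gr)}\n")


def chart_data(results: Sequence[ScanResult]) -> ChartData:
    """Data behind the RG/RGG pie chart and the non-GR residue bar graph."""
    summary = summarize_batch(results)
    total_units = summary.total_rg + summary.total_rgg
    if total_units:
        rg_pct = round1(100 * summary.total_rg / total_units)
        pie = {"RG": rg_pct, "RGG": round1(100 - rg_pct)}
    else:
        pie = {}
    bar = sorted(summary.total_non_gr.items(), key=lambda kv: (-kv[1], kv[0]))
    return ChartData(rg_rgg_pie=pie, non_gr_bar=bar)


def write_chart_json(data: ChartData, sink: IO[str]) -> None:
    json.dump(
        {"pie": data.rg_rgg_pie,
         "bar": [[aa, n] for aa, n in data.non_gr_bar]},
        sink, indent=2,
    )
    sink.write("\n")


def render_charts(data: ChartData, path: str) -> None:
    """Optionally render pie + bar charts to an image file.

    Requires matplotlib (``garfinder[charts]``).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    if data.rg_rgg_pie:
        ax1.pie(list(data.rg_rgg_pie.values()),
                labels=list(data.rg_rgg_pie.keys()), autopct="%.1f%%")
    ax1.set_title("RG vs RGG units")
    if data.non_gr_bar:
        residues, counts = zip(*data.non_gr_bar)
        ax2.bar(residues, counts)
    ax2.set_title("non-GR residues")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
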