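"""FASTA input/output and sequence normalization.

Protein sequences arrive as single records, small batches, or whole-proteome
files.  Scanning operates on normalized sequences: uppercase residue letters
only, with stop codons (``*``) and alignment gap characters (``-``, ``.``)
silently removed (a warning is logged, since they are common in proteome
exports but can never be part of a motif).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, List

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

#: Characters stripped from sequences during normalization.
STRIP_CHARS = "*-."

_STRIP_TABLE = str.maketrans("", "", STRIP_CHARS + " \t\r\n")


class FastaFormatError(ValueError):
    """Raised when the input stream is not valid FASTA."""


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry.

    ``identifier`` is the first whitespace-delimited token of the header
    (without the leading ``>``); ``description`` is the remainder (possibly
    empty).  ``sequence`` is the normalized, uppercase residue string.
    """

    identifier: str
    description: str
    sequence: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


def normalize_sequence(raw: str, *, record_name: str = "<record>") -> str:
    """Uppercase *raw*, strip whitespace, stops and gap characters.

    Raises :class:`FastaFormatError` if anything other than letters remains.
    """
    stripped = raw.translate(_STRIP_TABLE)
    if len(stripped) != len("".join(raw.split())):
        logger.warning(
            "record %s: removed stop/gap characters during normalization",
            record_name,
        )
    seq = stripped.upper()
    if seq and not seq.isalpha():
        bad = sorted({c for c in seq if not c.isalpha()})
        raise FastaFormatError(
            f"record {record_name}: invalid sequence characters {bad!r}"
        )
    return seq


def read_fasta(stream: IO[str]) -> List[ProteinRecord]:
    """Parse a FASTA character stream into :class:`ProteinRecord` objects.

    Record order is preserved.  Sequence lines are concatenated and
    normalized.  Non-standard residue letters (B, J, O, U, X, Z) are retained;
    downstream they behave as ordinary non-G/non-R residues, which is what the
    pattern's wildcard slots expect.

    Duplicate identifiers are disambiguated with a numeric suffix
    (``#2``, ``#3`` ...) so that report rows remain keyed uniquely.

    Raises :class:`FastaFormatError` on an empty stream, text before the
    first ``>``, or a record with an empty sequence.
    """
    text = stream.read()
    if not text.strip():
        raise FastaFormatError("empty input: no FASTA records found")
    head = text.lstrip()
    if not head.startswith(">"):
        raise FastaFormatError(
            "input does not start with '>': text before the first record"
        )

    import io

    records: List[ProteinRecord] = []
    seen: dict = {}
    for title, raw_seq in SimpleFastaParser(io.StringIO(text)):
        parts = title.split(None, 1)
        if not parts:
            raise FastaFormatError("record with empty header line")
        identifier = parts[0]
        description = parts[1] if len(parts) > 1 else ""
        seq = normalize_sequence(raw_seq, record_name=identifier)
        if not seq:
            raise FastaFormatError(f"record {identifier}: empty sequence")
        if identifier in seen:
            seen[identifier] += 1
            logger.warning(
                "duplicate identifier %s disambiguated as %s#%d",
                identifier, identifier, seen[identifier],
            )
            identifier = f"{identifier}#{seen[identifier]}"
        else:
            seen[identifier] = 1
        records.append(ProteinRecord(identifier, description, seq))
    if not records:
        raise FastaFormatError("no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], stream: IO[str],
                width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at *width* columns."""
    for rec in records:
        header = rec.identifier
        if rec.description:
            header += " " + rec.description
        stream.write(f">{header}\n")
        for i in range(0, len(rec.sequence), width):
            stream.write(rec.sequence[i:i + width] + "\n")
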