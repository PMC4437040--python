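"""Computed annotations: lengths, compositions, codon usage, translation, revcomp.

Annotation tools append their results to record descriptions as tagged
fields (``len:407``, ``comp_A:120``, ``xl0:MKV...``), so downstream selection
and sorting tools can operate on computed properties without leaving the
FASTA stream.  Genetic codes are the NCBI translation tables as distributed
with Biopython; translation is gap-aware so aligned coding sequences can be
translated in place.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable

from Bio.Data import CodonTable

from fastools.errors import FastoolsError, UsageError
from fastools.record_io import SequenceRecord, append_tag

GAP_CHARS = set("-.")


def annotate_length(record: SequenceRecord) -> SequenceRecord:
    """Append ``len:<L>`` where L is the sequence length including gaps."""
    return append_tag(record, "len", str(len(record.sequence)))


@dataclass(frozen=True)
class CompositionTable:
    """Symbol counts of one sequence; ``sum(counts.values()) == total == length``."""

    counts: dict[str, int]
    total: int


def composition(record: SequenceRecord) -> CompositionTable:
    """Count every distinct sequence character (case-sensitive, gaps included)."""
    counts = Counter(record.sequence)
    return CompositionTable(dict(counts), len(record.sequence))


def annotate_composition(record: SequenceRecord) -> SequenceRecord:
    """Append one ``comp_<symbol>:<n>`` tag per observed symbol (sorted by symbol)."""
    table = composition(record)
    out = record
    for symbol in sorted(table.counts):
        out = append_tag(out, f"comp_{symbol}", str(table.counts[symbol]))
    return out


@dataclass(frozen=True)
class CodonUsage:
    """Codon tallies with the initial codon and a terminal stop counted distinctly.

    Every whole codon of the frame enters ``main``; the first codon is
    additionally tallied in ``start`` and a terminal stop codon in ``stop``,
    so ``sum(main.values())`` equals the number of whole codons.  A trailing
    remainder shorter than a codon is ignored and counted in ``remainder``.
    """

    main: dict[str, int]
    start: dict[str, int]
    stop: dict[str, int]
    remainder: int


def codon_usage(record: SequenceRecord, table_id: int = 1) -> CodonUsage:
    seq = record.sequence.upper().replace("U", "T")
    codons = [seq[i : i + 3] for i in range(0, len(seq) - 2, 3)]
    remainder = len(seq) % 3
    main: Counter = Counter(codons)
    start: Counter = Counter()
    stop: Counter = Counter()
    if codons:
        start[codons[0]] += 1
        if codons[-1] in set(_genetic_code(table_id).stop_codons):
            stop[codons[-1]] += 1
    return CodonUsage(dict(main), dict(start), dict(stop), remainder)


def _genetic_code(table_id: int) -> CodonTable.CodonTable:
    try:
        return CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError as exc:
        raise UsageError(f"unknown NCBI translation table {table_id}") from exc


def translate(
    sequence: str, frame: int = 0, table_id: int = 1, gap_aware: bool = True
) -> str:
    """Translate a nucleotide sequence in one reading frame.

    *frame* shifts the start by 0-2 positions.  With *gap_aware*, an all-gap
    codon translates to ``-`` and a codon containing 1-2 gap characters to
    ``X``, so gapped alignments translate column-consistently.  Unknown or
    ambiguous codons translate to ``X``; stops to ``*``.
    """
    if frame not in (0, 1, 2):
        raise UsageError(f"frame must be 0, 1 or 2, got {frame}")
    code = _genetic_code(table_id)
    forward = code.forward_table
    stops = set(code.stop_codons)
    seq = sequence[frame:]
    out: list[str] = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        gaps = sum(ch in GAP_CHARS for ch in codon)
        if gap_aware and gaps == 3:
            out.append("-")
            continue
        if gaps:
            out.append("X")
            continue
        key = codon.upper().replace("U", "T")
        if key in stops:
            out.append("*")
        elif key in forward:
            out.append(forward[key])
        else:
            out.append("X")
    return "".join(out)


def annotate_translation(
    record: SequenceRecord, frame: int = 0, table_id: int = 1
) -> SequenceRecord:
    """Append the frame-*frame* translation as an ``xl<frame>`` tag."""
    return append_tag(
        record, f"xl{frame}", translate(record.sequence, frame, table_id)
    )


# IUPAC nucleotide complements, both cases, plus gap characters.
_COMPLEMENT_UPPER = {
    "A": "T", "T": "A", "G": "C", "C": "G", "U": "A",
    "R": "Y", "Y": "R", "W": "W", "S": "S", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
    "-": "-", ".": ".",
}
COMPLEMENT = dict(_COMPLEMENT_UPPER)
COMPLEMENT.update({k.lower(): v.lower() for k, v in _COMPLEMENT_UPPER.items() if k.isalpha()})


def reverse_complement(sequence: str) -> str:
    """Reverse complement under the IUPAC complement table, preserving case.

    Raises on any character outside the IUPAC nucleotide alphabet (gaps
    allowed), naming the character.
    """
    out: list[str] = []
    for ch in reversed(sequence):
        try:
            out.append(COMPLEMENT[ch])
        except KeyError:
            raise FastoolsError(
                f"cannot complement non-IUPAC character {ch!r}"
            ) from None
    return "".join(out)


def reverse_complement_record(record: SequenceRecord) -> SequenceRecord:
    qual = record.quality[::-1] if record.quality is not None else None
    return replace(record, sequence=reverse_complement(record.sequence), quality=qual)


def composition_table_rows(
    records: Iterable[SequenceRecord],
) -> tuple[list[str], list[list[str]]]:
    """Tabular composition: header (identifier, total, one column per symbol) + rows."""
    tables = [(r.identifier, composition(r)) for r in records]
    symbols = sorted({s for _, t in tables for s in t.counts})
    header = ["identifier", "length"] + symbols
    rows = [
        [ident, str(t.total)] + [str(t.counts.get(s, 0)) for s in symbols]
        for ident, t in tables
    ]
    return header, rows
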