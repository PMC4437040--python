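"""The sequence-record data model: FASTA/FASTQ streams and the field algebra.

A record's header carries an identifier (the token after ``>`` or ``@``) and a
free-text description.  The description is treated as an ordered collection of
*fields* split on a configurable delimiter regex (default: runs of
whitespace).  The identifier is addressed as field 0, description fields as
1..m one-based, and negative indices count from the last field — the same
convention used for sequence coordinates throughout the package.

Fields of the form ``name=value`` or ``name:value`` are *tagged values*:
annotation tools append them and downstream tools select or sort on them by
name, so per-record analytics survive a pipeline without side channels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, TextIO

from fastools.errors import FieldResolutionError, ParseError, UsageError

DEFAULT_DELIMITER = r"\s+"
DEFAULT_WRAP = 60


@dataclass
class SequenceRecord:
    """One sequence record: identifier, description, sequence, optional quality.

    Invariants: the identifier is a non-empty whitespace-free token; when a
    quality string is present it has the same length as the sequence.  The
    sequence is stored contiguously regardless of line wrapping on disk, with
    character case preserved verbatim.
    """

    identifier: str
    description: str = ""
    sequence: str = ""
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.identifier or re.search(r"\s", self.identifier):
            raise ValueError(
                f"identifier must be a non-empty whitespace-free token: {self.identifier!r}"
            )
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"quality length {len(self.quality)} != sequence length "
                f"{len(self.sequence)} for record {self.identifier!r}"
            )

    @property
    def header(self) -> str:
        return f"{self.identifier} {self.description}" if self.description else self.identifier


@dataclass(frozen=True)
class FieldAddress:
    """Address of one record field: 0 = identifier, 1..m / negative = description fields."""

    index: int
    delimiter: str = DEFAULT_DELIMITER


def _compile_delimiter(delimiter: str) -> re.Pattern:
    try:
        return re.compile(delimiter)
    except re.error as exc:
        raise UsageError(f"invalid delimiter regex {delimiter!r}: {exc}") from exc


def fields_of(record: SequenceRecord, delimiter: str = DEFAULT_DELIMITER) -> list[str]:
    """Split the description into its ordered fields.

    Empty strings produced by delimiter matches at the very start or end of
    the description are dropped; an empty description yields an empty list.
    """
    pat = _compile_delimiter(delimiter)
    if record.description == "":
        return []
    parts = pat.split(record.description)
    if parts and parts[0] == "":
        parts = parts[1:]
    if parts and parts[-1] == "":
        parts = parts[:-1]
    return parts


def get_field(
    record: SequenceRecord, address: FieldAddress
) -> str:
    """Resolve a field address on a record.

    Index 0 is the identifier; positive indices are one-based description
    fields; negative indices count from the last field (-1 = last).  An index
    whose magnitude exceeds the field count fails with
    :class:`FieldResolutionError`; callers decide whether that aborts or is
    treated as an empty value.
    """
    if address.index == 0:
        return record.identifier
    fields = fields_of(record, address.delimiter)
    i = address.index
    if i > 0:
        if i <= len(fields):
            return fields[i - 1]
    else:
        if -i <= len(fields):
            return fields[i]
    raise FieldResolutionError(
        f"field index {i} out of range for record {record.identifier!r} "
        f"with {len(fields)} description field(s)"
    )


_TAG_SEPARATORS = ("=", ":")


def get_tag(
    record: SequenceRecord, name: str, delimiter: str = DEFAULT_DELIMITER
) -> str | None:
    """Return the value of the first ``name=value`` / ``name:value`` field, or None.

    Fields are scanned left to right; the first field whose name part equals
    *name* wins (duplicate tags resolve to the first occurrence).
    """
    for f in fields_of(record, delimiter):
        for sep in _TAG_SEPARATORS:
            pre, s, post = f.partition(sep)
            if s and pre == name:
                return post
    return None


def append_tag(
    record: SequenceRecord, name: str, value: str, separator: str = ":"
) -> SequenceRecord:
    """Return a copy of *record* with ``name<sep>value`` appended as a new final field."""
    if separator not in _TAG_SEPARATORS:
        raise UsageError(f"tag separator must be '=' or ':', got {separator!r}")
    if any(s in name for s in _TAG_SEPARATORS):
        raise UsageError(f"tag name {name!r} may not contain '=' or ':'")
    tag = f"{name}{separator}{value}"
    desc = f"{record.description} {tag}" if record.description else tag
    return replace(record, description=desc)


def strip_last_field(record: SequenceRecord) -> SequenceRecord:
    """Drop the final description field (inverse of :func:`append_tag`)."""
    fields = fields_of(record)
    return replace(record, description=" ".join(fields[:-1]))


# ---------------------------------------------------------------------------
# parsing


def _split_header(line: str, lineno: int, start_char: str) -> tuple[str, str]:
    body = line[1:].strip()
    if not body:
        raise ParseError(f"header {start_char!r} has no identifier", lineno)
    parts = body.split(None, 1)
    return parts[0], parts[1] if len(parts) > 1 else ""


def _parse_fasta(lines: Iterable[str]) -> Iterator[SequenceRecord]:
    identifier: str | None = None
    description = ""
    chunks: list[str] = []
    header_line = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if line.startswith(">"):
            if identifier is not None:
                yield SequenceRecord(identifier, description, "".join(chunks))
            identifier, description = _split_header(line, lineno, ">")
            header_line = lineno
            chunks = []
        else:
            if identifier is None:
                if line.strip() == "":
                    continue
                raise ParseError("sequence data before first '>' header", lineno)
            chunks.append(line.strip())
    if identifier is not None:
        yield SequenceRecord(identifier, description, "".join(chunks))
    del header_line


def _parse_fastq(lines: Iterable[str]) -> Iterator[SequenceRecord]:
    it = iter(lines)
    lineno = 0
    while True:
        try:
            raw = next(it)
        except StopIteration:
            return
        lineno += 1
        head = raw.rstrip("\n").rstrip("\r")
        if head.strip() == "":
            continue
        if not head.startswith("@"):
            raise ParseError(f"expected '@' header, got {head!r}", lineno)
        identifier, description = _split_header(head, lineno, "@")
        try:
            seq = next(it).rstrip("\n").rstrip("\r")
            lineno += 1
            plus = next(it).rstrip("\n").rstrip("\r")
            lineno += 1
            qual = next(it).rstrip("\n").rstrip("\r")
            lineno += 1
        except StopIteration:
            raise ParseError(
                f"truncated FASTQ record for {identifier!r}", lineno
            ) from None
        if not plus.startswith("+"):
            raise ParseError(f"expected '+' separator, got {plus!r}", lineno - 1)
        if len(qual) != len(seq):
            raise ParseError(
                f"quality length {len(qual)} != sequence length {len(seq)} "
                f"for record {identifier!r}",
                lineno,
            )
        yield SequenceRecord(identifier, description, seq, qual)


def parse_records(
    stream: TextIO | Iterable[str] | str, format: str = "fasta"
) -> Iterator[SequenceRecord]:
    """Parse a FASTA or FASTQ text stream into records, in input order.

    *stream* may be an open text file, any iterable of lines, or a string.
    Multi-line sequence bodies are concatenated; an empty stream yields no
    records and no error.  Malformed headers and FASTQ length mismatches
    raise :class:`ParseError` naming the offending line.
    """
    if isinstance(stream, str):
        stream = stream.splitlines(keepends=True)
    if format == "fasta":
        return _parse_fasta(stream)
    if format == "fastq":
        return _parse_fastq(stream)
    raise UsageError(f"unknown format {format!r} (expected 'fasta' or 'fastq')")


# ---------------------------------------------------------------------------
# serialization


def _wrap(seq: str, width: int) -> Iterator[str]:
    if width <= 0 or not seq:
        yield seq
        return
    for i in range(0, len(seq), width):
        yield seq[i : i + width]


def serialize_record(
    record: SequenceRecord, format: str = "fasta", wrap_width: int = DEFAULT_WRAP
) -> str:
    if format == "fasta":
        lines = [f">{record.header}"]
        if record.sequence:
            lines.extend(_wrap(record.sequence, wrap_width))
        return "\n".join(lines) + "\n"
    if format == "fastq":
        if record.quality is None:
            raise UsageError(
                f"record {record.identifier!r} has no quality; cannot emit FASTQ "
                "(convert with a default quality character first)"
            )
        return f"@{record.header}\n{record.sequence}\n+\n{record.quality}\n"
    raise UsageError(f"unknown format {format!r}")


def serialize_records(
    records: Iterable[SequenceRecord],
    format: str = "fasta",
    wrap_width: int = DEFAULT_WRAP,
) -> str:
    """Serialize records to text; ``parse_records`` of the result round-trips exactly.

    ``wrap_width`` 0 disables sequence-line wrapping (FASTA only; FASTQ is
    always 4 lines per record and the ``+`` line is emitted bare).
    """
    return "".join(serialize_record(r, format, wrap_width) for r in records)


def write_records(
    records: Iterable[SequenceRecord],
    out: TextIO,
    format: str = "fasta",
    wrap_width: int = DEFAULT_WRAP,
) -> None:
    for r in records:
        out.write(serialize_record(r, format, wrap_width))
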