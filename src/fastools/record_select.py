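"""Record-level selection, ordering and deduplication.

Implements the operations behind fasgrep (regex selection, with optional
IUPAC-ambiguity expansion of the pattern), fasfilter (numeric interval
filtering on captured values), fashead/fastail, fassort and fasuniq.  Each
tool addresses records through a :class:`TargetSelector` choosing the
identifier, description, sequence, a numbered description field, or a tagged
value by name.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from fastools.errors import FieldResolutionError, UsageError
from fastools.rangespec import IntervalSet
from fastools.record_io import (
    DEFAULT_DELIMITER,
    FieldAddress,
    SequenceRecord,
    append_tag,
    get_field,
    get_tag,
)

# IUPAC ambiguity letters expanded to bracket classes; strict letters map to
# themselves so expansion is idempotent.
IUPAC_NUCLEOTIDE = {
    "R": "[AG]",
    "Y": "[CT]",
    "W": "[AT]",
    "S": "[CG]",
    "K": "[GT]",
    "M": "[AC]",
    "B": "[CGT]",
    "D": "[AGT]",
    "H": "[ACT]",
    "V": "[ACG]",
    "N": "[ACGT]",
}
IUPAC_PROTEIN = {
    "B": "[DN]",
    "Z": "[EQ]",
    "X": "[A-Z]",
}


def expand_iupac(pattern: str, seqtype: str = "nucleotide") -> str:
    """Expand IUPAC ambiguity letters in a regex into bracket classes.

    Only letters outside character classes and not escaped are expanded, so
    regex metacharacters and explicit classes pass through untouched.  The
    expansion is idempotent: its output contains no expandable letters
    outside classes.
    """
    if seqtype == "nucleotide":
        table = IUPAC_NUCLEOTIDE
    elif seqtype == "protein":
        table = IUPAC_PROTEIN
    else:
        raise UsageError(f"unknown sequence type {seqtype!r}")
    out: list[str] = []
    in_class = False
    escaped = False
    for ch in pattern:
        if escaped:
            out.append(ch)
            escaped = False
            continue
        if ch == "\\":
            out.append(ch)
            escaped = True
            continue
        if in_class:
            out.append(ch)
            if ch == "]":
                in_class = False
            continue
        if ch == "[":
            out.append(ch)
            in_class = True
            continue
        out.append(table.get(ch, ch))
    return "".join(out)


@dataclass
class TargetSelector:
    """Selects the part of a record an operation works on.

    ``kind`` is one of ``identifier``, ``description``, ``sequence``,
    ``field`` (with one-based ``index``) or ``tag`` (with ``name``).  Field
    and tag resolution honour the delimiter regex.  Resolution failures
    (missing field or tag) yield the empty string and are counted in
    ``missing``, so a pipeline never aborts mid-stream on ragged
    descriptions.
    """

    kind: str = "identifier"
    index: int = 0
    name: str = ""
    delimiter: str = DEFAULT_DELIMITER
    missing: int = field(default=0, compare=False)

    def resolve(self, record: SequenceRecord) -> str:
        if self.kind == "identifier":
            return record.identifier
        if self.kind == "description":
            return record.description
        if self.kind == "sequence":
            return record.sequence
        if self.kind == "field":
            try:
                return get_field(record, FieldAddress(self.index, self.delimiter))
            except FieldResolutionError:
                self.missing += 1
                return ""
        if self.kind == "tag":
            value = get_tag(record, self.name, self.delimiter)
            if value is None:
                self.missing += 1
                return ""
            return value
        raise UsageError(f"unknown target kind {self.kind!r}")


def _compile(pattern: str, ignore_case: bool = False) -> re.Pattern:
    try:
        return re.compile(pattern, re.IGNORECASE if ignore_case else 0)
    except re.error as exc:
        raise UsageError(f"invalid regular expression {pattern!r}: {exc}") from exc


def grep_records(
    records: Iterable[SequenceRecord],
    pattern: str,
    target: TargetSelector | None = None,
    negate: bool = False,
    expand: bool = False,
    ignore_case: bool = False,
    seqtype: str = "nucleotide",
) -> Iterator[SequenceRecord]:
    """Emit exactly the records whose resolved target matches (XOR *negate*).

    Input order is preserved; with *expand*, IUPAC ambiguity codes in the
    pattern are expanded to bracket classes before compilation.
    """
    if expand:
        pattern = expand_iupac(pattern, seqtype)
    rx = _compile(pattern, ignore_case)
    target = target or TargetSelector()
    for record in records:
        if bool(rx.search(target.resolve(record))) != negate:
            yield record


def filter_numeric(
    records: Iterable[SequenceRecord],
    interval_set: IntervalSet,
    target: TargetSelector | None = None,
    capture_regex: str | None = None,
) -> Iterator[SequenceRecord]:
    """Keep records whose numeric value falls inside the interval set.

    With *capture_regex*, the value is the text of the left-most capture
    group of the first match on the resolved target; otherwise the whole
    target must parse as a number.  Records with no match, an empty capture,
    or an unparseable value are dropped.
    """
    rx = None
    if capture_regex is not None:
        rx = _compile(capture_regex)
        if rx.groups < 1:
            raise UsageError(
                f"capture regex {capture_regex!r} has no capture group (parentheses)"
            )
    target = target or TargetSelector()
    for record in records:
        text = target.resolve(record)
        if rx is not None:
            m = rx.search(text)
            if not m or m.group(1) is None:
                continue
            text = m.group(1)
        try:
            value = float(text)
        except ValueError:
            continue
        if value in interval_set:
            yield record


def take_records(
    records: Iterable[SequenceRecord], n: int, end: str = "head"
) -> Iterator[SequenceRecord]:
    """First (*head*) or last (*tail*) n records, in input order.

    Tail buffers at most n records.
    """
    if n < 0:
        raise UsageError("record count must be non-negative")
    if end == "head":
        for i, record in enumerate(records):
            if i >= n:
                break
            yield record
    elif end == "tail":
        yield from deque(records, maxlen=n or None) if n else iter(())
    else:
        raise UsageError(f"unknown end {end!r} (expected 'head' or 'tail')")


def sort_records(
    records: Iterable[SequenceRecord],
    target: TargetSelector | None = None,
    numeric: bool = False,
    reverse: bool = False,
) -> list[SequenceRecord]:
    """Stable sort by the resolved target key.

    Numeric sort parses keys as reals; keys that fail to parse sort after all
    parseable keys, preserving input order among themselves (also under
    *reverse*, which reverses only the parseable block's order).
    """
    target = target or TargetSelector()
    items = list(records)
    if numeric:
        parseable: list[tuple[float, SequenceRecord]] = []
        unparseable: list[SequenceRecord] = []
        for record in items:
            try:
                parseable.append((float(target.resolve(record)), record))
            except ValueError:
                unparseable.append(record)
        parseable.sort(key=lambda kv: kv[0], reverse=reverse)
        return [r for _, r in parseable] + unparseable
    keyed = sorted(
        range(len(items)), key=lambda i: target.resolve(items[i]), reverse=reverse
    )
    return [items[i] for i in keyed]


def uniq_records(
    records: Iterable[SequenceRecord],
    target: TargetSelector | None = None,
    count: bool = False,
) -> Iterator[SequenceRecord]:
    """Collapse maximal runs of consecutive records with equal resolved targets.

    Only immediately successive records are compared (sort first to
    deduplicate globally).  The first record of each run is emitted; with
    *count*, a ``uniq_count:<run length>`` tag is appended to it.
    """
    target = target or TargetSelector()
    run_first: SequenceRecord | None = None
    run_key: str | None = None
    run_len = 0

    def emit() -> SequenceRecord:
        assert run_first is not None
        return append_tag(run_first, "uniq_count", str(run_len)) if count else run_first

    for record in records:
        key = target.resolve(record)
        if run_first is not None and key == run_key:
            run_len += 1
            continue
        if run_first is not None:
            yield emit()
        run_first, run_key, run_len = record, key, 1
    if run_first is not None:
        yield emit()
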