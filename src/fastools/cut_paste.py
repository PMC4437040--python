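"""Index-based extraction (fascut) and record-parallel concatenation (faspaste).

fascut applies one index-range spec per record, against either sequence
positions or description fields, and outputs the concatenation of the
selections — repetition, reordering, reversal and stepped ranges included.
faspaste zips several record streams together record-by-record, joining one
unit (sequences or descriptions) across streams while taking everything else
from a designated receiver stream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Sequence

from fastools.errors import UsageError
from fastools.rangespec import IndexRangeSpec, resolve_indices
from fastools.record_io import DEFAULT_DELIMITER, SequenceRecord, fields_of

FIELD_JOIN = " "  # canonical delimiter when rebuilding descriptions from fields


def cut_record(
    record: SequenceRecord,
    spec: IndexRangeSpec,
    unit: str = "residues",
    delimiter: str = DEFAULT_DELIMITER,
) -> SequenceRecord:
    """Extract indexed residues or description fields from one record.

    ``unit='residues'``: the new sequence is the concatenation of the
    selected positions (quality, if present, is sliced in parallel);
    identifier and description are unchanged.  ``unit='fields'``: the
    description is rebuilt from the selected fields joined by single spaces;
    the sequence is unchanged.  Empty selections are permitted.
    """
    if unit == "residues":
        idx = resolve_indices(spec, len(record.sequence))
        seq = "".join(record.sequence[i - 1] for i in idx)
        qual = (
            "".join(record.quality[i - 1] for i in idx)
            if record.quality is not None
            else None
        )
        return replace(record, sequence=seq, quality=qual)
    if unit == "fields":
        fields = fields_of(record, delimiter)
        idx = resolve_indices(spec, len(fields))
        return replace(record, description=FIELD_JOIN.join(fields[i - 1] for i in idx))
    raise UsageError(f"unknown cut unit {unit!r} (expected 'residues' or 'fields')")


@dataclass(frozen=True)
class PasteSpec:
    """How to paste: which unit is concatenated and which stream is the template.

    ``receiver_stream`` (1-based) provides identifier, description and the
    non-pasted unit of every output record.  With ``repeat_first``, any
    stream holding exactly one record is recycled against every record of
    the longer streams (the way a single reference sequence is prepended to
    a whole file).
    """

    unit: str = "sequence"
    receiver_stream: int = 1
    repeat_first: bool = False


def paste_records(
    streams: Sequence[Sequence[SequenceRecord]], spec: PasteSpec = PasteSpec()
) -> Iterator[SequenceRecord]:
    """Concatenate one unit across parallel streams, record-by-record.

    Output record *i* carries the receiver stream's identifier, description
    and non-pasted unit; the pasted unit is the concatenation of the streams'
    unit values in argument order.  Without ``repeat_first`` all streams must
    have equal length; with it, single-record streams are recycled and the
    remaining streams must agree on length.
    """
    if len(streams) < 2:
        raise UsageError("faspaste needs at least two input streams")
    if not 1 <= spec.receiver_stream <= len(streams):
        raise UsageError(
            f"receiver stream {spec.receiver_stream} out of range 1..{len(streams)}"
        )
    if spec.unit not in ("sequence", "description"):
        raise UsageError(f"unknown paste unit {spec.unit!r}")
    lists = [list(s) for s in streams]
    lengths = [len(s) for s in lists]
    if spec.repeat_first:
        governing = [n for n in lengths if n != 1]
        out_len = governing[0] if governing else 1
        if any(n != out_len for n in governing):
            raise UsageError(
                f"unequal stream lengths {lengths} (streams of length 1 repeat; "
                "the rest must agree)"
            )
    else:
        out_len = min(lengths)
        if any(n != out_len for n in lengths):
            raise UsageError(
                f"unequal stream lengths {lengths}: shortest exhausted after "
                f"{out_len} record(s)"
            )

    def row(stream_i: int, record_i: int) -> SequenceRecord:
        s = lists[stream_i]
        return s[0] if spec.repeat_first and len(s) == 1 else s[record_i]

    recv = spec.receiver_stream - 1
    for i in range(out_len):
        template = row(recv, i)
        if spec.unit == "sequence":
            seq = "".join(row(j, i).sequence for j in range(len(lists)))
            yield replace(template, sequence=seq, quality=None)
        else:
            parts = [row(j, i).description for j in range(len(lists))]
            desc = FIELD_JOIN.join(p for p in parts if p != "")
            yield replace(template, description=desc)
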