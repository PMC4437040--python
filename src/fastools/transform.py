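"""Character transliteration, regex substitution, format conversion, tallies.

The transliteration engine (fastr) follows classic ``tr`` semantics:
positional character remapping over expanded ranges, deletion, squashing of
consecutive repeats, degapping, and remapping of every character outside a
strict alphabet to a chosen replacement (the standard way to neutralise
sequencing ambiguities before population-genetic analysis).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

from fastools.errors import UsageError
from fastools.record_io import SequenceRecord
from fastools.record_select import TargetSelector

STRICT_NUCLEOTIDE = set("ACGTacgt")
STRICT_PROTEIN = set("ACDEFGHIKLMNPQRSTVWYacdefghiklmnpqrstvwy")
GAP_CHAR = "-"


def expand_char_ranges(text: str) -> str:
    """Expand ``tr``-style range text ("A-Z", "acgt", "A-Za-z0-9") to explicit characters.

    A backslash escapes the next character; a ``-`` first or last is literal.
    """
    out: list[str] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "\\" and i + 1 < n:
            out.append(text[i + 1])
            i += 2
            continue
        if i + 2 < n and text[i + 1] == "-" and text[i + 2] != "\\":
            lo, hi = ord(ch), ord(text[i + 2])
            if lo > hi:
                raise UsageError(f"decreasing character range {text[i:i+3]!r}")
            out.extend(chr(c) for c in range(lo, hi + 1))
            i += 3
            continue
        out.append(ch)
        i += 1
    return "".join(out)


@dataclass(frozen=True)
class TransliterationSpec:
    """A fastr operation: from/to range text plus mode flags.

    The expanded to-set is padded by repeating its last character so the two
    sets align positionally; ``delete`` removes from-set characters instead;
    ``squash`` collapses runs of identical post-transliteration characters;
    ``degap`` removes the gap character "-".
    """

    from_set: str = ""
    to_set: str = ""
    delete: bool = False
    squash: bool = False
    degap: bool = False


def _build_table(spec: TransliterationSpec) -> dict[int, str | None]:
    table: dict[int, str | None] = {}
    src = expand_char_ranges(spec.from_set) if spec.from_set else ""
    if spec.delete:
        for ch in src:
            table[ord(ch)] = None
    elif src:
        dst = expand_char_ranges(spec.to_set)
        if not dst:
            raise UsageError("transliteration needs a to-set (or the delete flag)")
        dst = dst + dst[-1] * (len(src) - len(dst))
        for s, d in zip(src, dst):
            table[ord(s)] = d
    if spec.degap:
        table[ord(GAP_CHAR)] = None
    return table


def _squash(text: str) -> str:
    out: list[str] = []
    for ch in text:
        if not out or out[-1] != ch:
            out.append(ch)
    return "".join(out)


def transliterate(
    record: SequenceRecord,
    spec: TransliterationSpec,
    target: TargetSelector | None = None,
) -> SequenceRecord:
    """Apply a transliteration spec to one part of a record."""
    target = target or TargetSelector(kind="sequence")
    table = _build_table(spec)

    def apply(text: str) -> str:
        text = text.translate(table)
        return _squash(text) if spec.squash else text

    return _apply_to_target(record, target, apply)


def _apply_to_target(record, target: TargetSelector, fn) -> SequenceRecord:
    if target.kind == "sequence":
        new = fn(record.sequence)
        qual = record.quality if len(new) == len(record.sequence) else None
        return replace(record, sequence=new, quality=qual)
    if target.kind == "identifier":
        return replace(record, identifier=fn(record.identifier))
    if target.kind == "description":
        return replace(record, description=fn(record.description))
    raise UsageError(f"transformation target {target.kind!r} not supported")


def remap_strict(
    record: SequenceRecord, seqtype: str = "nucleotide", replacement_char: str = GAP_CHAR
) -> SequenceRecord:
    """Replace every sequence character outside the strict alphabet.

    Strict alphabets are case-preserving: ACGT/acgt for nucleotide, the 20
    canonical amino-acid letters in both cases for protein.  Everything else
    (ambiguity codes, gaps, punctuation) becomes *replacement_char*.
    """
    if len(replacement_char) != 1:
        raise UsageError("replacement must be a single character")
    if seqtype == "nucleotide":
        strict = STRICT_NUCLEOTIDE
    elif seqtype == "protein":
        strict = STRICT_PROTEIN
    else:
        raise UsageError(f"unknown sequence type {seqtype!r}")
    seq = "".join(ch if ch in strict else replacement_char for ch in record.sequence)
    return replace(record, sequence=seq)


_GROUP_REF = re.compile(r"\$(\d+)|\$\{(\d+)\}")


def perl_template_to_python(template: str) -> str:
    r"""Convert Perl-style ``$1``/``${1}`` capture references to Python ``\g<1>``."""
    return _GROUP_REF.sub(lambda m: rf"\g<{m.group(1) or m.group(2)}>", template)


def substitute(
    record: SequenceRecord,
    pattern: str,
    template: str,
    target: TargetSelector | None = None,
    global_: bool = False,
) -> SequenceRecord:
    """Regex substitution on one part of a record (first match, or all with *global_*).

    The template may reference capture groups Perl-style (``$1``).  A record
    whose target has no match is returned unchanged.
    """
    target = target or TargetSelector(kind="identifier")
    try:
        rx = re.compile(pattern)
        py_template = perl_template_to_python(template)
        re.sub(rx, py_template, "")  # validate group references up front
    except (re.error, IndexError) as exc:
        raise UsageError(
            f"invalid substitution {pattern!r} -> {template!r}: {exc}"
        ) from exc

    def apply(text: str) -> str:
        return rx.sub(py_template, text, count=0 if global_ else 1)

    return _apply_to_target(record, target, apply)


def tally(records: Iterable[SequenceRecord]) -> tuple[int, int]:
    """(record count, total residue count including gaps) of a stream."""
    n = residues = 0
    for record in records:
        n += 1
        residues += len(record.sequence)
    return n, residues


def convert(
    records: Iterable[SequenceRecord],
    to_format: str,
    default_quality_char: str | None = None,
) -> Iterator[SequenceRecord]:
    """Convert records between FASTA and FASTQ representations.

    FASTQ→FASTA drops quality; FASTA→FASTQ requires *default_quality_char*
    and fills the quality string with it at sequence length.
    """
    if to_format == "fasta":
        for record in records:
            yield replace(record, quality=None)
    elif to_format == "fastq":
        for record in records:
            if record.quality is not None:
                yield record
            elif default_quality_char is not None:
                if len(default_quality_char) != 1:
                    raise UsageError("default quality must be a single character")
                yield replace(record, quality=default_quality_char * len(record.sequence))
            else:
                raise UsageError(
                    f"record {record.identifier!r} has no quality and no default "
                    "quality character was given"
                )
    else:
        raise UsageError(f"unknown target format {to_format!r}")
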