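"""GenBank flat-file parsing and annotation-based sequence extraction (gbfcut).

Parses the LOCUS…FEATURES…ORIGIN…// layout into records carrying a feature
table, selects features by key regex plus qualifier constraints (conjunction;
a constraint may be negated), and extracts feature sequences — including
split (``join``) and reverse-strand (``complement``) locations — as FASTA
records.

The location grammar covered is the common subset ``a``, ``a..b``,
``complement(L)``, ``join(L1,L2,…)`` with ``<``/``>`` partial-end markers.
``order()``/``one-of()`` and locations referencing other entries
(``accession:start..end``) are rejected explicitly rather than silently
skipped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from fastools.errors import ParseError, UsageError
from fastools.annotate import reverse_complement
from fastools.record_io import SequenceRecord


@dataclass(frozen=True)
class FeatureLocation:
    """Segmented, possibly complemented 1-based inclusive coordinates."""

    segments: tuple[tuple[int, int], ...]
    complement: bool = False
    partial5: bool = False
    partial3: bool = False

    @property
    def span(self) -> int:
        return sum(end - start + 1 for start, end in self.segments)

    def text(self) -> str:
        inner = ",".join(
            str(a) if a == b else f"{a}..{b}" for a, b in self.segments
        )
        if len(self.segments) > 1:
            inner = f"join({inner})"
        return f"complement({inner})" if self.complement else inner


@dataclass
class GenBankFeature:
    """One feature-table entry: key, location, ordered qualifier multimap."""

    key: str
    location: FeatureLocation
    location_text: str
    qualifiers: list[tuple[str, str]] = field(default_factory=list)

    def qualifier_values(self, name: str) -> list[str]:
        return [v for n, v in self.qualifiers if n == name]


@dataclass
class GenBankRecord:
    locus: str
    definition: str
    features: list[GenBankFeature]
    origin: str


_UNSUPPORTED = ("order(", "one-of(", "bond(", "gap(")


def parse_location(text: str) -> FeatureLocation:
    """Parse a feature-location string into segments + strand/partial flags.

    Supports single bases, ``a..b`` ranges, ``complement()`` around the whole
    location, ``join()`` of ranges, and ``<``/``>`` partial markers.  Other
    INSDC operators and cross-entry references raise :class:`ParseError`
    ("unsupported location").
    """
    raw = text
    text = text.replace(" ", "")
    for op in _UNSUPPORTED:
        if op in text:
            raise ParseError(f"unsupported location operator in {raw!r}")
    complement = False
    if text.startswith("complement(") and text.endswith(")"):
        complement = True
        text = text[len("complement(") : -1]
    if "complement(" in text:
        raise ParseError(f"unsupported nested complement in {raw!r}")
    if text.startswith("join(") and text.endswith(")"):
        text = text[len("join(") : -1]
    if "(" in text or ")" in text:
        raise ParseError(f"unsupported location syntax {raw!r}")
    if ":" in text:
        raise ParseError(f"unsupported cross-entry location reference in {raw!r}")
    segments: list[tuple[int, int]] = []
    partial5 = partial3 = False
    parts = text.split(",")
    for i, part in enumerate(parts):
        m = re.fullmatch(r"(<?)(\d+)(?:\.\.(>?)(\d+))?", part)
        if not m:
            raise ParseError(f"unparseable location segment {part!r} in {raw!r}")
        start = int(m.group(2))
        end = int(m.group(4)) if m.group(4) is not None else start
        if start > end:
            raise ParseError(f"segment start {start} > end {end} in {raw!r}")
        if m.group(1) and i == 0:
            partial5 = True
        if m.group(3) and i == len(parts) - 1:
            partial3 = True
        segments.append((start, end))
    if not segments:
        raise ParseError(f"empty location {raw!r}")
    return FeatureLocation(tuple(segments), complement, partial5, partial3)


# ---------------------------------------------------------------------------
# flat-file parsing

_FEATURE_KEY = re.compile(r"^ {5}(\S+)\s+(\S.*)$")
_QUALIFIER = re.compile(r"^ {21}/([^=\s]+)(?:=(.*))?$")
_CONTINUATION = re.compile(r"^ {21}(\S.*)$")


def parse_genbank(stream: Iterable[str] | str) -> list[GenBankRecord]:
    """Parse one or more GenBank flat-file records from text.

    Feature locations and qualifier values spanning continuation lines are
    joined; quotes around qualifier values are stripped; ORIGIN sequence
    lines are concatenated with coordinates and whitespace removed.  A
    record with features but no ORIGIN sequence, or an unterminated record,
    is an error.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in stream]
    records: list[GenBankRecord] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if not line.startswith("LOCUS"):
            raise ParseError(f"expected LOCUS line, got {line!r}", i + 1)
        parts = line.split()
        if len(parts) < 2:
            raise ParseError("LOCUS line has no locus name", i + 1)
        locus = parts[1]
        definition = ""
        features: list[GenBankFeature] = []
        origin_parts: list[str] = []
        saw_origin = False
        terminated = False
        i += 1
        while i < n:
            line = lines[i]
            if line.startswith("//"):
                terminated = True
                i += 1
                break
            if line.startswith("DEFINITION"):
                def_parts = [line[len("DEFINITION") :].strip()]
                i += 1
                while i < n and lines[i].startswith(" "):
                    def_parts.append(lines[i].strip())
                    i += 1
                definition = " ".join(p for p in def_parts if p)
                continue
            if line.startswith("FEATURES"):
                i += 1
                i = _parse_feature_table(lines, i, features)
                continue
            if line.startswith("ORIGIN"):
                saw_origin = True
                i += 1
                while i < n and not lines[i].startswith("//"):
                    origin_parts.append(re.sub(r"[\s\d]", "", lines[i]))
                    i += 1
                continue
            i += 1
        if not terminated:
            raise ParseError(f"unterminated record {locus!r} (missing '//')")
        origin = "".join(origin_parts)
        if features and not saw_origin:
            raise ParseError(f"record {locus!r} has features but no ORIGIN sequence")
        records.append(GenBankRecord(locus, definition, features, origin))
    return records


def _parse_feature_table(
    lines: list[str], i: int, features: list[GenBankFeature]
) -> int:
    n = len(lines)
    while i < n:
        line = lines[i]
        if line.startswith("//") or (line and not line.startswith(" ")):
            return i
        m = _FEATURE_KEY.match(line)
        if m:
            key, loc_text = m.group(1), m.group(2).strip()
            i += 1
            # location continuation lines precede the first qualifier
            while i < n:
                cm = _CONTINUATION.match(lines[i])
                if cm and not cm.group(1).startswith("/"):
                    loc_text += cm.group(1).strip()
                    i += 1
                else:
                    break
            qualifiers: list[tuple[str, str]] = []
            while i < n:
                qm = _QUALIFIER.match(lines[i])
                if not qm:
                    break
                qname = qm.group(1)
                qvalue = qm.group(2)
                i += 1
                if qvalue is None:
                    qualifiers.append((qname, ""))
                    continue
                quoted = qvalue.startswith('"')
                while quoted and not (len(qvalue) > 1 and qvalue.endswith('"')):
                    cm = _CONTINUATION.match(lines[i]) if i < n else None
                    if cm is None or cm.group(1).startswith("/"):
                        break
                    qvalue += " " + cm.group(1).strip()
                    i += 1
                if quoted and qvalue.endswith('"'):
                    qvalue = qvalue[1:-1]
                qualifiers.append((qname, qvalue))
            features.append(
                GenBankFeature(key, parse_location(loc_text), loc_text, qualifiers)
            )
        else:
            i += 1
    return i


# ---------------------------------------------------------------------------
# selection and extraction


@dataclass(frozen=True)
class QualifierConstraint:
    """Require (or forbid) a qualifier of *name* whose value matches *pattern*."""

    name: str
    pattern: str
    must_match: bool = True

    @classmethod
    def parse(cls, text: str) -> "QualifierConstraint":
        """Parse the CLI forms ``name=regex`` (must match) / ``name^regex`` (must not)."""
        for sep, positive in (("=", True), ("^", False)):
            name, s, pattern = text.partition(sep)
            if s and name:
                return cls(name, pattern, positive)
        raise UsageError(
            f"qualifier constraint {text!r} must have the form name=REGEX or name^REGEX"
        )


def feature_matches(
    feature: GenBankFeature,
    key_regex: str = ".",
    constraints: Iterable[QualifierConstraint] = (),
) -> bool:
    """True iff the key matches and every qualifier constraint is satisfied.

    A must-match constraint needs at least one qualifier of that name whose
    value matches; a must-not-match constraint needs no qualifier of that
    name whose value matches.  Constraints combine by conjunction.
    """
    if not re.search(key_regex, feature.key):
        return False
    for c in constraints:
        values = feature.qualifier_values(c.name)
        hit = any(re.search(c.pattern, v) for v in values)
        if hit != c.must_match:
            return False
    return True


def extract_feature(origin_sequence: str, location: FeatureLocation) -> str:
    """Extract a feature's sequence: segments concatenated in written order,
    then reverse-complemented as a whole if the location is complemented."""
    n = len(origin_sequence)
    parts: list[str] = []
    for start, end in location.segments:
        if not (1 <= start <= end <= n):
            raise ParseError(
                f"location segment {start}..{end} outside sequence of length {n}"
            )
        parts.append(origin_sequence[start - 1 : end])
    joined = "".join(parts)
    return reverse_complement(joined) if location.complement else joined


def cut_features(
    records: Iterable[GenBankRecord],
    key_regex: str = ".",
    constraints: Iterable[QualifierConstraint] = (),
    name_qualifiers: tuple[str, ...] = ("gene", "product", "note"),
) -> Iterator[SequenceRecord]:
    """Extract all matching features of all records as FASTA records.

    Output identifiers are ``<locus>_<key>_<k>`` with *k* a per-key ordinal,
    guaranteeing uniqueness within a run; descriptions carry the location
    string and the values of a few descriptive qualifiers.
    """
    constraints = list(constraints)
    try:
        re.compile(key_regex)
    except re.error as exc:
        raise UsageError(f"invalid key regex {key_regex!r}: {exc}") from exc
    for record in records:
        ordinals: dict[str, int] = {}
        for feature in record.features:
            if not feature_matches(feature, key_regex, constraints):
                continue
            ordinals[feature.key] = ordinals.get(feature.key, 0) + 1
            ident = f"{record.locus}_{feature.key}_{ordinals[feature.key]}"
            desc_parts = [feature.location_text]
            for q in name_qualifiers:
                for v in feature.qualifier_values(q):
                    desc_parts.append(f'{q}="{v}"')
            yield SequenceRecord(
                re.sub(r"\s", "_", ident),
                " ".join(desc_parts),
                extract_feature(record.origin, feature.location),
            )
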