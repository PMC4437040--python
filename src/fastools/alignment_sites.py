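"""Alignment-column classification and selection (alncut, gbfalncut).

Columns of a gapped alignment are classified by content — gap count,
all-gap, invariant vs variable, parsimony-informative — and selected by
class or its complement, optionally with a per-site tolerance threshold.
Feature projection maps GenBank feature coordinates on one (gapped) member
row to the corresponding alignment columns, so annotated regions can be
sliced out of an alignment without manual coordinate bookkeeping.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from fastools.errors import FastoolsError, UsageError
from fastools.genbank import FeatureLocation, GenBankRecord
from fastools.record_io import SequenceRecord

GAP_CHARS = set("-.")


@dataclass
class AlignmentMatrix:
    """Equal-length gapped rows addressed as columns 1..width."""

    rows: list[SequenceRecord]

    def __post_init__(self) -> None:
        widths = {len(r.sequence) for r in self.rows}
        if len(widths) > 1:
            raise FastoolsError(
                f"ragged alignment: row lengths {sorted(widths)} differ"
            )

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0].sequence) if self.rows else 0

    def column(self, j: int) -> str:
        """Column *j* (1-based) as a string of n characters."""
        return "".join(r.sequence[j - 1] for r in self.rows)

    def take_columns(self, columns: Sequence[int]) -> "AlignmentMatrix":
        """New alignment restricted to the given 1-based columns, in the given order."""
        return AlignmentMatrix(
            [
                replace(
                    r,
                    sequence="".join(r.sequence[j - 1] for j in columns),
                    quality=None,
                )
                for r in self.rows
            ]
        )

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "AlignmentMatrix":
        return cls(list(records))


@dataclass(frozen=True)
class ColumnClass:
    """Content classification of one column.

    For columns with at least one non-gap symbol, invariant and variable are
    mutually exclusive; all-gap columns are neither.  Parsimony-informative
    implies variable.
    """

    gap_count: int
    all_gap: bool
    invariant: bool
    variable: bool
    parsimony_informative: bool


def classify_columns(aln: AlignmentMatrix) -> list[ColumnClass]:
    """Classify every column of the alignment.

    A column is invariant iff all its non-gap symbols are identical,
    variable otherwise, and parsimony-informative iff at least two distinct
    non-gap symbols each occur at least twice.  Comparison is case-sensitive;
    ambiguity codes count as ordinary states (remap them upstream if they
    should be ignored).
    """
    if aln.n < 1:
        raise UsageError("alignment must have at least one row")
    out: list[ColumnClass] = []
    for j in range(1, aln.width + 1):
        col = aln.column(j)
        counts = Counter(ch for ch in col if ch not in GAP_CHARS)
        gap_count = len(col) - sum(counts.values())
        all_gap = not counts
        invariant = len(counts) == 1
        variable = len(counts) > 1
        informative = sum(1 for c in counts.values() if c >= 2) >= 2
        out.append(ColumnClass(gap_count, all_gap, invariant, variable, informative))
    return out


_MODES = ("invariant", "variable", "gapfree", "nonallgap", "parsinf")


def column_mask(
    aln: AlignmentMatrix,
    mode: str = "invariant",
    invert: bool = False,
    threshold: int = 0,
) -> list[int]:
    """1-based columns satisfying *mode* (complemented by *invert*).

    The threshold relaxes a mode per site: gapfree keeps columns with at
    most *threshold* gapped rows; invariant tolerates up to *threshold* rows
    deviating from the column's majority non-gap state.
    """
    if mode not in _MODES:
        raise UsageError(f"unknown column mode {mode!r} (expected one of {_MODES})")
    if threshold < 0:
        raise UsageError("threshold must be non-negative")
    kept: list[int] = []
    for j, cls in enumerate(classify_columns(aln), start=1):
        if mode == "gapfree":
            keep = cls.gap_count <= threshold
        elif mode == "nonallgap":
            keep = not cls.all_gap
        elif mode == "parsinf":
            keep = cls.parsimony_informative
        elif mode == "invariant":
            if threshold and not cls.all_gap:
                counts = Counter(
                    ch for ch in aln.column(j) if ch not in GAP_CHARS
                )
                deviants = sum(counts.values()) - max(counts.values())
                keep = deviants <= threshold
            else:
                keep = cls.invariant
        else:  # variable
            keep = cls.variable
        if keep != invert:
            kept.append(j)
    return kept


def select_columns(
    aln: AlignmentMatrix,
    mode: str = "invariant",
    invert: bool = False,
    threshold: int = 0,
) -> AlignmentMatrix:
    """Alignment restricted to the columns of :func:`column_mask` (order kept)."""
    return aln.take_columns(column_mask(aln, mode, invert, threshold))


def ungapped_to_column_map(gapped_sequence: str) -> dict[int, int]:
    """Map each 1-based ungapped position of a row to its 1-based column."""
    mapping: dict[int, int] = {}
    k = 0
    for j, ch in enumerate(gapped_sequence, start=1):
        if ch not in GAP_CHARS:
            k += 1
            mapping[k] = j
    return mapping


def find_reference_row(aln: AlignmentMatrix, accession: str, origin: str) -> int:
    """Locate the alignment row corresponding to a GenBank record.

    Primary rule: the accession (version suffix stripped) appears in the row
    identifier.  Fallback: the degapped row equals the origin sequence
    case-insensitively.  Returns a 0-based row index.
    """
    bare = accession.split(".")[0]
    hits = [i for i, r in enumerate(aln.rows) if bare and bare in r.identifier]
    if len(hits) == 1:
        return hits[0]
    if len(hits) > 1:
        raise FastoolsError(
            f"accession {accession!r} matches several rows: "
            + ", ".join(aln.rows[i].identifier for i in hits)
        )
    target = origin.upper()
    for i, r in enumerate(aln.rows):
        degapped = "".join(ch for ch in r.sequence if ch not in GAP_CHARS)
        if degapped.upper() == target:
            return i
    raise FastoolsError(
        f"no alignment row matches accession {accession!r} or its sequence; "
        "candidate identifiers: " + ", ".join(r.identifier for r in aln.rows)
    )


def project_feature(
    aln: AlignmentMatrix, reference_row: int, location: FeatureLocation
) -> list[int]:
    """Columns (ascending, 1-based) covered by feature coordinates on the reference row."""
    mapping = ungapped_to_column_map(aln.rows[reference_row].sequence)
    columns: set[int] = set()
    for start, end in location.segments:
        for pos in range(start, end + 1):
            if pos not in mapping:
                raise FastoolsError(
                    f"feature coordinate {pos} beyond degapped reference length "
                    f"{len(mapping)}"
                )
            columns.add(mapping[pos])
    return sorted(columns)


def cut_by_features(
    aln: AlignmentMatrix,
    gb: GenBankRecord,
    key_regex: str = ".",
) -> AlignmentMatrix:
    """Restrict an alignment to the columns of all features matching *key_regex*.

    The reference row is located by the GenBank locus/accession appearing in
    a row identifier (fallback: exact degapped-sequence match), and its
    degapped residues are checked against the ORIGIN sequence over the
    feature's coordinates before projection.
    """
    from fastools.genbank import feature_matches

    row = find_reference_row(aln, gb.locus, gb.origin)
    mapping = ungapped_to_column_map(aln.rows[row].sequence)
    ref_seq = aln.rows[row].sequence
    columns: set[int] = set()
    matched = False
    for feature in gb.features:
        if not feature_matches(feature, key_regex):
            continue
        matched = True
        for start, end in feature.location.segments:
            for pos in range(start, end + 1):
                if pos not in mapping:
                    raise FastoolsError(
                        f"feature coordinate {pos} beyond degapped reference "
                        f"length {len(mapping)}"
                    )
                col = mapping[pos]
                if gb.origin and pos <= len(gb.origin):
                    if ref_seq[col - 1].upper() != gb.origin[pos - 1].upper():
                        raise FastoolsError(
                            f"reference row disagrees with ORIGIN at position {pos}"
                        )
                columns.add(col)
    if not matched:
        raise FastoolsError(
            f"no feature key matches {key_regex!r} in record {gb.locus!r}"
        )
    return aln.take_columns(sorted(columns))
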