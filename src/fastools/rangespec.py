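"""Range dialects for index selection and numeric filtering.

Three comma-separable dialects coexist, mirroring the conventions users
already know: GenBank/Perl ``from..to``, R/Octave ``from:to`` (optionally
``from:to:by``), and Unix-cut ``from-to``.  Index ranges drive positional
extraction (fascut) and support repetition, reordering, reversal and variable
steps; interval sets drive numeric record filtering (fasfilter) and support
scientific notation plus open ends (``100-`` means "at least 100", ``-100``
means "at most 100").  All finite interval endpoints are inclusive.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from fastools.errors import UsageError

_INT = r"[+-]?\d+"
_NUM = r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?"

_RE_INT_DOTDOT = re.compile(rf"^({_INT})\.\.({_INT})$")
_RE_INT_COLON = re.compile(rf"^({_INT}):({_INT})(?::({_INT}))?$")
_RE_INT_CUT = re.compile(rf"^({_INT})-({_INT})$")
_RE_INT_SINGLE = re.compile(rf"^({_INT})$")

_RE_NUM_DOTDOT = re.compile(rf"^({_NUM})\.\.({_NUM})$")
_RE_NUM_COLON = re.compile(rf"^({_NUM}):({_NUM})$")
_RE_NUM_CUT = re.compile(rf"^({_NUM})-({_NUM})$")
_RE_NUM_OPEN_HI = re.compile(rf"^({_NUM})-$")
_RE_NUM_OPEN_LO = re.compile(rf"^-({_NUM})$")
_RE_NUM_SINGLE = re.compile(rf"^({_NUM})$")


@dataclass(frozen=True)
class IndexRangeSpec:
    """Ordered index-range segments (start, end, by); ``by`` None = direction default.

    Segments preserve user order and duplicates.  Negative endpoints count
    from the end of the addressed object (-1 = last).  When ``by`` is omitted
    it defaults, after endpoint resolution, to +1 for ascending segments and
    -1 for descending ones, so ``3..1`` is a reversal rather than empty.
    """

    segments: tuple[tuple[int, int, int | None], ...]


def parse_index_ranges(text: str) -> IndexRangeSpec:
    """Parse comma-separated index-range text in any of the three dialects."""
    segments: list[tuple[int, int, int | None]] = []
    if text.strip() == "":
        raise UsageError("empty range specification")
    for seg in text.split(","):
        seg = seg.strip()
        if seg == "":
            raise UsageError(f"empty segment in range specification {text!r}")
        m = _RE_INT_DOTDOT.match(seg)
        if m:
            segments.append((int(m.group(1)), int(m.group(2)), None))
            continue
        m = _RE_INT_COLON.match(seg)
        if m:
            by = int(m.group(3)) if m.group(3) is not None else None
            if by == 0:
                raise UsageError(f"step of 0 in segment {seg!r}")
            segments.append((int(m.group(1)), int(m.group(2)), by))
            continue
        m = _RE_INT_CUT.match(seg)
        if m:
            segments.append((int(m.group(1)), int(m.group(2)), None))
            continue
        m = _RE_INT_SINGLE.match(seg)
        if m:
            i = int(m.group(1))
            segments.append((i, i, None))
            continue
        raise UsageError(f"unparseable range segment {seg!r}")
    return IndexRangeSpec(tuple(segments))


def _resolve_endpoint(value: int, length: int) -> int:
    # negative indices count from the end: -1 = last
    return length + 1 + value if value < 0 else value


def resolve_indices(spec: IndexRangeSpec, length: int) -> list[int]:
    """Expand a spec against an object of *length* into ordered 1-based indices.

    Each segment is enumerated start, start+by, ... without passing end;
    indices falling outside 1..length are dropped silently so one spec can be
    applied across records of varying length.  Concatenation across segments
    preserves order and duplicates; the result may be empty.
    """
    if length < 1:
        return []
    out: list[int] = []
    for start, end, by in spec.segments:
        a = _resolve_endpoint(start, length)
        b = _resolve_endpoint(end, length)
        step = by if by is not None else (1 if a <= b else -1)
        if step > 0:
            i = a
            while i <= b:
                if 1 <= i <= length:
                    out.append(i)
                i += step
        else:
            i = a
            while i >= b:
                if 1 <= i <= length:
                    out.append(i)
                i += step
    return out


@dataclass(frozen=True)
class IntervalSet:
    """Union of closed real intervals; infinite ends encode open ranges."""

    intervals: tuple[tuple[float, float], ...]

    def __contains__(self, x: float) -> bool:
        return any(lo <= x <= hi for lo, hi in self.intervals)


def parse_interval_set(text: str) -> IntervalSet:
    """Parse comma-separated numeric ranges into an :class:`IntervalSet`.

    Accepts ``a..b``, ``a:b``, ``a-b``, open forms ``a-`` / ``-b`` and bare
    numbers (degenerate point intervals); numerals may use scientific
    notation.  A finite interval with low > high is an error.
    """
    intervals: list[tuple[float, float]] = []
    if text.strip() == "":
        raise UsageError("empty interval specification")
    for seg in text.split(","):
        seg = seg.strip()
        if seg == "":
            raise UsageError(f"empty segment in interval specification {text!r}")
        for pat in (_RE_NUM_DOTDOT, _RE_NUM_COLON, _RE_NUM_CUT):
            m = pat.match(seg)
            if m:
                lo, hi = float(m.group(1)), float(m.group(2))
                break
        else:
            m = _RE_NUM_OPEN_HI.match(seg)
            if m:
                lo, hi = float(m.group(1)), math.inf
            else:
                m = _RE_NUM_OPEN_LO.match(seg)
                if m:
                    lo, hi = -math.inf, float(m.group(1))
                else:
                    m = _RE_NUM_SINGLE.match(seg)
                    if m:
                        lo = hi = float(m.group(1))
                    else:
                        raise UsageError(f"unparseable interval segment {seg!r}")
        if lo > hi:
            raise UsageError(f"interval low {lo} > high {hi} in segment {seg!r}")
        intervals.append((lo, hi))
    return IntervalSet(tuple(intervals))


def interval_contains(interval_set: IntervalSet, x: float) -> bool:
    """True iff *x* lies in any interval of the set (finite ends closed)."""
    return x in interval_set
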