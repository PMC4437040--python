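"""Molecular population-genetic statistics per alignment (alnpi).

Given an alignment of n sequences over L usable sites this module computes
the classical summary statistics of within-population variation:

* S, s — number and fraction of segregating sites;
* k — number of distinct sequences (alleles);
* eta — total mutation count, summing (distinct states - 1) per column;
* eta_S — singleton mutations: states seen in exactly one sequence at a
  segregating column;
* Pi, pi — mean pairwise differences per locus (Nei & Li) and per site;
* theta_W — Watterson's estimator S/a1 with a1 the (n-1)-th harmonic number;
* E(K) — Ewens' expected allele count under the infinite-alleles model;
* Tajima's D — the normalised difference Pi - theta_W;
* Fu & Li's D* and F* — outgroup-free neutrality tests contrasting singleton
  mutations with total mutations (D*) or with pairwise diversity (F*), using
  the corrected variance coefficients of Simonsen, Churchill & Aquadro
  (1995).

Undefined statistics (no variation, or n below the minimum the coefficients
need) are reported as None and rendered ``NA`` in tabular output, never as 0.

The default site policy is complete deletion: columns containing any gap or
non-strict nucleotide are excluded before counting, matching the common
workflow in which ambiguities are remapped to gaps and gapped sites removed
upstream.  ``policy='as_is'`` treats every column as usable and every
distinct character as a state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from fastools.alignment_sites import AlignmentMatrix, GAP_CHARS
from fastools.errors import UsageError
from fastools.transform import STRICT_NUCLEOTIDE

__all__ = [
    "PopGenSummary",
    "usable_columns",
    "basic_counts",
    "mean_pairwise",
    "watterson",
    "tajima_D",
    "fu_li_Dstar",
    "fu_li_Fstar",
    "ewens_EK",
    "summarize",
    "sliding_windows",
    "pairwise_differences",
]


def harmonic(n: int, power: int = 1) -> float:
    """a1 = sum_{i=1}^{n} 1/i (power=1) or a2 with 1/i^2 (power=2)."""
    return sum(1.0 / i**power for i in range(1, n + 1))


def usable_columns(
    aln: AlignmentMatrix, policy: str = "complete_deletion"
) -> list[int]:
    """1-based columns entering the analysis.

    ``complete_deletion`` drops every column containing a gap or a character
    outside the strict nucleotide alphabet; ``as_is`` keeps all columns.
    """
    if policy == "as_is":
        return list(range(1, aln.width + 1))
    if policy != "complete_deletion":
        raise UsageError(f"unknown site policy {policy!r}")
    ok = STRICT_NUCLEOTIDE
    kept = []
    for j in range(1, aln.width + 1):
        col = aln.column(j)
        if all(ch in ok for ch in col):
            kept.append(j)
    return kept


def _column_states(col: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for ch in col:
        if ch not in GAP_CHARS:
            counts[ch.upper()] = counts.get(ch.upper(), 0) + 1
    return counts


def basic_counts(
    aln: AlignmentMatrix, columns: Sequence[int] | None = None
) -> tuple[int, int, int, float, int, int]:
    """(n, k, S, s, eta, eta_S) over the given usable columns.

    S counts columns with >= 2 distinct states; eta sums (distinct states-1)
    per column, so eta == S exactly when every segregating column is
    biallelic; eta_S counts (column, state) pairs where the state occurs in
    exactly one sequence at a segregating column; k counts distinct row
    strings restricted to the usable columns.
    """
    if aln.n < 2:
        raise UsageError("population-genetic counts need at least two sequences")
    if columns is None:
        columns = usable_columns(aln)
    L = len(columns)
    S = eta = eta_S = 0
    for j in columns:
        states = _column_states(aln.column(j))
        if len(states) >= 2:
            S += 1
            eta += len(states) - 1
            eta_S += sum(1 for c in states.values() if c == 1)
    rows = {
        "".join(r.sequence[j - 1] for j in columns).upper() for r in aln.rows
    }
    k = len(rows)
    s = S / L if L else 0.0
    return aln.n, k, S, s, eta, eta_S


def mean_pairwise(
    aln: AlignmentMatrix, columns: Sequence[int] | None = None
) -> tuple[float, float]:
    """(Pi per locus, pi per site): mean Hamming distance over all sequence pairs."""
    if aln.n < 2:
        raise UsageError("pairwise differences need at least two sequences")
    if columns is None:
        columns = usable_columns(aln)
    L = len(columns)
    seqs = ["".join(r.sequence[j - 1] for j in columns).upper() for r in aln.rows]
    total = 0
    for a, b in combinations(seqs, 2):
        total += sum(x != y for x, y in zip(a, b))
    pairs = aln.n * (aln.n - 1) // 2
    Pi = total / pairs
    return Pi, (Pi / L if L else 0.0)


def pairwise_differences(
    aln: AlignmentMatrix, columns: Sequence[int] | None = None
) -> list[list[int]]:
    """n x n matrix of pairwise difference counts over usable columns."""
    if columns is None:
        columns = usable_columns(aln)
    seqs = ["".join(r.sequence[j - 1] for j in columns).upper() for r in aln.rows]
    n = len(seqs)
    mat = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(x != y for x, y in zip(seqs[i], seqs[j]))
            mat[i][j] = mat[j][i] = d
    return mat


def watterson(S: int, n: int, L: int) -> tuple[float, float]:
    """Watterson's estimator: (theta_W per locus = S/a1, per site = S/(a1 L))."""
    if n < 2:
        raise UsageError("Watterson's estimator needs n >= 2")
    a1 = harmonic(n - 1)
    per_locus = S / a1
    return per_locus, (per_locus / L if L else 0.0)


def tajima_D(Pi: float, S: int, n: int) -> float | None:
    """Tajima's D from mean pairwise differences and segregating sites.

    D = (Pi - S/a1) / sqrt(e1 S + e2 S(S-1)) with Tajima's (1989) constants;
    None (NA) when S == 0.
    """
    if n < 2:
        return None
    if S == 0:
        return None
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    num = Pi - S / a1
    # at n=3 the variance constants vanish identically; a zero numerator is
    # still an exact null result, so report 0 rather than 0/0
    if num == 0:
        return 0.0
    if var <= 0:
        return None
    return num / math.sqrt(var)


def _fu_li_star_coefficients(n: int) -> tuple[float, float, float, float]:
    """(uD*, vD*, uF*, vF*) variance coefficients for the starred statistics.

    The corrected forms of Simonsen, Churchill & Aquadro (1995), which fix
    the misprints in the original 1993 presentation; the same forms are used
    by the standard reference implementations the statistics are usually
    checked against.
    """
    a = harmonic(n - 1)
    b = harmonic(n - 1, 2)
    a1 = a + 1.0 / n  # harmonic number of order n
    cn = 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2) / (n - 1) ** 2
        + (2 / (n - 1)) * (1.5 - (2 * a1 - 3) / (n - 2) - 1.0 / n)
    )
    vD = (
        (n / (n - 1)) ** 2 * b
        + a**2 * dn
        - 2 * (n * a * (a + 1)) / (n - 1) ** 2
    ) / (a**2 + b)
    uD = (n / (n - 1)) * (a - n / (n - 1)) - vD
    vF = (
        dn
        + 2 * (n * n + n + 3) / (9 * n * (n - 1))
        - (2 / (n - 1)) * (4 * b - 6 + 8.0 / n)
    ) / (a**2 + b)
    uF = (
        (
            n / (n - 1)
            + (n + 1) / (3 * (n - 1))
            - 4.0 / (n * (n - 1))
            + 2 * (n + 1) / (n - 1) ** 2 * (a1 - 2 * n / (n + 1))
        )
        / a
        - vF
    )
    return uD, vD, uF, vF


def fu_li_Dstar(eta: int, eta_S: int, n: int) -> float | None:
    """Fu & Li's D* (no outgroup): total vs singleton mutations.

    D* = ((n/(n-1)) eta - a1 eta_S) / sqrt(uD* eta + vD* eta^2); None when
    eta == 0 or n < 3 (coefficients undefined below three sequences).
    """
    if n < 3 or eta == 0:
        return None
    a = harmonic(n - 1)
    uD, vD, _, _ = _fu_li_star_coefficients(n)
    var = uD * eta + vD * eta * eta
    num = (n / (n - 1)) * eta - a * eta_S
    if num == 0:
        return 0.0
    if var <= 0:
        return None
    return num / math.sqrt(var)


def fu_li_Fstar(Pi: float, eta: int, eta_S: int, n: int) -> float | None:
    """Fu & Li's F* (no outgroup): pairwise diversity vs singleton mutations.

    F* = (Pi - ((n-1)/n) eta_S) / sqrt(uF* eta + vF* eta^2); None when
    eta == 0 or n < 3.
    """
    if n < 3 or eta == 0:
        return None
    _, _, uF, vF = _fu_li_star_coefficients(n)
    var = uF * eta + vF * eta * eta
    num = Pi - ((n - 1) / n) * eta_S
    if num == 0:
        return 0.0
    if var <= 0:
        return None
    return num / math.sqrt(var)


def ewens_EK(n: int, theta: float) -> float:
    """Ewens' expected number of alleles in a sample of n under the
    infinite-alleles model: E(K) = sum_{i=0}^{n-1} theta/(theta+i), reading
    the i=0 term as 1 (and E(K)=1 at theta=0)."""
    if theta < 0:
        raise UsageError("theta must be non-negative")
    if n < 1:
        raise UsageError("n must be positive")
    if theta == 0:
        return 1.0
    return 1.0 + sum(theta / (theta + i) for i in range(1, n))


@dataclass
class PopGenSummary:
    """The whole-alignment statistics row; None fields are undefined (NA)."""

    n: int
    k: int
    L: int
    S: int
    s: float
    Pi: float
    pi: float
    theta_W: float
    theta_W_per_site: float
    EK: float
    D: float | None
    Dstar: float | None
    Fstar: float | None
    eta: int
    eta_S: int
    excluded_columns: int = 0

    FIELDS = (
        "n", "k", "L", "S", "s", "Pi", "pi", "theta_W",
        "theta_W_per_site", "EK", "D", "Dstar", "Fstar", "eta", "eta_S",
    )

    def row(self) -> list[str]:
        out = []
        for name in self.FIELDS:
            v = getattr(self, name)
            if v is None:
                out.append("NA")
            elif isinstance(v, float):
                out.append(f"{v:.6g}")
            else:
                out.append(str(v))
        return out


def summarize(
    aln: AlignmentMatrix, policy: str = "complete_deletion"
) -> PopGenSummary:
    """All summary statistics of one alignment under the given site policy."""
    if aln.n < 2:
        raise UsageError("summary statistics need at least two sequences")
    columns = usable_columns(aln, policy)
    L = len(columns)
    n, k, S, s, eta, eta_S = basic_counts(aln, columns)
    Pi, pi = mean_pairwise(aln, columns)
    theta_l, theta_s = watterson(S, n, L)
    return PopGenSummary(
        n=n,
        k=k,
        L=L,
        S=S,
        s=s,
        Pi=Pi,
        pi=pi,
        theta_W=theta_l,
        theta_W_per_site=theta_s,
        EK=ewens_EK(n, theta_l),
        D=tajima_D(Pi, S, n),
        Dstar=fu_li_Dstar(eta, eta_S, n),
        Fstar=fu_li_Fstar(Pi, eta, eta_S, n),
        eta=eta,
        eta_S=eta_S,
        excluded_columns=aln.width - L,
    )


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window request: width, step and single-letter statistic codes.

    Codes: ``d`` = Tajima's D, ``p`` = pi per site, ``w`` = theta_W per
    site, ``s`` = segregating sites.
    """

    width: int
    step: int
    stat_codes: tuple[str, ...] = ("d",)

    @classmethod
    def parse(cls, text: str) -> "WindowSpec":
        """Parse the ``WIDTH:STEP:CODES`` command-line form (e.g. ``100:25:d``)."""
        parts = text.split(":")
        if len(parts) not in (2, 3):
            raise UsageError(
                f"window spec {text!r} must have the form WIDTH:STEP[:CODES]"
            )
        try:
            width, step = int(parts[0]), int(parts[1])
        except ValueError:
            raise UsageError(f"non-integer window parameters in {text!r}") from None
        codes = tuple(parts[2]) if len(parts) == 3 and parts[2] else ("d",)
        if width < 1 or step < 1:
            raise UsageError("window width and step must be positive")
        for c in codes:
            if c not in _WINDOW_STATS:
                raise UsageError(
                    f"unknown window statistic code {c!r} (known: "
                    f"{''.join(_WINDOW_STATS)})"
                )
        return cls(width, step, codes)


def _window_stat(code: str, aln: AlignmentMatrix, policy: str):
    columns = usable_columns(aln, policy)
    n, _, S, _, _, _ = basic_counts(aln, columns)
    if code == "s":
        return S
    if code == "w":
        return watterson(S, n, len(columns))[1]
    Pi, pi = mean_pairwise(aln, columns)
    if code == "p":
        return pi
    return tajima_D(Pi, S, n)


_WINDOW_STATS = {"d": "tajima_D", "p": "pi", "w": "theta_W_per_site", "s": "S"}


def sliding_windows(
    aln: AlignmentMatrix,
    spec: WindowSpec,
    policy: str = "complete_deletion",
) -> tuple[list[str], list[list]]:
    """Per-window statistics table: (header, rows).

    Windows start at columns 1, 1+step, 1+2·step, …; only full-width windows
    are emitted.  Each row is [start, end, stat…] with the requested codes in
    order; the site policy is applied within each window slice.
    """
    if spec.width > aln.width:
        raise UsageError(
            f"window width {spec.width} exceeds alignment width {aln.width}"
        )
    header = ["window_start", "window_end"] + [_WINDOW_STATS[c] for c in spec.stat_codes]
    rows: list[list] = []
    start = 1
    while start + spec.width - 1 <= aln.width:
        sub = aln.take_columns(range(start, start + spec.width))
        rows.append(
            [start, start + spec.width - 1]
            + [_window_stat(c, sub, policy) for c in spec.stat_codes]
        )
        start += spec.step
    return header, rows
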