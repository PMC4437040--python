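"""Deterministic generators for test and demonstration inputs.

Everything here is synthetic and seeded: alignments with planted segregating
and singleton sites whose summary statistics are known by construction, an
infinite-sites coalescent sampler serving as the neutral-model oracle for
the statistics module, toy GenBank flat files with split/complemented
features, toy NCBI taxdump files, and a PopSet-style gapped alignment for
end-to-end pipeline runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from fastools.alignment_sites import AlignmentMatrix
from fastools.errors import UsageError
from fastools.record_io import SequenceRecord


@dataclass(frozen=True)
class PlantedAlignmentSpec:
    """An alignment with chosen state multisets planted at chosen columns.

    ``planted`` maps 1-based column index → string of n states (one per
    row); all other columns are monomorphic background.  The planted S, eta
    and eta_S are exactly recoverable by counting.
    """

    n: int
    L: int
    planted: dict[int, str] = field(default_factory=dict)
    background: str = "A"


def make_planted_alignment(spec: PlantedAlignmentSpec) -> AlignmentMatrix:
    """Build the alignment described by a :class:`PlantedAlignmentSpec`."""
    for col, states in spec.planted.items():
        if not 1 <= col <= spec.L:
            raise UsageError(f"planted column {col} outside 1..{spec.L}")
        if len(states) != spec.n:
            raise UsageError(
                f"column {col} has {len(states)} states for n={spec.n} rows"
            )
    rows = []
    for i in range(spec.n):
        seq = [
            spec.planted[j][i] if j in spec.planted else spec.background
            for j in range(1, spec.L + 1)
        ]
        rows.append(SequenceRecord(f"seq{i + 1}", "", "".join(seq)))
    return AlignmentMatrix(rows)


def worked_alignment() -> AlignmentMatrix:
    """The 3x4 hand-checkable alignment ACGT / ACGA / TCGA.

    Two segregating columns (1 and 4), both biallelic with singleton states:
    S=2, eta=2, eta_S=2, k=3, Pi=4/3, theta_W=4/3, and D = D* = F* = 0.
    """
    return make_planted_alignment(
        PlantedAlignmentSpec(
            n=3, L=4, planted={1: "AAT", 2: "CCC", 3: "GGG", 4: "TAA"}
        )
    )


# ---------------------------------------------------------------------------
# coalescent sampler


def coalescent_sample(n: int, theta: float, rng: np.random.Generator) -> AlignmentMatrix:
    """One infinite-sites coalescent sample rendered as a biallelic alignment.

    The standard neutral coalescent: while k lineages remain, an exponential
    waiting time with rate C(k,2) elapses and a uniformly chosen pair merges.
    Mutations are Poisson with mean theta/2 per unit branch length, dropped
    uniformly on branches; each mutation makes one biallelic column with the
    carrying lineage's descendants as T and everyone else as A.  Under this
    model E[S] = theta * a1 and E[Pi] = theta.
    """
    if n < 2:
        raise UsageError("coalescent sample needs n >= 2")
    if theta < 0:
        raise UsageError("theta must be non-negative")
    # simulate intervals: during the interval with k lineages each lineage
    # carries its descendant set for time t_k ~ Exp(C(k,2))
    lineages: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    branches: list[tuple[float, frozenset[int]]] = []  # (length, descendants)
    k = n
    while k > 1:
        rate = k * (k - 1) / 2
        t = rng.exponential(1.0 / rate)
        for lineage in lineages:
            branches.append((t, lineage))
        i, j = rng.choice(k, size=2, replace=False)
        merged = lineages[i] | lineages[j]
        lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
        k -= 1
    total_length = sum(t for t, _ in branches)
    n_mut = rng.poisson(theta / 2.0 * total_length) if total_length > 0 else 0
    columns: list[frozenset[int]] = []
    if n_mut:
        weights = np.array([t for t, _ in branches])
        picks = rng.choice(len(branches), size=n_mut, p=weights / weights.sum())
        columns = [branches[p][1] for p in picks]
    rows = []
    for i in range(n):
        seq = "".join("T" if i in carriers else "A" for carriers in columns)
        rows.append(SequenceRecord(f"sample{i + 1}", "", seq))
    return AlignmentMatrix(rows)


# ---------------------------------------------------------------------------
# GenBank fixture


def make_genbank_fixture(
    locus: str,
    origin: str,
    features: list[tuple[str, str, list[tuple[str, str]]]],
    definition: str = "synthetic record.",
) -> str:
    """Render a synthetic GenBank flat-file record.

    *features* is a list of (key, location string, [(qualifier, value), ...]).
    Coordinates must lie within the origin; the output parses cleanly with
    :func:`fastools.genbank.parse_genbank`.
    """
    import re

    for _, loc, _ in features:
        for m in re.finditer(r"\d+", loc):
            if not 1 <= int(m.group()) <= len(origin):
                raise UsageError(
                    f"location {loc!r} outside origin of length {len(origin)}"
                )
    lines = [
        f"LOCUS       {locus}             {len(origin)} bp    DNA     linear   SYN",
        f"DEFINITION  {definition}",
        "FEATURES             Location/Qualifiers",
    ]
    for key, loc, qualifiers in features:
        lines.append(f"     {key:<16}{loc}")
        for qname, qvalue in qualifiers:
            lines.append(f'                     /{qname}="{qvalue}"')
    lines.append("ORIGIN")
    for i in range(0, len(origin), 60):
        chunk = origin[i : i + 60]
        blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    lines.append("//")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# taxdump fixture


def make_taxdump_fixture(
    nodes: list[tuple[int, int, str]],
    names: list[tuple[int, str, str]],
) -> tuple[str, str]:
    """Render (nodes.dmp text, names.dmp text) in the NCBI taxdump dialect.

    *nodes*: (taxid, parent taxid, rank); *names*: (taxid, name, name class).
    The root must be its own parent; cycles are rejected by the loader, not
    here.
    """
    nodes_text = "".join(
        f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n" for taxid, parent, rank in nodes
    )
    names_text = "".join(
        f"{taxid}\t|\t{name}\t|\t\t|\t{name_class}\t|\n"
        for taxid, name, name_class in names
    )
    return nodes_text, names_text


def toy_taxdump() -> tuple[str, str]:
    """A small bacterial/metazoan taxonomy used across tests and examples."""
    nodes = [
        (1, 1, "no rank"),
        (2, 1, "superkingdom"),          # Bacteria
        (28211, 2, "class"),             # Alphaproteobacteria
        (356, 28211, "order"),           # Rhizobiales
        (379, 356, "genus"),             # Rhizobium
        (384, 379, "species"),           # Rhizobium leguminosarum
        (33208, 1, "kingdom"),           # Metazoa
        (9606, 33208, "species"),        # Homo sapiens
        (7227, 33208, "species"),        # Drosophila melanogaster
    ]
    names = [
        (1, "root", "scientific name"),
        (2, "Bacteria", "scientific name"),
        (28211, "Alphaproteobacteria", "scientific name"),
        (356, "Rhizobiales", "scientific name"),
        (379, "Rhizobium", "scientific name"),
        (384, "Rhizobium leguminosarum", "scientific name"),
        (33208, "Metazoa", "scientific name"),
        (33208, "metazoans", "synonym"),
        (9606, "Homo sapiens", "scientific name"),
        (7227, "Drosophila melanogaster", "scientific name"),
    ]
    return make_taxdump_fixture(nodes, names)


# ---------------------------------------------------------------------------
# PopSet-style alignment


POPSET_MATCHING_ACCESSIONS = (
    # the annotated reference locus (three related submissions) ...
    "AF194338.1",
    "AF194339.1",
    "AF194340.1",
    # ... and three allelic variants whose accessions contain 3490/3496
    "AY243490.1",
    "AY243496.1",
    "AY349061.1",
)
POPSET_OTHER_ACCESSIONS = tuple(
    f"AY243{num}.1"
    for num in (489, 491, 492, 493, 494, 495, 497, 498, 499,
                501, 502, 503, 504, 505, 507, 508, 509, 510)
)


def make_popset_alignment(seed: int = 0, width: int = 360) -> AlignmentMatrix:
    """Synthetic stand-in for an NCBI PopSet-style gapped gene alignment.

    Emulates a population set of one annotated reference plus partially
    sequenced allelic variants: gi-style identifiers, shared gap columns,
    scattered IUPAC ambiguities, and point variation.  Exactly six
    identifiers match the filter pattern ``(AF194|349[06])`` by
    construction (:data:`POPSET_MATCHING_ACCESSIONS`), so the ground truth
    of identifier-based filtering on this fixture is known.  This is a
    synthetic emulation, not NCBI data.
    """
    rng = np.random.default_rng(seed)
    accessions = list(POPSET_MATCHING_ACCESSIONS + POPSET_OTHER_ACCESSIONS)
    n = len(accessions)
    base = rng.choice(list("ACGT"), size=width)
    seqs = np.tile(base, (n, 1))
    # point variation: ~3% of sites polymorphic
    for j in rng.choice(width, size=max(1, width // 30), replace=False):
        alt = rng.choice([b for b in "ACGT" if b != base[j]])
        carriers = rng.choice(n, size=rng.integers(1, max(2, n // 2)), replace=False)
        seqs[carriers, j] = alt
    # shared gap columns (alignment of partial sequences)
    gap_cols = rng.choice(width, size=width // 12, replace=False)
    for j in gap_cols:
        carriers = rng.choice(n, size=rng.integers(1, n), replace=False)
        seqs[carriers, j] = "-"
    # scattered ambiguity calls
    for _ in range(n):
        i = rng.integers(0, n)
        j = rng.integers(0, width)
        seqs[i, j] = rng.choice(list("RYWSN"))
    rows = []
    for i, acc in enumerate(accessions):
        gi = 32329589 + i
        ident = f"gi|{gi}|gb|{acc}|"
        desc = "synthetic allelic variant, partial cds"
        rows.append(SequenceRecord(ident, desc, "".join(seqs[i])))
    return AlignmentMatrix(rows)
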