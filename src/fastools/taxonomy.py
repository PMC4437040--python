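"""NCBI-taxonomy loading, clade filtering and taxonomic sorting (fastax, fastaxsort).

Loads the standard taxdump flat files (``nodes.dmp``/``names.dmp``, fields
separated by ``\\t|\\t`` and lines terminated ``\\t|``) into a parent-pointer
tree, resolves record labels to taxids (numeric ids directly, otherwise
scientific names and synonyms, tolerating strain suffixes by progressively
dropping trailing tokens), and answers ancestor-or-self clade queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from fastools.errors import ParseError, UsageError
from fastools.record_io import FieldAddress, SequenceRecord, get_field, DEFAULT_DELIMITER
from fastools.errors import FieldResolutionError

ROOT_TAXID = 1
_NAME_CLASSES = ("scientific name", "synonym")


@dataclass
class TaxonomyTree:
    """taxid → parent/rank/name maps with a name → taxids index."""

    parent: dict[int, int] = field(default_factory=dict)
    rank: dict[int, str] = field(default_factory=dict)
    scientific: dict[int, str] = field(default_factory=dict)
    names: dict[str, set[int]] = field(default_factory=dict)

    def lineage(self, taxid: int) -> list[int]:
        """Path taxid → root (ancestor-or-self, root last)."""
        path = [taxid]
        while taxid in self.parent and self.parent[taxid] != taxid:
            taxid = self.parent[taxid]
            path.append(taxid)
        return path

    def resolve_name(self, name: str) -> set[int]:
        """Taxids for a clade label: numeric id, scientific name, or synonym."""
        name = name.strip()
        if name.isdigit():
            taxid = int(name)
            return {taxid} if taxid in self.parent else set()
        return set(self.names.get(name, ()))


def _split_dmp_line(line: str, lineno: int, min_fields: int) -> list[str]:
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    fields = line.split("\t|\t")
    if len(fields) < min_fields:
        raise ParseError(
            f"malformed taxdump line (expected >= {min_fields} fields)", lineno
        )
    return fields


def load_taxonomy(
    nodes_text: Iterable[str] | str, names_text: Iterable[str] | str
) -> TaxonomyTree:
    """Load nodes.dmp + names.dmp text into a validated :class:`TaxonomyTree`.

    Only the "scientific name" and "synonym" name classes are indexed.  A
    parent reference to an absent taxid, or a parent cycle not anchored at
    the self-parenting root, is a load error naming the taxid.
    """
    if isinstance(nodes_text, str):
        nodes_text = nodes_text.splitlines()
    if isinstance(names_text, str):
        names_text = names_text.splitlines()
    tree = TaxonomyTree()
    for lineno, line in enumerate(nodes_text, start=1):
        if not line.strip():
            continue
        fields = _split_dmp_line(line, lineno, 3)
        try:
            taxid, parent = int(fields[0]), int(fields[1])
        except ValueError:
            raise ParseError("non-numeric taxid in nodes.dmp", lineno) from None
        tree.parent[taxid] = parent
        tree.rank[taxid] = fields[2]
    # validation: every node reaches a self-parenting root without cycles
    for taxid in tree.parent:
        seen = set()
        node = taxid
        while True:
            if node not in tree.parent:
                raise ParseError(
                    f"orphan taxid {node} (parent of {taxid} lineage absent)"
                )
            parent = tree.parent[node]
            if parent == node:
                break
            if node in seen:
                raise ParseError(f"cycle in taxonomy at taxid {node}")
            seen.add(node)
            node = parent
    for lineno, line in enumerate(names_text, start=1):
        if not line.strip():
            continue
        fields = _split_dmp_line(line, lineno, 4)
        try:
            taxid = int(fields[0])
        except ValueError:
            raise ParseError("non-numeric taxid in names.dmp", lineno) from None
        name, name_class = fields[1], fields[3]
        if name_class not in _NAME_CLASSES:
            continue
        if taxid not in tree.parent:
            raise ParseError(f"name for unknown taxid {taxid}", lineno)
        tree.names.setdefault(name, set()).add(taxid)
        if name_class == "scientific name":
            tree.scientific[taxid] = name
    return tree


def in_clade(tree: TaxonomyTree, taxid: int, clade_taxid: int, strict: bool = False) -> bool:
    """True iff *clade_taxid* is an ancestor of (or equals) *taxid*."""
    if taxid not in tree.parent or clade_taxid not in tree.parent:
        if strict:
            raise UsageError(f"unknown taxid {taxid if taxid not in tree.parent else clade_taxid}")
        return False
    return clade_taxid in tree.lineage(taxid)


def resolve_label(tree: TaxonomyTree, label: str) -> set[int]:
    """Resolve a record label to taxids, dropping trailing tokens on failure.

    Handles species-plus-strain labels like "Rhizobium leguminosarum bv.
    viciae 3841": the full label is tried first, then progressively shorter
    prefixes; the first successful lookup wins.
    """
    tokens = label.strip().split()
    while tokens:
        taxids = tree.resolve_name(" ".join(tokens))
        if taxids:
            return taxids
        tokens = tokens[:-1]
    return set()


def filter_by_clade(
    records: Iterable[SequenceRecord],
    tree: TaxonomyTree,
    clade_name: str,
    field_index: int | None = None,
    delimiter: str = DEFAULT_DELIMITER,
    negate: bool = False,
    require_valid: bool = False,
) -> Iterator[SequenceRecord]:
    """Keep records whose addressed label lies in the clade (XOR *negate*).

    *field_index* None addresses the whole description (the default target
    of taxonomic selection); 0 the identifier; otherwise a description
    field.  A label resolving to several taxids (homonyms) is in the clade
    if any of them is.  With *require_valid*, records whose label resolves
    to no taxid are dropped regardless of *negate*; otherwise they count as
    outside the clade.
    """
    clade_taxids = tree.resolve_name(clade_name)
    if not clade_taxids:
        raise UsageError(f"clade {clade_name!r} not found in taxonomy")
    address = FieldAddress(field_index or 0, delimiter)
    for record in records:
        if field_index is None:
            label = record.description
        else:
            try:
                label = get_field(record, address)
            except FieldResolutionError:
                label = ""
        taxids = resolve_label(tree, label)
        if not taxids:
            if require_valid:
                continue
            member = False
        else:
            member = any(
                in_clade(tree, t, c) for t in taxids for c in clade_taxids
            )
        if member != negate:
            yield record


def taxonomic_sort_key(tree: TaxonomyTree, taxid: int) -> tuple:
    """Sort key grouping clades contiguously: canonical names along root→taxid.

    Unknown taxids sort after all known ones (stable among themselves).
    """
    if taxid not in tree.parent:
        return (1,)
    path = list(reversed(tree.lineage(taxid)))
    return (0, tuple(tree.scientific.get(t, str(t)) for t in path))


def sort_by_taxonomy(
    records: Iterable[SequenceRecord],
    tree: TaxonomyTree,
    field_index: int | None = None,
    delimiter: str = DEFAULT_DELIMITER,
) -> list[SequenceRecord]:
    """Stable sort of records by the taxonomic key of their resolved label.

    *field_index* follows :func:`filter_by_clade` (None = description).
    """
    items = list(records)
    address = FieldAddress(field_index or 0, delimiter)

    def key(record: SequenceRecord) -> tuple:
        if field_index is None:
            label = record.description
        else:
            try:
                label = get_field(record, address)
            except FieldResolutionError:
                return (1,)
        taxids = resolve_label(tree, label)
        if not taxids:
            return (1,)
        return min(taxonomic_sort_key(tree, t) for t in sorted(taxids))

    return sorted(items, key=key)
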