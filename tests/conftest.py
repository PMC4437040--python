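import pytest

from fastools import fixtures
from fastools.record_io import SequenceRecord, serialize_records


@pytest.fixture
def worked_alignment():
    """The 3x4 hand-checkable alignment ACGT / ACGA / TCGA."""
    return fixtures.worked_alignment()


@pytest.fixture
def popset_text():
    """Synthetic PopSet-style gapped alignment, serialized as multi-FASTA."""
    return serialize_records(fixtures.make_popset_alignment(seed=0).rows)


@pytest.fixture
def genbank_text():
    """Toy GenBank record with a split CDS, a complemented tRNA and a 5'UTR."""
    origin = "AAATTTGGGCCCAAATTTGGGCCCAAATTTGGGCCC"
    return fixtures.make_genbank_fixture(
        "SYNREC1",
        origin,
        [
            ("5'UTR", "1..6", [("note", "synthetic 5'UTR")]),
            ("CDS", "join(7..12,19..24)", [("product", "toy split CDS"),
                                           ("note", "spans two exons")]),
            ("tRNA", "complement(25..30)", [("product", "tRNA-Ser"),
                                            ("note", "recognises UCN codons")]),
            ("tRNA", "31..36", [("product", "tRNA-Leu"),
                                ("note", "codons AGN family")]),
        ],
    )


@pytest.fixture
def taxdump_texts():
    """(nodes.dmp, names.dmp) text of the toy taxonomy."""
    return fixtures.toy_taxdump()


@pytest.fixture
def trna_records():
    """Records labelled with species names in the third |-delimited field."""
    rows = [
        ("t1", "acc1 | Val | Rhizobium leguminosarum bv. viciae 3841"),
        ("t2", "acc2 | Ala | Homo sapiens"),
        ("t3", "acc3 | Gly | Drosophila melanogaster"),
        ("t4", "acc4 | Ser | Alphaproteobacteria"),
        ("t5", "acc5 | Leu | no_such_taxon"),
    ]
    return [SequenceRecord(i, d, "ACGT") for i, d in rows]
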