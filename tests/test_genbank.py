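import io

import pytest
from Bio import SeqIO

from fastools.errors import ParseError, UsageError
from fastools.fixtures import make_genbank_fixture
from fastools.genbank import (
    QualifierConstraint,
    cut_features,
    extract_feature,
    feature_matches,
    parse_genbank,
    parse_location,
)


class TestLocationGrammar:
    def test_join(self):
        loc = parse_location("join(1..3,7..9)")
        assert loc.segments == ((1, 3), (7, 9))
        assert not loc.complement

    def test_complement(self):
        loc = parse_location("complement(4..6)")
        assert loc.segments == ((4, 6),) and loc.complement

    def test_partial_markers(self):
        assert parse_location("<1..200").partial5
        assert parse_location("1..>200").partial3

    def test_single_base(self):
        assert parse_location("5").segments == ((5, 5),)

    def test_complement_join(self):
        loc = parse_location("complement(join(1..2,5..6))")
        assert loc.segments == ((1, 2), (5, 6)) and loc.complement

    @pytest.mark.parametrize("bad", ["order(1..2,3..4)", "one-of(1,2)..5",
                                     "J01749:1..100"])
    def test_unsupported_operators_rejected(self, bad):
        with pytest.raises(ParseError, match="unsupported"):
            parse_location(bad)

    def test_reversed_segment_is_error(self):
        with pytest.raises(ParseError):
            parse_location("9..3")


class TestFlatFileParsing:
    def test_minimal_split_cds(self):
        text = make_genbank_fixture(
            "TOY1", "AAATTTGGG", [("CDS", "join(1..3,7..9)", [("gene", "g")])]
        )
        (record,) = parse_genbank(text)
        assert record.locus == "TOY1"
        assert record.origin == "AAATTTGGG"
        (feat,) = record.features
        assert feat.key == "CDS"
        assert feat.location.segments == ((1, 3), (7, 9))
        assert feat.qualifier_values("gene") == ["g"]

    def test_qualifier_value_spanning_lines(self):
        text = (
            "LOCUS       X1             6 bp    DNA\n"
            "FEATURES             Location/Qualifiers\n"
            "     CDS             1..6\n"
            '                     /note="a very long note that\n'
            '                     continues on the next line"\n'
            "ORIGIN\n"
            "        1 aaattt\n"
            "//\n"
        )
        (record,) = parse_genbank(text)
        (feat,) = record.features
        assert feat.qualifier_values("note") == [
            "a very long note that continues on the next line"
        ]

    def test_two_records(self):
        text = make_genbank_fixture("R1", "AAA", []) + make_genbank_fixture(
            "R2", "CCC", []
        )
        assert [r.locus for r in parse_genbank(text)] == ["R1", "R2"]

    def test_unterminated_record_is_error(self):
        with pytest.raises(ParseError, match="unterminated"):
            parse_genbank("LOCUS       X1 3 bp\nORIGIN\n        1 aaa\n")

    def test_features_without_origin_is_error(self):
        text = (
            "LOCUS       X1 3 bp\n"
            "FEATURES             Location/Qualifiers\n"
            "     CDS             1..3\n"
            "//\n"
        )
        with pytest.raises(ParseError, match="ORIGIN"):
            parse_genbank(text)

    def test_agrees_with_reference_parser(self, genbank_text):
        """The fixture parses identically under an independent GenBank reader."""
        ours = parse_genbank(genbank_text)[0]
        theirs = SeqIO.read(io.StringIO(genbank_text), "genbank")
        assert ours.origin.upper() == str(theirs.seq).upper()
        # same feature keys in order (skip the implicit 'source' if present)
        their_keys = [f.type for f in theirs.features if f.type != "source"]
        assert [f.key for f in ours.features] == their_keys
        # split CDS coordinates agree (Biopython is 0-based half-open)
        ours_cds = next(f for f in ours.features if f.key == "CDS")
        theirs_cds = next(f for f in theirs.features if f.type == "CDS")
        theirs_segments = tuple(
            (int(p.start) + 1, int(p.end)) for p in theirs_cds.location.parts
        )
        assert ours_cds.location.segments == theirs_segments


class TestMatching:
    def _trna_ser(self):
        text = make_genbank_fixture(
            "M1", "A" * 30,
            [("tRNA", "1..10", [("product", "tRNA-Ser"), ("note", "no family")])],
        )
        return parse_genbank(text)[0].features[0]

    def test_conjunction_with_negation(self):
        feat = self._trna_ser()
        constraints = [QualifierConstraint.parse("product=Ser"),
                       QualifierConstraint.parse("note^AGN")]
        assert feature_matches(feat, "tRNA", constraints)

    def test_negated_constraint_rejects(self):
        text = make_genbank_fixture(
            "M1", "A" * 30,
            [("tRNA", "1..10", [("product", "tRNA-Ser"), ("note", "codons AGN")])],
        )
        feat = parse_genbank(text)[0].features[0]
        constraints = [QualifierConstraint.parse("product=Ser"),
                       QualifierConstraint.parse("note^AGN")]
        assert not feature_matches(feat, "tRNA", constraints)

    def test_key_regex_partial_match(self):
        text = make_genbank_fixture("M1", "A" * 10, [("5'UTR", "1..4", [])])
        feat = parse_genbank(text)[0].features[0]
        assert feature_matches(feat, "UTR")

    def test_bad_constraint_text(self):
        with pytest.raises(UsageError):
            QualifierConstraint.parse("no_separator")


class TestExtraction:
    def test_split_feature(self):
        assert extract_feature("AAATTTGGG", parse_location("join(1..3,7..9)")) == "AAAGGG"

    def test_complement(self):
        assert extract_feature("AAACCC", parse_location("complement(4..6)")) == "GGG"

    def test_single_base(self):
        assert extract_feature("ACGTA", parse_location("5")) == "A"

    def test_whole_sequence_identity(self):
        assert extract_feature("ACGTACGT", parse_location("join(1..8)")) == "ACGTACGT"

    def test_length_equals_span_even_complemented(self):
        loc = parse_location("complement(join(2..4,6..9))")
        assert len(extract_feature("ACGTACGTAC", loc)) == loc.span == 7

    def test_out_of_bounds_is_error(self):
        with pytest.raises(ParseError, match="outside"):
            extract_feature("ACG", parse_location("2..5"))

    def test_cut_features_unique_ids_and_headers(self, genbank_text):
        records = parse_genbank(genbank_text)
        out = list(cut_features(records, key_regex="tRNA"))
        assert len(out) == 2
        ids = [r.identifier for r in out]
        assert len(ids) == len(set(ids))
        assert all(i.startswith("SYNREC1_tRNA_") for i in ids)

    def test_cut_features_respects_qualifiers(self, genbank_text):
        records = parse_genbank(genbank_text)
        out = list(
            cut_features(records, "tRNA",
                         [QualifierConstraint.parse("product=Ser"),
                          QualifierConstraint.parse("note^AGN")])
        )
        assert len(out) == 1
        assert "tRNA-Ser" in out[0].description
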