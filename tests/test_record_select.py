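import random

import pytest
from hypothesis import given, settings, strategies as st

from fastools.errors import UsageError
from fastools.rangespec import parse_interval_set
from fastools.record_io import SequenceRecord, get_tag
from fastools.record_select import (
    TargetSelector,
    expand_iupac,
    filter_numeric,
    grep_records,
    sort_records,
    take_records,
    uniq_records,
)


def recs(*pairs):
    return [SequenceRecord(i, d, s) for i, d, s in pairs]


class TestIupacExpansion:
    def test_worked_motif(self):
        assert expand_iupac("WTTTAYRTTTW") == "[AT]TTTA[CT][AG]TTT[AT]"

    def test_strict_pattern_unchanged(self):
        assert expand_iupac("ACGT") == "ACGT"

    def test_single_codes(self):
        assert expand_iupac("N") == "[ACGT]"
        assert expand_iupac("X", "protein") == "[A-Z]"
        assert expand_iupac("B", "protein") == "[DN]"

    def test_character_classes_and_escapes_untouched(self):
        assert expand_iupac("[WY]W\\W") == "[WY][AT]\\W"

    def test_metacharacters_untouched(self):
        assert expand_iupac("^W{2,3}$") == "^[AT]{2,3}$"

    @settings(max_examples=100, deadline=None)
    @given(st.text("ACGTRYWSKMBDHVN^$.[]\\{}2,", max_size=20))
    def test_idempotent_on_own_output(self, pattern):
        once = expand_iupac(pattern)
        assert expand_iupac(once) == once

    def test_unknown_seqtype(self):
        with pytest.raises(UsageError):
            expand_iupac("A", "rna")


class TestGrep:
    def test_negated_sequence_match(self):
        records = recs(("a", "", "MKV"), ("b", "", "AKV"), ("c", "", "MMM"))
        out = list(grep_records(records, "^M", TargetSelector("sequence"), negate=True))
        assert [r.identifier for r in out] == ["b"]

    def test_match_all(self):
        records = recs(("a", "", ""), ("b", "", ""))
        assert len(list(grep_records(records, "."))) == 2

    def test_tag_target(self):
        records = recs(
            ("a", "xl0:MNASTV", ""), ("b", "xl0:MNPSTV", ""), ("c", "other:1", "")
        )
        out = list(
            grep_records(records, "N[^P][ST][^P]", TargetSelector("tag", name="xl0"))
        )
        assert [r.identifier for r in out] == ["a"]

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.text("ACGT", min_size=1, max_size=8), max_size=10),
           st.sampled_from(["A", "^AC", "G{2}", "T$"]))
    def test_partition_property(self, seqs, pattern):
        records = [SequenceRecord(f"r{i}", "", s) for i, s in enumerate(seqs)]
        kept = list(grep_records(records, pattern, TargetSelector("sequence")))
        dropped = list(
            grep_records(records, pattern, TargetSelector("sequence"), negate=True)
        )
        assert sorted(r.identifier for r in kept + dropped) == sorted(
            r.identifier for r in records
        )
        assert not {r.identifier for r in kept} & {r.identifier for r in dropped}

    def test_invalid_regex_is_startup_error(self):
        with pytest.raises(UsageError):
            list(grep_records([], "("))


class TestFilterNumeric:
    def test_gi_number_capture(self):
        records = recs(
            ("gi|300000000", "x", ""), ("gi|100", "y", ""), ("noid", "z", "")
        )
        out = list(
            filter_numeric(records, parse_interval_set("2e8..5e8"),
                           capture_regex=r"gi\|(\d+)")
        )
        assert [r.identifier for r in out] == ["gi|300000000"]

    def test_no_capture_drops_record(self):
        records = recs(("abc", "", ""),)
        assert list(
            filter_numeric(records, parse_interval_set("0-"), capture_regex=r"(\d+)")
        ) == []

    def test_unbounded_set_keeps_all_parseable(self):
        records = recs(("1", "", ""), ("-2.5e3", "", ""), ("x", "", ""))
        out = list(filter_numeric(records, parse_interval_set("-1e300..1e300")))
        assert [r.identifier for r in out] == ["1", "-2.5e3"]

    def test_capture_regex_without_group_is_error(self):
        with pytest.raises(UsageError):
            list(filter_numeric([], parse_interval_set("0-"), capture_regex=r"\d+"))


class TestHeadTail:
    def test_head_one(self):
        records = recs(("a", "", ""), ("b", "", ""), ("c", "", ""))
        assert [r.identifier for r in take_records(records, 1)] == ["a"]

    def test_tail(self):
        records = recs(("a", "", ""), ("b", "", ""), ("c", "", ""))
        assert [r.identifier for r in take_records(records, 2, "tail")] == ["b", "c"]

    @pytest.mark.parametrize("end", ["head", "tail"])
    def test_zero_and_overlong(self, end):
        records = recs(("a", "", ""), ("b", "", ""))
        assert list(take_records(records, 0, end)) == []
        assert len(list(take_records(records, 10, end))) == 2


class TestSort:
    def test_numeric_sort_by_tag(self):
        records = recs(
            ("a", "comp_A:7", ""), ("b", "comp_A:2", ""), ("c", "comp_A:11", "")
        )
        out = sort_records(records, TargetSelector("tag", name="comp_A"), numeric=True)
        assert [r.identifier for r in out] == ["b", "a", "c"]

    def test_sequence_sort_lexicographic(self):
        records = recs(("a", "", "TTT"), ("b", "", "AAA"), ("c", "", "CCC"))
        out = sort_records(records, TargetSelector("sequence"))
        assert [r.sequence for r in out] == ["AAA", "CCC", "TTT"]

    def test_stability_and_idempotence(self):
        records = recs(("a", "", "X"), ("b", "", "X"), ("c", "", "A"))
        once = sort_records(records, TargetSelector("sequence"))
        assert [r.identifier for r in once] == ["c", "a", "b"]
        assert sort_records(once, TargetSelector("sequence")) == once

    def test_unparseable_numeric_keys_sort_last_in_input_order(self):
        records = recs(("x", "", ""), ("n1", "5", ""), ("y", "", ""), ("n2", "1", ""))
        out = sort_records(records, TargetSelector("description"), numeric=True)
        assert [r.identifier for r in out] == ["n2", "n1", "x", "y"]

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.text("ABC", max_size=4), max_size=12))
    def test_sort_is_permutation(self, keys):
        records = [SequenceRecord(f"r{i}", "", k) for i, k in enumerate(keys)]
        out = sort_records(records, TargetSelector("sequence"))
        assert sorted(r.identifier for r in out) == sorted(r.identifier for r in records)


class TestUniq:
    def test_only_adjacent_collapse(self):
        records = recs(("a1", "", "A"), ("a2", "", "A"), ("b", "", "B"), ("a3", "", "A"))
        out = list(uniq_records(records, TargetSelector("sequence")))
        assert [r.identifier for r in out] == ["a1", "b", "a3"]

    def test_count_tag_sums_to_input(self):
        records = recs(
            ("a1", "", "A"), ("a2", "", "A"), ("b", "", "B"), ("c1", "", "C"),
            ("c2", "", "C"), ("c3", "", "C"),
        )
        out = list(uniq_records(records, TargetSelector("sequence"), count=True))
        counts = [int(get_tag(r, "uniq_count")) for r in out]
        assert counts == [2, 1, 3]
        assert sum(counts) == len(records)

    def test_empty_stream(self):
        assert list(uniq_records([])) == []

    def test_uniq_after_sort_leaves_no_equal_neighbours(self):
        rng = random.Random(0)
        records = [
            SequenceRecord(f"r{i}", "", rng.choice(["AA", "CC", "GG"]))
            for i in range(30)
        ]
        out = list(
            uniq_records(
                sort_records(records, TargetSelector("sequence")),
                TargetSelector("sequence"),
            )
        )
        seqs = [r.sequence for r in out]
        assert len(seqs) == len(set(seqs))
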