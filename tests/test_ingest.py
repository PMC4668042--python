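import io
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lexikit as lk
from lexikit.ingest import (
    ParseError,
    annotate_grammatical_info,
    collation_key,
    filter_entries,
    normalize_and_merge,
    read_frequency_list,
)


class TestReadFrequencyList:
    def test_parses_form_and_count(self):
        entries = read_frequency_list(io.StringIO("casa 123\n"), "nom")
        assert entries == [lk.RawEntry("casa", "nom", 123)]

    def test_empty_stream_gives_empty_list(self):
        assert read_frequency_list(io.StringIO(""), "nom") == []

    @pytest.mark.parametrize("line", ["casa abc", "casa", "casa -3"])
    def test_malformed_line_names_line_number(self, line):
        with pytest.raises(ParseError, match="line 1"):
            read_frequency_list(io.StringIO(line + "\n"), "nom")

    def test_unknown_category_rejected(self):
        with pytest.raises(lk.ingest.LexiconError, match="category"):
            read_frequency_list(io.StringIO("casa 1\n"), "noun")

    def test_blank_lines_skipped_and_order_preserved(self):
        text = "b 2\n\n  \na 1\n"
        entries = read_frequency_list(io.StringIO(text), "ver")
        assert [e.orthography for e in entries] == ["b", "a"]


class TestNormalizeAndMerge:
    def test_case_variants_merge_by_summing(self):
        merged, report = normalize_and_merge(
            [lk.RawEntry("Casa", "nom", 10), lk.RawEntry("casa", "nom", 5)]
        )
        assert merged == [lk.RawEntry("casa", "nom", 15)]
        assert report.merged_case_variants == 1

    def test_single_entry_unchanged(self):
        merged, _ = normalize_and_merge([lk.RawEntry("casa", "nom", 10)])
        assert merged == [lk.RawEntry("casa", "nom", 10)]

    def test_lowercasing_applies_even_without_merge(self):
        merged, _ = normalize_and_merge([lk.RawEntry("CASA", "nom", 0)])
        assert merged[0].orthography == "casa"

    def test_mixed_categories_rejected(self):
        with pytest.raises(lk.ingest.LexiconError):
            normalize_and_merge(
                [lk.RawEntry("a", "nom", 1), lk.RawEntry("b", "ver", 1)]
            )

    @given(
        st.lists(
            st.tuples(
                st.text(alphabet="aAbBcC", min_size=1, max_size=6),
                st.integers(min_value=0, max_value=100),
            ),
            min_size=1,
            max_size=30,
        )
    )
    @settings(deadline=None, max_examples=60)
    def test_idempotent_and_token_conserving(self, raw):
        entries = [lk.RawEntry(f, "nom", c) for f, c in raw]
        once, report = normalize_and_merge(entries)
        twice, report2 = normalize_and_merge(once)
        assert once == twice
        assert report2.merged_case_variants == 0
        assert sum(e.raw_freq for e in once) == sum(e.raw_freq for e in entries)
        assert report.merged_case_variants == len(entries) - len(once)


class TestFilterEntries:
    def test_over_30_characters_removed(self):
        long_form = "a" * 31
        kept, report = filter_entries([lk.RawEntry(long_form, "nom", 1)])
        assert kept == [] and report.removed_too_long == 1

    def test_exactly_30_characters_kept(self):
        kept, _ = filter_entries([lk.RawEntry("a" * 30, "nom", 1)])
        assert len(kept) == 1

    @pytest.mark.parametrize(
        "form,cat,expected_kept",
        [
            ("2015", "num", False),
            ("9", "num", True),
            ("9", "nom", True),
            ("9", "ver", False),  # whitelist applies only under adj/nom/num
            ("3º", "num", True),
            ("7ª", "adj", True),
            ("casa", "nom", True),
            ("r2d2", "nom", False),
        ],
    )
    def test_numeric_whitelist(self, form, cat, expected_kept):
        kept, _ = filter_entries([lk.RawEntry(form, cat, 1)])
        assert (len(kept) == 1) is expected_kept

    def test_report_counts_partition_the_input(self):
        entries = [
            lk.RawEntry("casa", "nom", 1),
            lk.RawEntry("2015", "nom", 1),
            lk.RawEntry("b" * 31, "nom", 1),
        ]
        kept, report = filter_entries(entries)
        assert report.kept + report.removed_numeric + report.removed_too_long == len(entries)
        assert report.kept == len(kept)


class TestCollation:
    def test_letters_before_digits_before_hyphen(self):
        forms = ["9", "casa", "guarda-chuva", "z", "3"]
        ordered = sorted(forms, key=collation_key)
        assert ordered == ["casa", "guarda-chuva", "z", "3", "9"]

    def test_accented_letters_sort_with_base(self):
        ordered = sorted(["ate", "até", "atz", "ata"], key=collation_key)
        assert ordered[0] == "ata" and ordered[-1] == "atz"
        assert set(ordered[1:3]) == {"ate", "até"}
        # code point breaks the base-letter tie deterministically
        assert ordered[1] == "ate"


class TestAssembleLexicon:
    def test_ids_follow_descending_frequency(self):
        lex = lk.assemble_lexicon(
            [lk.RawEntry("b", "nom", 5), lk.RawEntry("a", "nom", 10)], seed=0
        )
        frame = lex.frame
        assert list(frame["orthography"]) == ["a", "b"]
        assert list(frame["id"]) == [1, 2]

    def test_empty_input_is_an_error(self):
        with pytest.raises(lk.ingest.LexiconError, match="empty"):
            lk.assemble_lexicon([], seed=0)

    def test_same_seed_reproduces_random_column(self, demo_lex):
        again = lk.demo_lexicon(seed=42)
        assert (again.frame["random"] == demo_lex.frame["random"]).all()
        different = lk.demo_lexicon(seed=43)
        assert (different.frame["random"] != demo_lex.frame["random"]).any()

    def test_token_total_conserved(self, demo_lex):
        assert demo_lex.token_total == demo_lex.frame["ortho_freq"].sum()
        assert demo_lex.type_total == len(demo_lex.frame)
        assert list(demo_lex.frame["id"]) == list(range(1, demo_lex.type_total + 1))

    def test_shuffled_input_yields_identical_lexicon(self):
        entries = [
            e for entries in lk.demo_corpus().values() for e in entries
        ]
        shuffled = entries[:]
        random.Random(7).shuffle(shuffled)
        a = lk.assemble_lexicon(entries, seed=5).frame
        b = lk.assemble_lexicon(shuffled, seed=5).frame
        assert a.equals(b)

    def test_all_25_columns_present_in_order(self, demo_lex):
        assert tuple(demo_lex.frame.columns) == lk.COLUMNS


class TestGrammaticalInfo:
    RULES = {("ver", "as"): "ind, pre, 2, s", ("nom", "o"): "m, s"}

    def test_verb_suffix_rule(self):
        entry = lk.RawEntry("falas", "ver", 5)
        assert annotate_grammatical_info(entry, self.RULES) == "ind, pre, 2, s"

    def test_noun_suffix_rule(self):
        entry = lk.RawEntry("cachorro", "nom", 397)
        assert annotate_grammatical_info(entry, self.RULES) == "m, s"

    def test_no_matching_suffix_gives_empty_string(self):
        entry = lk.RawEntry("xyz", "adv", 1)
        assert annotate_grammatical_info(entry, self.RULES) == ""

    def test_longest_suffix_wins(self):
        rules = {("nom", "a"): "f, s", ("nom", "osa"): "f, s, c1"}
        entry = lk.RawEntry("gloriosa", "nom", 1)
        assert annotate_grammatical_info(entry, rules) == "f, s, c1"

    def test_unknown_feature_code_rejected(self):
        with pytest.raises(lk.ingest.LexiconError, match="feature"):
            annotate_grammatical_info(
                lk.RawEntry("falas", "ver", 1), {("ver", "as"): "bogus"}
            )


def test_build_lexicon_runs_full_pipeline():
    lists = {
        "nom": [("Casa", 10), ("casa", 5), ("2015", 3), ("x" * 31, 1)],
        "ver": [("ama", 4)],
    }
    lexicon, report = lk.build_lexicon(lists, seed=0)
    assert set(lexicon.frame["orthography"]) == {"casa", "ama"}
    assert report.merged_case_variants == 1
    assert report.removed_numeric == 1
    assert report.removed_too_long == 1
    assert lexicon.token_total == 19
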