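import io
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

import lexikit as lk
from lexikit import compare


def corpus(name, **entries):
    return compare.CorpusFrequencyList(name=name, entries=entries)


class TestCollapseHomographs:
    def test_homograph_frequencies_sum(self):
        lex, _ = lk.build_lexicon(
            {"nom": [("cachorro", 397)], "adj": [("cachorro", 3)]}, seed=0
        )
        collapsed = compare.collapse_homographs(lex)
        assert collapsed.entries["cachorro"] == 400

    def test_no_homographs_is_identity(self, demo_lex):
        collapsed = compare.collapse_homographs(demo_lex)
        frame = demo_lex.frame
        solo = frame[frame["nb_homogr"] == 1]
        for form, freq in zip(solo["orthography"], solo["ortho_freq"]):
            assert collapsed.entries[form] == freq

    def test_type_count_never_exceeds_entry_count(self, demo_lex):
        collapsed = compare.collapse_homographs(demo_lex)
        assert len(collapsed.entries) <= demo_lex.type_total
        assert collapsed.token_total == demo_lex.token_total


class TestAlignment:
    def test_disjoint_corpora_align_empty(self):
        aligned = compare.align_corpora([corpus("a", x=1), corpus("b", y=1)])
        assert aligned.empty

    def test_identical_corpora_align_fully(self):
        a = corpus("a", x=1, y=2)
        b = corpus("b", x=3, y=4)
        aligned = compare.align_corpora([a, b])
        assert set(aligned.index) == {"x", "y"}

    def test_zero_frequency_excluded(self):
        a = corpus("a", **{"a": 1, "b": 2, "c": 0})
        b = corpus("b", **{"a": 3, "b": 0, "c": 5})
        aligned = compare.align_corpora([a, b])
        assert list(aligned.index) == ["a"]


class TestZipfCorrelation:
    def test_self_correlation_is_one(self):
        a = corpus("a", x=10, y=5, z=1)
        aligned = compare.align_corpora([a, corpus("b", x=10, y=5, z=1)])
        r = compare.zipf_correlation(aligned, {"a": 16, "b": 16})
        assert r.loc["a", "a"] == pytest.approx(1.0)
        assert r.loc["a", "b"] == pytest.approx(1.0)

    def test_constant_scaling_preserves_correlation(self):
        a = corpus("a", x=10, y=5, z=1, w=40)
        b = corpus("b", x=100, y=50, z=10, w=400)  # same shape, 10x tokens
        aligned = compare.align_corpora([a, b])
        r = compare.zipf_correlation(
            aligned, {"a": a.token_total, "b": b.token_total}
        )
        assert r.loc["a", "b"] == pytest.approx(1.0)

    def test_matches_textbook_pearson(self):
        a = corpus("a", v=50, w=20, x=10, y=5, z=1)
        b = corpus("b", v=40, w=30, x=5, y=8, z=2)
        aligned = compare.align_corpora([a, b])
        totals = {"a": a.token_total, "b": b.token_total}
        r = compare.zipf_correlation(aligned, totals)
        za = [a.zipf(f) for f in aligned.index]
        zb = [b.zipf(f) for f in aligned.index]
        expected, _p = scipy_stats.pearsonr(za, zb)
        assert r.loc["a", "b"] == pytest.approx(expected)
        # matrix structure
        assert r.loc["b", "a"] == pytest.approx(r.loc["a", "b"])
        assert np.all(np.abs(r.to_numpy()) <= 1 + 1e-12)

    def test_too_few_forms_rejected(self):
        aligned = compare.align_corpora([corpus("a", x=1, y=1), corpus("b", x=1, y=1)])
        with pytest.raises(ValueError):
            compare.zipf_correlation(aligned, {"a": 2, "b": 2})


class TestFisherContrast:
    def test_equal_correlations_give_zero(self):
        assert compare.fisher_rz_contrast(0.5, 100, 0.5, 200) == 0.0

    def test_antisymmetric_in_the_pair(self):
        z = compare.fisher_rz_contrast(0.8, 50, 0.6, 70)
        assert compare.fisher_rz_contrast(0.6, 70, 0.8, 50) == pytest.approx(-z)

    def test_direct_formula_evaluation(self):
        z = compare.fisher_rz_contrast(0.8, 45_968, 0.7, 45_968)
        expected = (math.atanh(0.8) - math.atanh(0.7)) / math.sqrt(2 / 45_965)
        assert z == pytest.approx(expected)
        assert round(z, 2) == 35.07

    @pytest.mark.parametrize("r1,n1", [(1.0, 100), (-1.0, 100), (0.5, 3)])
    def test_domain_errors(self, r1, n1):
        with pytest.raises(ValueError):
            compare.fisher_rz_contrast(r1, n1, 0.1, 100)


class TestContainment:
    def test_diagonal_is_hundred(self):
        m = compare.containment_matrix([corpus("a", x=1, y=1), corpus("b", x=1)])
        assert m.loc["a", "a"] == 100.0 and m.loc["b", "b"] == 100.0

    def test_hand_counted_overlap(self):
        a = corpus("a", a=1, b=1, c=1)
        b = corpus("b", b=1, c=1, d=1)
        m = compare.containment_matrix([a, b])
        assert m.loc["a", "b"] == pytest.approx(66.67)

    def test_containment_identity(self):
        a = corpus("a", a=1, b=1, c=1, d=1, e=1)
        b = corpus("b", c=1, d=1, e=1)
        m = compare.containment_matrix([a, b])
        assert m.loc["a", "b"] * 5 == pytest.approx(m.loc["b", "a"] * 3, abs=0.2)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            compare.containment_matrix([corpus("a", x=1), corpus("b")])


class TestDiscrepancies:
    def test_identical_corpora_have_none(self):
        a = corpus("a", x=5, y=2)
        b = corpus("b", x=1, y=9)
        over, under = compare.estimation_discrepancies(a, b)
        assert over.empty and under.empty

    def test_hand_ordered_example(self):
        a = corpus("a", x=100, y=1)
        b = corpus("b", y=50, z=9)
        over, under = compare.estimation_discrepancies(a, b, k=1)
        assert list(over["form"]) == ["x"]
        assert list(under["form"]) == ["z"]

    def test_lists_ordered_by_descending_frequency(self):
        a = corpus("a", p=3, q=30, r=300)
        b = corpus("b", s=1)
        over, _under = compare.estimation_discrepancies(a, b, k=3)
        assert list(over["form"]) == ["r", "q", "p"]
        assert list(over["freq"]) == sorted(over["freq"], reverse=True)


class TestDistributionProfile:
    def test_long_word_excluded_and_fraction_reported(self):
        lex, _ = lk.build_lexicon(
            {"nom": [("a" * 21 + "b" * 0, 5), ("casa", 10), ("cama", 8)]}, seed=0
        )
        profile = compare.distribution_profile(lex)
        assert profile.removed_counts["letters"] == 1
        assert profile.removed_fraction == pytest.approx(1 / 3)
        assert profile.types_by_category.sum() == 2

    def test_infinite_thresholds_keep_everything(self, demo_lex):
        profile = compare.distribution_profile(
            demo_lex,
            max_letters=np.inf, max_neighbors=np.inf,
            max_old20=np.inf, max_homographs=np.inf,
        )
        assert profile.removed_fraction == 0
        assert profile.types_by_category.sum() == demo_lex.type_total

    def test_category_counts_partition_filtered_total(self, demo_lex):
        profile = compare.distribution_profile(demo_lex)
        assert profile.types_by_category.sum() == round(
            demo_lex.type_total * (1 - profile.removed_fraction)
        )
        assert profile.types_by_length_category.to_numpy().sum() == (
            profile.types_by_category.sum()
        )


def test_noisier_corpora_correlate_less():
    """Two corpora from the same Zipfian ranks with independent log-normal
    noise: the Zipf-scale correlation decreases as the noise grows."""
    rng_master = np.random.default_rng(0)
    ranks = np.arange(1, 2001)
    base = 1e6 * ranks**-1.0
    mean_r = {}
    for sigma in (0.1, 0.5, 1.5):
        rs = []
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            fa = np.maximum(1, np.round(base * rng.lognormal(0, sigma, base.size)))
            fb = np.maximum(1, np.round(base * rng.lognormal(0, sigma, base.size)))
            names = [f"w{i}" for i in ranks]
            a = compare.CorpusFrequencyList("a", dict(zip(names, fa.astype(int))))
            b = compare.CorpusFrequencyList("b", dict(zip(names, fb.astype(int))))
            aligned = compare.align_corpora([a, b])
            r = compare.zipf_correlation(
                aligned, {"a": a.token_total, "b": b.token_total}
            )
            rs.append(r.loc["a", "b"])
        mean_r[sigma] = np.mean(rs)
    assert mean_r[0.1] > mean_r[0.5] > mean_r[1.5]


def test_read_corpus_tsv_lowercases_and_merges():
    text = "Casa\t10\ncasa\t5\naté\t2\n"
    corpus_list = compare.read_corpus_tsv(io.StringIO(text), "ext")
    assert corpus_list.entries == {"casa": 15, "até": 2}
    assert corpus_list.token_total == 17
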