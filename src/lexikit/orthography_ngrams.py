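"""Character-level orthographic structure and positional n-gram statistics.

Words are coded per character into consonant/vowel classes (C, V, plus N for
digits, A for accented vowels, P for in-word punctuation such as the hyphen,
and S for any other symbol), decomposed into boundary-marked bigrams and
trigrams (``#`` marks word start and end, ``_`` separates windows), and the
whole lexicon is aggregated into positional n-gram tables counting word
TYPES per (grammatical category, position, n-gram) — the same tables that
drive pseudoword generation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "BOUNDARY",
    "SEPARATOR",
    "DEFAULT_CVCV_MAPPING",
    "NgramTable",
    "letter_count",
    "cvcv_code",
    "reverse_form",
    "ngram_decompose",
    "ngram_windows",
    "build_ngram_table",
    "word_ngram_frequency",
]

BOUNDARY = "#"
SEPARATOR = "_"

_VOWELS = "aeiou"
_ACCENTED = "áàâãäéèêëíìîïóòôõöúùûüýÿ"
_PUNCT = "-'’"


def _default_mapping() -> dict[str, str]:
    mapping: dict[str, str] = {}
    for ch in _VOWELS:
        mapping[ch] = "V"
    for ch in "bcdfghjklmnpqrstvwxyzç":
        mapping[ch] = "C"
    for ch in _ACCENTED:
        mapping[ch] = "A"
    for ch in "0123456789":
        mapping[ch] = "N"
    for ch in _PUNCT:
        mapping[ch] = "P"
    return mapping


#: Character → class-letter table used by :func:`cvcv_code` when no custom
#: mapping is supplied. Unlisted characters (º, ª, ...) map to "S".
DEFAULT_CVCV_MAPPING: Mapping[str, str] = _default_mapping()


def letter_count(form: str) -> int:
    """Number of characters in the form; hyphens, accented letters and
    digits each count as one."""
    if not form:
        raise ValueError("empty form")
    return len(form)


def cvcv_code(form: str, mapping: Mapping[str, str] | None = None) -> str:
    """Per-character consonant/vowel class string (same length as the form).

    Classes: C consonant, V vowel, A accented vowel, N digit, P punctuation,
    S other symbol. A custom ``mapping`` must cover every character present;
    with the default mapping unknown characters fall back to S.
    """
    if not form:
        raise ValueError("empty form")
    if mapping is None:
        return "".join(DEFAULT_CVCV_MAPPING.get(ch, "S") for ch in form)
    out = []
    for ch in form:
        if ch not in mapping:
            raise ValueError(f"character {ch!r} missing from CVCV mapping")
        out.append(mapping[ch])
    return "".join(out)


def reverse_form(form: str) -> str:
    """Characters in reverse order."""
    if not form:
        raise ValueError("empty form")
    return form[::-1]


def ngram_windows(form: str, n: int) -> list[str]:
    """Sliding windows of width ``n`` over the boundary-marked form.

    A word of L letters yields L+1 bigrams and L trigrams (for L ≥ 2); the
    decomposition always slides over ``#form#``, so a 1-letter word has two
    bigrams and one trigram.
    """
    if n not in (2, 3):
        raise ValueError("n must be 2 or 3")
    if not form:
        raise ValueError("empty form")
    bounded = BOUNDARY + form + BOUNDARY
    return [bounded[i : i + n] for i in range(len(bounded) - n + 1)]


def ngram_decompose(form: str, n: int) -> str:
    """Underscore-joined bounded n-gram string, e.g. ``#c_ca_..._o#``."""
    return SEPARATOR.join(ngram_windows(form, n))


@dataclass
class NgramTable:
    """Positional n-gram type counts.

    ``counts`` maps ``(gram_cat, position, ngram)`` — position is 1-based
    over the bounded decomposition — to the number of distinct word types of
    that category containing that n-gram at that position. Marginals
    collapse position, category, or both.
    """

    n: int
    counts: dict[tuple[str, int, str], int] = field(default_factory=dict)

    def count(self, gram_cat: str, position: int, ngram: str) -> int:
        return self.counts.get((gram_cat, position, ngram), 0)

    # marginals are computed lazily and cached
    def _marginal(self, attr: str, keyfunc) -> dict:
        cache = self.__dict__.setdefault("_marginals", {})
        if attr not in cache:
            agg: dict = defaultdict(int)
            for key, value in self.counts.items():
                agg[keyfunc(key)] += value
            cache[attr] = dict(agg)
        return cache[attr]

    def count_any_position(self, gram_cat: str, ngram: str) -> int:
        """Type count collapsed over position."""
        return self._marginal("cat_gram", lambda k: (k[0], k[2])).get(
            (gram_cat, ngram), 0
        )

    def count_any_category(self, position: int, ngram: str) -> int:
        """Type count collapsed over grammatical category."""
        return self._marginal("pos_gram", lambda k: (k[1], k[2])).get(
            (position, ngram), 0
        )

    def count_total(self, ngram: str) -> int:
        """Type count collapsed over both position and category."""
        return self._marginal("gram", lambda k: k[2]).get(ngram, 0)

    def categories(self) -> frozenset[str]:
        return frozenset(k[0] for k in self.counts)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: gram_cat, position, ngram, type_count."""
        rows = [
            {"gram_cat": c, "position": p, "ngram": g, "type_count": v}
            for (c, p, g), v in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["gram_cat", "position", "ngram", "type_count"])

    def to_tsv(self, destination) -> None:
        self.to_frame().to_csv(destination, sep="\t", index=False, encoding="utf-8")


def build_ngram_table(lexicon, n: int) -> NgramTable:
    """Aggregate positional n-gram TYPE counts over a lexicon.

    ``lexicon`` may be a :class:`~lexikit.ingest.Lexicon` or its frame; each
    (orthography, gram_cat) word type contributes 1 to every
    (category, position, n-gram) cell of its decomposition regardless of its
    raw frequency. The same n-gram at two positions of one word counts at
    each position.
    """
    frame = getattr(lexicon, "frame", lexicon)
    table = NgramTable(n=n)
    counts = table.counts
    seen: set[tuple[str, str]] = set()
    for form, cat in zip(frame["orthography"], frame["gram_cat"]):
        if (form, cat) in seen:
            continue
        seen.add((form, cat))
        for pos, gram in enumerate(ngram_windows(form, n), start=1):
            key = (cat, pos, gram)
            counts[key] = counts.get(key, 0) + 1
    table.__dict__.pop("_marginals", None)
    return table


def word_ngram_frequency(
    form: str,
    gram_cat: str,
    table: NgramTable,
    *,
    collapse_position: bool = False,
    collapse_category: bool = False,
) -> int:
    """Sum of the table's type counts over the word's n-grams.

    By default each n-gram is looked up at its own position for the word's
    own category; the collapse switches sum the positional and/or categorial
    marginals instead. Unattested n-grams contribute 0, so the function also
    scores arbitrary candidate strings (pseudoword legality).
    """
    total = 0
    for pos, gram in enumerate(ngram_windows(form, table.n), start=1):
        if collapse_position and collapse_category:
            total += table.count_total(gram)
        elif collapse_position:
            total += table.count_any_position(gram_cat, gram)
        elif collapse_category:
            total += table.count_any_category(pos, gram)
        else:
            total += table.count(gram_cat, pos, gram)
    return total
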