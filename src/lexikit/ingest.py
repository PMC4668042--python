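"""Reading, cleaning and assembling POS-tagged word-frequency lists.

The input format is the one distributed by POS-tagged corpus projects:
one UTF-8 text file per grammatical category, each non-blank line holding
an orthographic form and a raw occurrence count separated by whitespace.
From these lists the module builds a :class:`Lexicon` — an ordered table
with one row per (form, category) pair carrying the full set of derived
psycholinguistic variables (frequency transforms, orthographic structure,
neighborhood measures, n-gram strings and frequencies).
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "COLUMNS",
    "FEATURE_CODES",
    "RawEntry",
    "CleaningReport",
    "Lexicon",
    "LexiconError",
    "ParseError",
    "read_frequency_list",
    "normalize_and_merge",
    "filter_entries",
    "annotate_grammatical_info",
    "assemble_lexicon",
    "build_lexicon",
    "collation_key",
    "fold",
]

#: Grammatical-category codes, in their conventional listing order.
CATEGORIES = ("adj", "adv", "gram", "nom", "num", "ver", "prop")

#: The 25 lexicon columns, in canonical order.
COLUMNS = (
    "orthography",
    "gram_cat",
    "gram_inf",
    "ortho_freq",
    "ortho_freq/M",
    "log10_ortho_freq",
    "zipf_scale",
    "zipf_rank",
    "nb_letters",
    "nb_homogr",
    "homographs",
    "pu_ortho",
    "ortho_neigh",
    "old20",
    "cvcv_ortho",
    "bigrams",
    "bigram_freq",
    "trigrams",
    "trigram_freq",
    "rev_ortho",
    "rev_cvcv_ortho",
    "rev_bigrams",
    "rev_trigrams",
    "random",
    "id",
)

#: Grammatical-information feature codes (gender, number, person, verb
#: class, mood, tense and nominal forms) allowed in ``gram_inf``.
FEATURE_CODES = frozenset(
    {
        "m", "f", "s", "p", "1", "2", "3",
        "c1", "c2", "c3",
        "ind", "sub", "imp",
        "pre", "perf", "fut",
        "inf", "ger", "pp",
    }
)

_MAX_FORM_LENGTH = 30

# Single digits plus the nine masculine/feminine ordinal forms are the only
# digit-containing entries retained, and only under adj/nom/num.
_NUMERIC_WHITELIST = frozenset(
    [str(d) for d in range(10)]
    + [f"{d}º" for d in range(1, 10)]
    + [f"{d}ª" for d in range(1, 10)]
    + [f"{d}°" for d in range(1, 10)]  # degree sign, a common ordinal variant
)
_NUMERIC_CATEGORIES = frozenset({"adj", "nom", "num"})


class LexiconError(ValueError):
    """Invalid configuration or lexicon state."""


class ParseError(LexiconError):
    """Malformed frequency-list input."""


@dataclass(frozen=True)
class RawEntry:
    """One frequency-list line: form, category and raw count."""

    orthography: str
    gram_cat: str
    raw_freq: int

    def __post_init__(self) -> None:
        if not self.orthography:
            raise LexiconError("empty orthography")
        if self.gram_cat not in CATEGORIES:
            raise LexiconError(f"unknown grammatical category: {self.gram_cat!r}")
        if self.raw_freq < 0:
            raise LexiconError(f"negative frequency for {self.orthography!r}")


@dataclass
class CleaningReport:
    """Bookkeeping for the cleaning pipeline."""

    kept: int = 0
    removed_numeric: int = 0
    removed_too_long: int = 0
    merged_case_variants: int = 0

    def __add__(self, other: "CleaningReport") -> "CleaningReport":
        return CleaningReport(
            kept=other.kept,  # "kept" reflects the latest stage
            removed_numeric=self.removed_numeric + other.removed_numeric,
            removed_too_long=self.removed_too_long + other.removed_too_long,
            merged_case_variants=self.merged_case_variants + other.merged_case_variants,
        )


@dataclass
class Lexicon:
    """An assembled lexicon: 25-column table plus corpus totals.

    ``frame`` holds one row per entry with columns :data:`COLUMNS`;
    ``token_total`` is the sum of raw frequencies over entries and
    ``type_total`` the number of entries (word types).
    """

    frame: pd.DataFrame
    token_total: int
    type_total: int
    category_tokens: dict[str, int] = field(default_factory=dict)
    category_types: dict[str, int] = field(default_factory=dict)
    lemma_types: dict[str, int] = field(default_factory=dict)

    @property
    def forms(self) -> frozenset[str]:
        """Distinct orthographic forms pooled across categories."""
        return frozenset(self.frame["orthography"])

    def to_csv(self, destination) -> None:
        self.frame.to_csv(destination, index=False, encoding="utf-8")

    @classmethod
    def from_csv(cls, source) -> "Lexicon":
        frame = pd.read_csv(
            source, encoding="utf-8", keep_default_na=False,
            dtype={"orthography": str, "gram_inf": str, "homographs": str},
        )
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise LexiconError(f"lexicon CSV missing columns: {missing}")
        frame["orthography"] = frame["orthography"].astype(str)
        lex = cls(
            frame=frame,
            token_total=int(frame["ortho_freq"].sum()),
            type_total=len(frame),
        )
        counts = frame.groupby("gram_cat")["ortho_freq"]
        lex.category_tokens = counts.sum().astype(int).to_dict()
        lex.category_types = counts.size().astype(int).to_dict()
        return lex


# ---------------------------------------------------------------------------
# collation and folding

def _strip_accents(text: str) -> str:
    return "".join(
        ch for ch in unicodedata.normalize("NFD", text) if not unicodedata.combining(ch)
    )


def fold(text: str) -> str:
    """Case- and accent-fold a string (ó → o, Ç → c) for loose matching."""
    return _strip_accents(text.lower())


def _char_key(ch: str) -> tuple[int, str, str]:
    base = _strip_accents(ch)
    base = base[0] if base else ch
    if "a" <= base <= "z" or "A" <= base <= "Z":
        return (0, base.lower(), ch)
    if ch.isdigit():
        return (1, ch, ch)
    if ch == "-":
        return (2, ch, ch)
    return (3, ch, ch)


def collation_key(form: str):
    """Total collation order: letters a–z (accents with their base letter),
    then digits 0–9, then hyphen, then anything else; code point breaks ties.
    """
    return tuple(_char_key(ch) for ch in form)


# ---------------------------------------------------------------------------
# reading and cleaning

def read_frequency_list(source: IO[str] | str | Path, gram_cat: str) -> list[RawEntry]:
    """Parse a ``form<whitespace>count`` frequency list for one category.

    Raises :class:`ParseError` naming the offending line for lines without a
    trailing integer count, and :class:`LexiconError` for unknown categories.
    """
    if gram_cat not in CATEGORIES:
        raise LexiconError(f"unknown grammatical category: {gram_cat!r}")
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return read_frequency_list(handle, gram_cat)

    entries: list[RawEntry] = []
    for lineno, line in enumerate(source, start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.rsplit(maxsplit=1)
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: expected 'form count', got {line!r}")
        form, count = parts
        try:
            freq = int(count)
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer count {count!r}") from None
        if freq < 0:
            raise ParseError(f"line {lineno}: negative count {count!r}")
        entries.append(RawEntry(form, gram_cat, freq))
    return entries


def normalize_and_merge(entries: Sequence[RawEntry]) -> tuple[list[RawEntry], CleaningReport]:
    """Lower-case orthographies and merge case variants by summing counts.

    Entries must share one grammatical category. Merging sums frequencies so
    the token total is conserved. Idempotent.
    """
    cats = {e.gram_cat for e in entries}
    if len(cats) > 1:
        raise LexiconError(f"entries span multiple categories: {sorted(cats)}")

    merged: dict[str, int] = {}
    order: list[str] = []
    n_merged = 0
    for entry in entries:
        low = entry.orthography.lower()
        if low in merged:
            merged[low] += entry.raw_freq
            n_merged += 1
        else:
            merged[low] = entry.raw_freq
            order.append(low)
    cat = next(iter(cats)) if cats else ""
    out = [RawEntry(form, cat, merged[form]) for form in order]
    report = CleaningReport(kept=len(out), merged_case_variants=n_merged)
    return out, report


def _is_numeric(form: str) -> bool:
    return any(ch.isdigit() for ch in form)


def filter_entries(
    entries: Sequence[RawEntry],
    max_length: int = _MAX_FORM_LENGTH,
) -> tuple[list[RawEntry], CleaningReport]:
    """Drop over-long and numeric entries.

    Forms longer than ``max_length`` characters are removed. Digit-containing
    forms are removed unless they are a single digit 0–9 or an ordinal
    1º–9º/1ª–9ª occurring under adj, nom or num.
    """
    kept: list[RawEntry] = []
    report = CleaningReport()
    for entry in entries:
        if len(entry.orthography) > max_length:
            report.removed_too_long += 1
            continue
        if _is_numeric(entry.orthography):
            allowed = (
                entry.orthography in _NUMERIC_WHITELIST
                and entry.gram_cat in _NUMERIC_CATEGORIES
            )
            if not allowed:
                report.removed_numeric += 1
                continue
        kept.append(entry)
    report.kept = len(kept)
    return kept, report


def annotate_grammatical_info(
    entry: RawEntry, rule_table: Mapping[tuple[str, str], str]
) -> str:
    """Look up grammatical features (gender, number, tense, ...) by suffix.

    ``rule_table`` maps ``(gram_cat, suffix)`` to a comma-separated string of
    feature codes. The longest suffix matching the entry's form wins; no
    match yields the empty string.
    """
    for (cat, _suffix), features in rule_table.items():
        if cat not in CATEGORIES:
            raise LexiconError(f"rule table uses unknown category {cat!r}")
        codes = [c.strip() for c in features.split(",") if c.strip()]
        bad = [c for c in codes if c not in FEATURE_CODES]
        if bad:
            raise LexiconError(f"rule table uses unknown feature codes {bad}")
    best = ""
    best_len = -1
    for (cat, suffix), features in rule_table.items():
        if cat == entry.gram_cat and entry.orthography.endswith(suffix):
            if len(suffix) > best_len:
                best, best_len = features, len(suffix)
    return best


# A small illustrative suffix rule table for Portuguese-like inputs. Real
# morphological annotation needs a curated table; this one covers the usual
# demo forms (2nd person present -as, masculine/feminine singular -o/-a).
DEFAULT_SUFFIX_RULES: dict[tuple[str, str], str] = {
    ("ver", "as"): "ind, pre, 2, s",
    ("ver", "ei"): "ind, perf, 1, s",
    ("nom", "o"): "m, s",
    ("nom", "a"): "f, s",
    ("nom", "os"): "m, p",
    ("nom", "as"): "f, p",
    ("adj", "a"): "f, s",
    ("adj", "o"): "m, s",
}


# ---------------------------------------------------------------------------
# assembly

def assemble_lexicon(
    entries: Iterable[RawEntry],
    seed: int,
    *,
    rule_table: Mapping[tuple[str, str], str] | None = None,
    lemma_lists: Mapping[str, Sequence[RawEntry]] | None = None,
    token_total: int | None = None,
) -> Lexicon:
    """Build the full 25-column lexicon from cleaned entries.

    Entries are sorted by descending orthographic frequency, then by
    orthography under :func:`collation_key` (category order breaks exact
    ties), and numbered ``id`` = 1..N. All derived columns are computed here
    by delegating to the frequency, orthography/n-gram and relations modules.
    The ``random`` column draws one seeded uniform per entry in id order,
    rounded (half-even) to 8 decimals.
    """
    from . import frequency, orthography_ngrams, relations

    entries = list(entries)
    if not entries:
        raise LexiconError("empty lexicon")

    cat_rank = {c: i for i, c in enumerate(CATEGORIES)}
    entries.sort(
        key=lambda e: (
            -e.raw_freq,
            collation_key(e.orthography),
            cat_rank[e.gram_cat],
        )
    )

    frame = pd.DataFrame(
        {
            "orthography": [e.orthography for e in entries],
            "gram_cat": [e.gram_cat for e in entries],
            "ortho_freq": [e.raw_freq for e in entries],
        }
    )
    total = int(frame["ortho_freq"].sum()) if token_total is None else int(token_total)

    rules = DEFAULT_SUFFIX_RULES if rule_table is None else rule_table
    frame["gram_inf"] = [annotate_grammatical_info(e, rules) for e in entries]

    # frequency transforms
    freqs = frame["ortho_freq"].to_numpy()
    frame["ortho_freq/M"] = np.round(frequency.per_million(freqs, total), 4)
    with np.errstate(divide="ignore"):
        frame["log10_ortho_freq"] = np.round(np.log10(np.maximum(freqs, 1)), 4)
        frame["zipf_scale"] = np.round(frequency.zipf_scale(np.maximum(freqs, 1), total), 4)
    frame["zipf_rank"] = frequency.zipf_rank(freqs)

    # orthographic structure
    forms_col = frame["orthography"]
    frame["nb_letters"] = forms_col.str.len()
    frame["cvcv_ortho"] = [orthography_ngrams.cvcv_code(f) for f in forms_col]
    frame["rev_ortho"] = [orthography_ngrams.reverse_form(f) for f in forms_col]
    frame["rev_cvcv_ortho"] = [orthography_ngrams.reverse_form(c) for c in frame["cvcv_ortho"]]
    frame["bigrams"] = [orthography_ngrams.ngram_decompose(f, 2) for f in forms_col]
    frame["trigrams"] = [orthography_ngrams.ngram_decompose(f, 3) for f in forms_col]
    frame["rev_bigrams"] = [
        orthography_ngrams.ngram_decompose(f, 2) for f in frame["rev_ortho"]
    ]
    frame["rev_trigrams"] = [
        orthography_ngrams.ngram_decompose(f, 3) for f in frame["rev_ortho"]
    ]

    # corpus-relative measures over distinct pooled forms
    distinct = sorted(set(forms_col), key=collation_key)
    pu = relations.uniqueness_points(distinct)
    neigh = relations.coltheart_n_all(distinct)
    # OLD20 is undefined when only one distinct form exists
    old = (
        relations.old20_all(distinct)
        if len(distinct) > 1
        else {distinct[0]: float("nan")}
    )
    frame["pu_ortho"] = forms_col.map(pu)
    frame["ortho_neigh"] = forms_col.map(neigh)
    frame["old20"] = forms_col.map(old)

    nb_homogr, homographs = relations.homograph_profile(frame)
    frame["nb_homogr"] = nb_homogr
    frame["homographs"] = homographs

    # positional n-gram tables and word-level n-gram frequencies
    bi_table = orthography_ngrams.build_ngram_table(frame, 2)
    tri_table = orthography_ngrams.build_ngram_table(frame, 3)
    frame["bigram_freq"] = [
        orthography_ngrams.word_ngram_frequency(f, c, bi_table)
        for f, c in zip(forms_col, frame["gram_cat"])
    ]
    frame["trigram_freq"] = [
        orthography_ngrams.word_ngram_frequency(f, c, tri_table)
        for f, c in zip(forms_col, frame["gram_cat"])
    ]

    rng = np.random.default_rng(seed)
    frame["random"] = np.round(rng.random(len(frame)), 8)
    frame["id"] = np.arange(1, len(frame) + 1)

    frame = frame[list(COLUMNS)]

    lexicon = Lexicon(frame=frame, token_total=total, type_total=len(frame))
    grouped = frame.groupby("gram_cat")["ortho_freq"]
    lexicon.category_tokens = grouped.sum().astype(int).to_dict()
    lexicon.category_types = grouped.size().astype(int).to_dict()
    if lemma_lists:
        lexicon.lemma_types = {cat: len(lst) for cat, lst in lemma_lists.items()}
    return lexicon


def build_lexicon(
    category_lists: Mapping[str, Sequence[RawEntry] | Sequence[tuple[str, int]]],
    seed: int,
    *,
    rule_table: Mapping[tuple[str, str], str] | None = None,
    lemma_lists: Mapping[str, Sequence[RawEntry]] | None = None,
) -> tuple[Lexicon, CleaningReport]:
    """Run the full cleaning pipeline and assemble a lexicon.

    ``category_lists`` maps category codes to entry lists (``RawEntry`` or
    plain ``(form, count)`` tuples). Each list is normalized (lower-cased,
    case variants merged by summing) and filtered (length and numeric rules)
    before assembly.
    """
    cleaned: list[RawEntry] = []
    report = CleaningReport()
    for cat, raw in category_lists.items():
        entries = [
            e if isinstance(e, RawEntry) else RawEntry(e[0], cat, int(e[1]))
            for e in raw
        ]
        merged, rep1 = normalize_and_merge(entries)
        kept, rep2 = filter_entries(merged)
        report = report + rep1 + rep2
        cleaned.extend(kept)
    lexicon = assemble_lexicon(
        cleaned, seed, rule_table=rule_table, lemma_lists=lemma_lists
    )
    report.kept = len(cleaned)
    return lexicon, report
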