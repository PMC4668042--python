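"""Pseudoword generation from positional n-gram tables.

Pseudowords — pronounceable strings absent from the lexicon — are built by
left-to-right chain sampling over the position-indexed n-gram table of one
grammatical category: start from a word-initial ``#x`` n-gram, extend at
each next position by an n-gram overlapping the current suffix, and stop on
a word-final ``x#`` n-gram within the requested length bounds. Extensions
are weighted by positional type counts by default, so generated strings
inherit the category's sub-lexical statistics; every positional n-gram of a
returned string is attested at its position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .ingest import CATEGORIES, Lexicon, LexiconError
from .orthography_ngrams import BOUNDARY, NgramTable, word_ngram_frequency

__all__ = ["PseudowordConfig", "GenerationWarning", "generate_pseudowords", "ngram_legality"]


class GenerationWarning(UserWarning):
    """Raised (as a warning) when fewer pseudowords than requested exist."""


@dataclass
class PseudowordConfig:
    """Generation settings.

    ``order`` chooses bigram or trigram chaining; ``uniform`` disables
    type-count weighting (useful for stimulus balancing); ``max_attempts``
    bounds rejection sampling (default 1000 × count).
    """

    gram_cat: str
    count: int = 10
    length_min: int = 3
    length_max: int = 10
    order: str = "bigram"
    seed: int = 0
    max_attempts: int | None = None
    uniform: bool = False

    def __post_init__(self) -> None:
        if self.gram_cat not in CATEGORIES:
            raise LexiconError(f"unknown grammatical category {self.gram_cat!r}")
        if not (1 <= self.length_min <= self.length_max <= 30):
            raise LexiconError("lengths must satisfy 1 <= min <= max <= 30")
        if self.order not in ("bigram", "trigram"):
            raise LexiconError("order must be 'bigram' or 'trigram'")
        if self.count < 1:
            raise LexiconError("count must be >= 1")
        if self.max_attempts is None:
            self.max_attempts = 1000 * self.count


def _positional_index(table: NgramTable, gram_cat: str):
    """(position, prefix) → list of (ngram, weight) for one category."""
    index: dict[tuple[int, str], list[tuple[str, int]]] = {}
    k = table.n - 1
    for (cat, pos, gram), count in table.counts.items():
        if cat != gram_cat:
            continue
        index.setdefault((pos, gram[:k]), []).append((gram, count))
    return index


def _sample_chain(
    index, n: int, length_min: int, length_max: int, rng: np.random.Generator,
    uniform: bool,
) -> str | None:
    """One chain-sampling attempt; returns a word or None on a dead end."""
    overlap = n - 1
    if n == 2:
        starts = index.get((1, BOUNDARY), [])
    else:  # trigram prefixes at position 1 are "#x": pool them all
        starts = [
            (g, c)
            for (pos, _pref), grams in index.items()
            if pos == 1
            for g, c in grams
            if g.startswith(BOUNDARY)
        ]
    if not starts:
        return None
    word = _weighted_choice(starts, rng, uniform)[1:]
    if BOUNDARY in word:  # degenerate "##" or "#x#" start
        word = word.replace(BOUNDARY, "")
        return word if length_min <= len(word) <= length_max else None

    position = 2
    while True:
        suffix = word[-overlap:]
        candidates = index.get((position, suffix), [])
        enders = [(g, c) for g, c in candidates if g.endswith(BOUNDARY)]
        extenders = [(g, c) for g, c in candidates if not g.endswith(BOUNDARY)]
        # a non-terminal extension adds one character
        can_extend = extenders and len(word) + 1 <= length_max
        can_end = enders and length_min <= len(word) <= length_max
        pool = (extenders if can_extend else []) + (enders if can_end else [])
        if not pool:
            return None
        gram = _weighted_choice(pool, rng, uniform)
        if gram.endswith(BOUNDARY):
            return word
        word += gram[-1]
        position += 1


def _weighted_choice(pool, rng: np.random.Generator, uniform: bool) -> str:
    grams = [g for g, _ in pool]
    if uniform:
        return grams[rng.integers(len(grams))]
    weights = np.array([c for _, c in pool], dtype=float)
    return grams[rng.choice(len(grams), p=weights / weights.sum())]


def generate_pseudowords(
    config: PseudowordConfig, table: NgramTable, lexicon: Lexicon | Iterable[str]
) -> list[str]:
    """Generate up to ``config.count`` distinct pseudowords.

    Every output satisfies: (a) each positional n-gram, boundary n-grams
    included, is attested in ``table`` at its position for the category;
    (b) the string is absent from the lexicon's orthographies; (c) the
    length is within bounds. Same seed, same output. If ``max_attempts``
    runs out the partial list is returned with a :class:`GenerationWarning`.
    """
    if config.gram_cat not in table.categories() and table.counts:
        raise LexiconError(
            f"table holds no n-grams for category {config.gram_cat!r}"
        )
    forms = lexicon.forms if isinstance(lexicon, Lexicon) else frozenset(lexicon)
    index = _positional_index(table, config.gram_cat)
    rng = np.random.default_rng(config.seed)

    found: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(found) < config.count and attempts < config.max_attempts:
        attempts += 1
        word = _sample_chain(
            index, table.n, config.length_min, config.length_max, rng, config.uniform
        )
        if word is None or word in seen or word in forms:
            continue
        seen.add(word)
        found.append(word)
    if len(found) < config.count:
        warnings.warn(
            f"generated {len(found)} of {config.count} requested pseudowords "
            f"after {attempts} attempts",
            GenerationWarning,
            stacklevel=2,
        )
    return found


def ngram_legality(form: str, gram_cat: str, table: NgramTable) -> int:
    """Sum of positional type counts over the candidate's n-grams.

    Identical to the lexicon's word-level n-gram frequency, applied to an
    arbitrary string: unattested n-grams contribute 0, so higher scores mean
    more lexicon-like sub-lexical structure.
    """
    return word_ngram_frequency(form, gram_cat, table)
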