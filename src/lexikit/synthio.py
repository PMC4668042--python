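"""Synthetic frequency lists and the built-in demonstration lexicon.

Real POS-tagged frequency lists are large and externally hosted, so the
toolkit ships two generators. :func:`generate_synthetic_lexicon` draws a
Zipfian toy lexicon — distinct pronounceable CV-alternating forms whose
rank-frequency curve follows ``freq(r) = max(1, round(C·r^-a))`` — split
over grammatical categories in realistic proportions. :func:`demo_corpus`
returns a small fixed lexicon embedding the canonical worked-example words
(cachorro, the homograph ativa, the wildcard example sets) so searches and
statistics are reproducible without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .ingest import CATEGORIES, Lexicon, RawEntry, build_lexicon

__all__ = [
    "SyntheticSpec",
    "generate_synthetic_lexicon",
    "demo_corpus",
    "demo_lexicon",
    "write_frequency_lists",
]

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"

#: Category mix loosely matching a written-language POS-tagged corpus:
#: nouns and verbs dominate, adjectives about half of either, closed
#: categories a sliver.
_DEFAULT_MIX = {
    "nom": 0.40,
    "ver": 0.39,
    "adj": 0.18,
    "adv": 0.012,
    "gram": 0.012,
    "num": 0.006,
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic Zipfian lexicon.

    ``zipf_exponent`` is the rank-frequency power-law slope magnitude;
    ``top_freq`` the frequency of rank 1; lengths are drawn from a normal
    (``length_mean``, ``length_sd``) clipped to [1, 30], matching typical
    written-corpus word lengths.
    """

    n_types: int = 1000
    zipf_exponent: float = 1.0
    top_freq: int = 100_000
    alphabet_consonants: str = _CONSONANTS
    alphabet_vowels: str = _VOWELS
    length_mean: float = 9.0
    length_sd: float = 3.0
    category_mix: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_MIX))
    seed: int = 0
    cv_alternating: bool = True

    def __post_init__(self) -> None:
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category mix must sum to 1, got {total}")
        unknown = set(self.category_mix) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in mix: {sorted(unknown)}")


def _random_form(rng: np.random.Generator, spec: SyntheticSpec) -> str:
    length = int(np.clip(round(rng.normal(spec.length_mean, spec.length_sd)), 1, 30))
    cons, vows = spec.alphabet_consonants, spec.alphabet_vowels
    if spec.cv_alternating:
        start_c = rng.random() < 0.5
        chars = []
        for i in range(length):
            pool = cons if (i % 2 == 0) == start_c else vows
            chars.append(pool[rng.integers(len(pool))])
        return "".join(chars)
    pool = cons + vows
    return "".join(pool[rng.integers(len(pool))] for _ in range(length))


def generate_synthetic_lexicon(spec: SyntheticSpec) -> dict[str, list[RawEntry]]:
    """Per-category frequency lists with a Zipfian rank-frequency shape.

    Produces ``n_types`` distinct forms with
    ``freq(rank r) = max(1, round(top_freq · r^-zipf_exponent))``, assigned
    to categories by the mix proportions. Deterministic in ``seed``.
    """
    rng = np.random.default_rng(spec.seed)
    forms: list[str] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 200 * spec.n_types + 1000
    while len(forms) < spec.n_types:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "alphabet/length settings cannot produce enough distinct forms"
            )
        form = _random_form(rng, spec)
        if form not in seen:
            seen.add(form)
            forms.append(form)

    ranks = np.arange(1, spec.n_types + 1)
    freqs = np.maximum(
        1, np.round(spec.top_freq * ranks ** (-spec.zipf_exponent))
    ).astype(int)

    cats = list(spec.category_mix)
    probs = np.array([spec.category_mix[c] for c in cats])
    assignment = rng.choice(len(cats), size=spec.n_types, p=probs)

    lists: dict[str, list[RawEntry]] = {c: [] for c in cats}
    for form, freq, idx in zip(forms, freqs, assignment):
        cat = cats[idx]
        lists[cat].append(RawEntry(form, cat, int(freq)))
    return {c: lst for c, lst in lists.items() if lst}


# ---------------------------------------------------------------------------
# fixed demonstration corpus

def demo_corpus() -> dict[str, list[RawEntry]]:
    """Small deterministic per-category frequency lists for demos and tests.

    Synthetic stand-in for a full POS-tagged corpus: embeds the canonical
    example words — cachorro (noun, 397), the three-way homograph ativa,
    the wildcard example sets {amor, anos, aloe, após} (pattern ``a_o_``)
    and {amor, ama, amei, amava} (pattern ``am%``) — plus fillers (neighbor
    clusters, a hyphenated compound, accented and numeric forms) so every
    derived column is non-degenerate. Byte-identical across calls.
    """
    data: dict[str, list[tuple[str, int]]] = {
        "adj": [("ativa", 15), ("cara", 31), ("rara", 9)],
        "adv": [("após", 85), ("quase", 10)],
        "gram": [("até", 300), ("com", 800), ("para", 500)],
        "nom": [
            ("cachorro", 397),
            ("amor", 120),
            ("anos", 95),
            ("aloe", 8),
            ("aposta", 25),
            ("casa", 200),
            ("casas", 60),
            ("cama", 50),
            ("cana", 7),
            ("dama", 9),
            ("ativa", 12),
            ("ama", 6),
            ("guarda-chuva", 4),
        ],
        "num": [("9", 11), ("3", 17)],
        "ver": [
            ("ama", 45),
            ("amei", 20),
            ("amava", 18),
            ("falas", 5),
            ("ativa", 4),
            ("come", 33),
        ],
    }
    return {
        cat: [RawEntry(form, cat, freq) for form, freq in rows]
        for cat, rows in data.items()
    }


def demo_lexicon(seed: int = 42) -> Lexicon:
    """The demonstration corpus run through the full build pipeline."""
    lexicon, _report = build_lexicon(demo_corpus(), seed=seed)
    return lexicon


def write_frequency_lists(
    lists: Mapping[str, list[RawEntry]], directory: str | Path
) -> dict[str, Path]:
    """Write per-category ``form count`` text files; returns category → path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cat, entries in lists.items():
        path = directory / f"{cat}.txt"
        with open(path, "w", encoding="utf-8") as handle:
            for entry in entries:
                handle.write(f"{entry.orthography} {entry.raw_freq}\n")
        paths[cat] = path
    return paths
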