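"""Cross-corpus validation and within-lexicon distribution profiles.

Frequency norms from different corpora are compared on the Zipf scale
(which removes corpus size from the comparison): corpora are aligned on
word types common to all with positive frequency, correlated pairwise
(Pearson), and correlation differences are tested with Fisher r-to-z
contrasts. Type-level coverage is summarized as a containment matrix
(percentage of one corpus's types present in another) and as ranked lists
of words one corpus over- or under-estimates relative to another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .frequency import zipf_scale
from .ingest import Lexicon

__all__ = [
    "CorpusFrequencyList",
    "DistributionProfile",
    "collapse_homographs",
    "read_corpus_tsv",
    "align_corpora",
    "zipf_correlation",
    "fisher_rz_contrast",
    "containment_matrix",
    "estimation_discrepancies",
    "distribution_profile",
]


@dataclass
class CorpusFrequencyList:
    """A named corpus reduced to form → raw frequency.

    ``token_total`` defaults to the sum of frequencies; pass an explicit
    total when the source corpus states one.
    """

    name: str
    entries: dict[str, int]
    token_total: int | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.entries.values()):
            raise ValueError("negative frequency in corpus list")
        if self.token_total is None:
            self.token_total = int(sum(self.entries.values()))

    @property
    def types(self) -> frozenset[str]:
        return frozenset(self.entries)

    def zipf(self, form: str) -> float:
        return zipf_scale(self.entries[form], self.token_total)


def collapse_homographs(lexicon: Lexicon, name: str = "lexicon") -> CorpusFrequencyList:
    """Sum homograph frequencies into one record per orthographic form."""
    sums = lexicon.frame.groupby("orthography")["ortho_freq"].sum()
    return CorpusFrequencyList(
        name=name,
        entries={form: int(freq) for form, freq in sums.items()},
        token_total=lexicon.token_total,
    )


def read_corpus_tsv(source: IO[str] | str | Path, name: str) -> CorpusFrequencyList:
    """Read an external two-column (form, count) TSV frequency list.

    Forms are lower-cased; accents are preserved so that cross-corpus
    matching stays exact and does not manufacture spurious overlap.
    """
    frame = pd.read_csv(
        source, sep="\t", header=None, names=["form", "count"],
        dtype={"form": str}, keep_default_na=False, encoding="utf-8",
    )
    entries: dict[str, int] = {}
    for form, count in zip(frame["form"], frame["count"]):
        entries[form.lower()] = entries.get(form.lower(), 0) + int(count)
    return CorpusFrequencyList(name=name, entries=entries)


def align_corpora(lists: Sequence[CorpusFrequencyList]) -> pd.DataFrame:
    """Frequency table over forms present with frequency > 0 in EVERY list.

    Columns are corpus names, rows are the common word types; an empty
    intersection yields an empty table.
    """
    if len(lists) < 2:
        raise ValueError("alignment needs at least two corpora")
    common: set[str] | None = None
    for corpus in lists:
        positive = {f for f, v in corpus.entries.items() if v > 0}
        common = positive if common is None else common & positive
    forms = sorted(common or ())
    data = {corpus.name: [corpus.entries[f] for f in forms] for corpus in lists}
    return pd.DataFrame(data, index=forms)


def zipf_correlation(
    aligned: pd.DataFrame, totals: Mapping[str, int]
) -> pd.DataFrame:
    """Pairwise Pearson correlation of Zipf-scale values.

    Each corpus's frequencies are put on the Zipf scale with its own token
    total before correlating; requires at least 3 aligned forms.
    """
    if len(aligned) < 3:
        raise ValueError("Zipf correlation needs at least 3 aligned forms")
    zipfs = pd.DataFrame(
        {
            name: zipf_scale(aligned[name].to_numpy(), totals[name])
            for name in aligned.columns
        },
        index=aligned.index,
    )
    return zipfs.corr(method="pearson")


def fisher_rz_contrast(r1: float, n1: int, r2: float, n2: int) -> float:
    """z statistic for the difference of two independent correlations:
    ``(atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))``.
    """
    for r in (r1, r2):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("sample sizes must exceed 3")
    return (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )


def containment_matrix(lists: Sequence[CorpusFrequencyList]) -> pd.DataFrame:
    """Percentage of row-corpus types present in the column corpus.

    ``cell(A, B) = |types(A) ∩ types(B)| / |types(A)| × 100``; the diagonal
    is 100 by construction.
    """
    if len(lists) < 2:
        raise ValueError("containment needs at least two corpora")
    for corpus in lists:
        if not corpus.entries:
            raise ValueError(f"corpus {corpus.name!r} is empty")
    names = [c.name for c in lists]
    types = {c.name: c.types for c in lists}
    matrix = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in lists:
        for b in lists:
            shared = len(types[a.name] & types[b.name])
            matrix.loc[a.name, b.name] = round(100.0 * shared / len(types[a.name]), 2)
    return matrix


def estimation_discrepancies(
    a: CorpusFrequencyList, b: CorpusFrequencyList, k: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Words each corpus over-estimates relative to the other.

    Over-estimated: the k most frequent forms of ``a`` absent from ``b``;
    under-estimated: the k most frequent forms of ``b`` absent from ``a``.
    Each list carries the owning corpus's Zipf-scale value and is ordered by
    descending frequency.
    """
    if not a.entries or not b.entries:
        raise ValueError("both corpora must be non-empty")

    def top_missing(src: CorpusFrequencyList, other: CorpusFrequencyList) -> pd.DataFrame:
        missing = [
            (form, freq)
            for form, freq in src.entries.items()
            if freq > 0 and form not in other.entries
        ]
        missing.sort(key=lambda item: (-item[1], item[0]))
        rows = [
            {"form": form, "freq": freq, "zipf_scale": round(src.zipf(form), 4)}
            for form, freq in missing[:k]
        ]
        return pd.DataFrame(rows, columns=["form", "freq", "zipf_scale"])

    return top_missing(a, b), top_missing(b, a)


@dataclass
class DistributionProfile:
    """Outlier-filtered distribution summaries of one lexicon."""

    removed_fraction: float
    removed_counts: dict[str, int]
    types_by_category: pd.Series
    types_by_length_category: pd.DataFrame
    rank_frequency: pd.DataFrame  # log10 freq vs log10 rank, per category
    mean_neigh_by_length_category: pd.DataFrame
    mean_old20_by_length_category: pd.DataFrame


def distribution_profile(
    lexicon: Lexicon,
    *,
    max_letters: float = 20,
    max_neighbors: float = 40,
    max_old20: float = 14,
    max_homographs: float = 5,
) -> DistributionProfile:
    """Outlier-filtered distribution summaries.

    Entries with more than ``max_letters`` letters, ``max_neighbors``
    orthographic neighbors, ``max_old20`` OLD20 or ``max_homographs``
    homographs are removed (set a threshold to ``inf`` to disable it); the
    remaining entries are profiled by category and word length.
    """
    frame = lexicon.frame
    if frame.empty:
        raise ValueError("empty lexicon")
    removals = {
        "letters": frame["nb_letters"] > max_letters,
        "neighbors": frame["ortho_neigh"] > max_neighbors,
        "old20": frame["old20"] > max_old20,
        "homographs": frame["nb_homogr"] > max_homographs,
    }
    drop = pd.Series(False, index=frame.index)
    removed_counts = {}
    for label, mask in removals.items():
        removed_counts[label] = int(mask.sum())
        drop |= mask
    kept = frame[~drop]

    rank_freq = pd.DataFrame(
        {
            "gram_cat": kept["gram_cat"].to_numpy(),
            "log10_rank": np.log10(kept["zipf_rank"].to_numpy(dtype=float)),
            "log10_freq": np.log10(kept["ortho_freq"].to_numpy(dtype=float)),
        }
    )
    return DistributionProfile(
        removed_fraction=round(float(drop.sum()) / len(frame), 6),
        removed_counts=removed_counts,
        types_by_category=kept.groupby("gram_cat").size(),
        types_by_length_category=kept.pivot_table(
            index="nb_letters", columns="gram_cat", values="orthography",
            aggfunc="count", fill_value=0,
        ),
        rank_frequency=rank_freq,
        mean_neigh_by_length_category=kept.pivot_table(
            index="nb_letters", columns="gram_cat", values="ortho_neigh",
            aggfunc="mean",
        ),
        mean_old20_by_length_category=kept.pivot_table(
            index="nb_letters", columns="gram_cat", values="old20",
            aggfunc="mean",
        ),
    )
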