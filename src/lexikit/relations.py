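"""Corpus-relative lexical measures.

All measures here depend on the whole lexicon, not on a single word: the
orthographic uniqueness point (leftmost position at which a word's prefix
is shared by no other word), Coltheart's N (same-length neighbors at
Hamming distance 1), OLD20 (mean Levenshtein distance to the 20 closest
words) and homograph profiles. The three form-based measures operate on the
set of DISTINCT orthographic forms pooled across grammatical categories — a
homograph is never its own neighbor.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .ingest import CATEGORIES

__all__ = [
    "uniqueness_point",
    "uniqueness_points",
    "coltheart_n",
    "coltheart_n_all",
    "old20",
    "old20_all",
    "homograph_profile",
]


# ---------------------------------------------------------------------------
# orthographic uniqueness point

def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def uniqueness_points(forms: Sequence[str]) -> dict[str, int]:
    """Uniqueness point for every distinct form.

    The longest common prefix a form shares with any other form is attained
    at an adjacent form in sorted order, so one sorted pass suffices. A form
    that is a prefix of another form has no disambiguating position and gets
    length + 1.
    """
    distinct = sorted(set(forms))
    out: dict[str, int] = {}
    for i, form in enumerate(distinct):
        shared = 0
        if i > 0:
            shared = max(shared, _lcp(form, distinct[i - 1]))
        if i + 1 < len(distinct):
            shared = max(shared, _lcp(form, distinct[i + 1]))
        out[form] = min(shared + 1, len(form) + 1)
    return out


def uniqueness_point(form: str, forms: Iterable[str]) -> int:
    """Smallest k such that no other form shares the first k characters."""
    pool = set(forms)
    if form not in pool:
        raise ValueError(f"{form!r} not in the form set")
    return uniqueness_points(pool)[form]


# ---------------------------------------------------------------------------
# Coltheart's N

def _hamming_neighbors_matrix(group: list[str]) -> np.ndarray:
    """Neighbor counts within one same-length group (vectorized)."""
    arr = np.array([[ord(c) for c in w] for w in group], dtype=np.int32)
    counts = np.zeros(len(group), dtype=np.int64)
    # block over rows to bound memory on large groups
    block = max(1, 2_000_000 // max(arr.size, 1))
    for start in range(0, len(group), block):
        sub = arr[start : start + block]
        diffs = (sub[:, None, :] != arr[None, :, :]).sum(axis=2)
        counts[start : start + block] = (diffs == 1).sum(axis=1)
    return counts


def coltheart_n_all(forms: Sequence[str]) -> dict[str, int]:
    """Coltheart's N for every distinct form (grouped by length)."""
    by_len: dict[int, list[str]] = defaultdict(list)
    for form in set(forms):
        by_len[len(form)].append(form)
    out: dict[str, int] = {}
    for group in by_len.values():
        if len(group) == 1:
            out[group[0]] = 0
            continue
        counts = _hamming_neighbors_matrix(group)
        for form, count in zip(group, counts):
            out[form] = int(count)
    return out


def coltheart_n(form: str, forms: Iterable[str]) -> int:
    """Count of OTHER forms of the same length at Hamming distance 1."""
    if not form:
        raise ValueError("empty form")
    count = 0
    for other in set(forms):
        if other == form or len(other) != len(form):
            continue
        if sum(a != b for a, b in zip(form, other)) == 1:
            count += 1
    return count


# ---------------------------------------------------------------------------
# OLD20

def old20_all(forms: Sequence[str], k: int = 20) -> dict[str, float]:
    """Mean Levenshtein distance to the k nearest other forms, for all forms.

    Candidates are scanned in order of length difference from the target:
    since the edit distance is bounded below by the length difference, the
    scan stops as soon as the next length band cannot improve the current
    k-th smallest distance. Distances come from edlib (unit-cost
    insertions, deletions, substitutions).
    """
    distinct = sorted(set(forms))
    if len(distinct) < 2:
        raise ValueError("OLD20 needs at least two distinct forms")
    by_len: dict[int, list[str]] = defaultdict(list)
    for form in distinct:
        by_len[len(form)].append(form)
    lengths = sorted(by_len)

    out: dict[str, float] = {}
    for form in distinct:
        length = len(form)
        dists: list[int] = []
        # length bands in increasing |Δlen|
        for delta in range(0, max(lengths[-1] - length, length - lengths[0]) + 1):
            if len(dists) >= k:
                kth = sorted(dists)[k - 1] if len(dists) >= k else None
                if kth is not None and delta > kth:
                    break
            bands = {length + delta, length - delta} & set(lengths)
            for band in bands:
                for other in by_len[band]:
                    if other == form:
                        continue
                    d = edlib.align(form, other, task="distance")["editDistance"]
                    dists.append(d)
        dists.sort()
        nearest = dists[:k]
        out[form] = round(float(np.mean(nearest)), 4)
    return out


def old20(form: str, forms: Iterable[str], k: int = 20) -> float:
    """Mean Levenshtein distance from ``form`` to its k nearest other forms.

    With fewer than k other forms the mean runs over all of them. Ties at
    the k-th distance are resolved on the distance multiset (the k smallest
    distances), never by word identity.
    """
    others = sorted(set(forms) - {form})
    if not others:
        raise ValueError("OLD20 needs at least one other form")
    dists = sorted(
        edlib.align(form, other, task="distance")["editDistance"] for other in others
    )
    return round(float(np.mean(dists[:k])), 4)


# ---------------------------------------------------------------------------
# homographs

def homograph_profile(frame: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-entry homograph count and category listing.

    For each row, ``nb_homogr`` is the number of distinct grammatical
    categories in which the row's orthographic form occurs (its own category
    included) and ``homographs`` lists those codes, comma-separated, in
    conventional category order.
    """
    order = {c: i for i, c in enumerate(CATEGORIES)}
    cats_by_form = (
        frame.groupby("orthography")["gram_cat"]
        .agg(lambda cats: sorted(set(cats), key=order.__getitem__))
        .to_dict()
    )
    nb = frame["orthography"].map(lambda f: len(cats_by_form[f]))
    listing = frame["orthography"].map(lambda f: ", ".join(cats_by_form[f]))
    return nb, listing
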