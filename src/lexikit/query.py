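"""Lexicon search: word-list lookup, multi-criterion filtering, statistics.

Two engines are provided. The simple engine matches a user-supplied word
list against the lexicon (case- and accent-insensitively by default). The
complex engine combines column criteria — wildcard patterns on string
columns (``_`` one character, ``%`` any chain) and strict range expressions
on numeric columns (``< x``, ``> y``, ``< x > y`` open interval) — as a
conjunction, orders and pages the results, computes on-the-fly statistics
and exports the full result set as RFC-4180 CSV.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ingest import COLUMNS, Lexicon, collation_key, fold

__all__ = [
    "STRING_COLUMNS",
    "NUMERIC_COLUMNS",
    "STATS_COLUMNS",
    "QueryError",
    "Criterion",
    "SearchResult",
    "SearchStats",
    "match_pattern",
    "simple_search",
    "complex_search",
    "result_statistics",
    "export_csv",
]

STRING_COLUMNS = frozenset(
    {
        "orthography", "gram_cat", "gram_inf", "homographs", "cvcv_ortho",
        "bigrams", "trigrams", "rev_ortho", "rev_cvcv_ortho", "rev_bigrams",
        "rev_trigrams",
    }
)
NUMERIC_COLUMNS = frozenset(COLUMNS) - STRING_COLUMNS

#: Columns summarized by :func:`result_statistics`.
STATS_COLUMNS = (
    "ortho_freq", "log10_ortho_freq", "zipf_scale", "bigram_freq",
    "trigram_freq", "nb_letters", "ortho_neigh", "old20",
)

#: Accepted aliases for column names in criteria.
_COLUMN_ALIASES = {"freq_ortho": "ortho_freq", "homogr": "homographs"}


class QueryError(ValueError):
    """Malformed search request."""


@dataclass(frozen=True)
class Criterion:
    """One search condition on a lexicon column.

    ``expression`` is a wildcard pattern for string columns or a range
    expression for numeric columns. ``mode`` "include" keeps rows satisfying
    the condition, "exclude" negates it; ``enabled=False`` disables the
    criterion without removing it from the query.
    """

    column: str
    expression: str
    mode: str = "include"
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("include", "exclude"):
            raise QueryError(f"unknown criterion mode {self.mode!r}")


@dataclass
class SearchResult:
    """Result of a search: one visible page plus the full match set."""

    matches: pd.DataFrame
    page: int = 1
    page_size: int = 50
    unmatched: list[str] = field(default_factory=list)

    @property
    def total_found(self) -> int:
        return len(self.matches)

    @property
    def rows(self) -> pd.DataFrame:
        start = (self.page - 1) * self.page_size
        return self.matches.iloc[start : start + self.page_size]

    @property
    def n_pages(self) -> int:
        return max(1, -(-len(self.matches) // self.page_size))


@dataclass
class SearchStats:
    """Max/min/mean of the eight summary columns, or empty for no matches."""

    table: pd.DataFrame | None

    @property
    def empty(self) -> bool:
        return self.table is None


# ---------------------------------------------------------------------------
# pattern matching

def _compile_pattern(pattern: str, strict: bool) -> re.Pattern:
    parts = []
    for ch in pattern:
        if ch == "_":
            parts.append(".")
        elif ch == "%":
            parts.append(".*")
        else:
            parts.append(re.escape(ch if strict else fold(ch)))
    return re.compile("".join(parts) + r"\Z", re.DOTALL)


def match_pattern(pattern: str, value: str, strict: bool = False) -> bool:
    """Wildcard match: ``_`` matches exactly one character, ``%`` any
    (possibly empty) chain. Literal characters compare case- and
    accent-insensitively unless ``strict`` is set.
    """
    if not pattern:
        raise QueryError("empty pattern")
    target = value if strict else fold(value)
    return _compile_pattern(pattern, strict).match(target) is not None


_RANGE_RE = re.compile(
    r"^\s*(?P<op1>[<>])\s*(?P<v1>-?\d+(?:\.\d+)?)"
    r"(?:\s*(?P<op2>[<>])\s*(?P<v2>-?\d+(?:\.\d+)?))?\s*$"
)


def _range_predicate(expression: str):
    """Parse ``< x``, ``> y`` or ``< x > y`` into a strict-inequality test."""
    m = _RANGE_RE.match(expression)
    if not m:
        raise QueryError(f"malformed range expression {expression!r}")
    lo = hi = None
    for op, val in ((m["op1"], m["v1"]), (m["op2"], m["v2"])):
        if op is None:
            continue
        val = float(val)
        if op == "<":
            if hi is not None:
                raise QueryError(f"duplicate '<' in {expression!r}")
            hi = val
        else:
            if lo is not None:
                raise QueryError(f"duplicate '>' in {expression!r}")
            lo = val

    def predicate(values: pd.Series) -> pd.Series:
        mask = pd.Series(True, index=values.index)
        if hi is not None:
            mask &= values < hi
        if lo is not None:
            mask &= values > lo
        return mask

    return predicate


# ---------------------------------------------------------------------------
# engines

def _frame(lexicon) -> pd.DataFrame:
    return getattr(lexicon, "frame", lexicon)


def simple_search(
    words: Sequence[str],
    lexicon: Lexicon,
    *,
    strict: bool = False,
    page: int = 1,
    page_size: int = 50,
) -> SearchResult:
    """Find all entries whose orthography matches any listed word.

    Comparison folds case and accents unless ``strict``; words with no hit
    are reported in ``result.unmatched``.
    """
    if not words:
        raise QueryError("empty word list")
    frame = _frame(lexicon)
    key = frame["orthography"] if strict else frame["orthography"].map(fold)
    wanted = {w if strict else fold(w): w for w in words}
    mask = key.isin(wanted)
    matches = frame[mask]
    hit_keys = set(key[mask])
    unmatched = [orig for folded, orig in wanted.items() if folded not in hit_keys]
    return SearchResult(matches=matches.reset_index(drop=True), page=page,
                        page_size=page_size, unmatched=unmatched)


def _criterion_mask(frame: pd.DataFrame, criterion: Criterion, strict: bool) -> pd.Series:
    column = _COLUMN_ALIASES.get(criterion.column, criterion.column)
    if column not in COLUMNS:
        raise QueryError(f"unknown column {criterion.column!r}")
    if column in NUMERIC_COLUMNS:
        mask = _range_predicate(criterion.expression)(frame[column])
    else:
        pattern = criterion.expression
        if not pattern:
            raise QueryError("empty pattern")
        compiled = _compile_pattern(pattern, strict)
        values = frame[column] if strict else frame[column].map(fold)
        mask = values.map(lambda v: compiled.match(v) is not None)
    if criterion.mode == "exclude":
        mask = ~mask
    return mask


def _sort_frame(frame: pd.DataFrame, column: str, ascending: bool) -> pd.DataFrame:
    if column in STRING_COLUMNS:
        key = frame[column].map(collation_key)
        order = key.sort_values(kind="mergesort", ascending=ascending).index
        return frame.loc[order]
    return frame.sort_values(column, kind="mergesort", ascending=ascending)


def complex_search(
    criteria: Sequence[Criterion],
    lexicon: Lexicon,
    *,
    order: tuple[str, str] = ("id", "asc"),
    page: int = 1,
    page_size: int = 50,
    strict: bool = False,
) -> SearchResult:
    """Filter the lexicon by the conjunction of the enabled criteria.

    Include-criteria must all hold and exclude-criteria must all fail for a
    row to match; results are sorted by the ``order`` column and direction
    (stable, with the collation order of the build for string columns).
    """
    frame = _frame(lexicon)
    mask = pd.Series(True, index=frame.index)
    for criterion in criteria:
        if not criterion.enabled:
            continue
        mask &= _criterion_mask(frame, criterion, strict)
    matches = frame[mask]

    column, direction = order
    column = _COLUMN_ALIASES.get(column, column)
    if column not in COLUMNS:
        raise QueryError(f"unknown order column {order[0]!r}")
    if direction not in ("asc", "desc"):
        raise QueryError(f"order direction must be asc or desc, got {direction!r}")
    matches = _sort_frame(matches, column, direction == "asc")
    return SearchResult(matches=matches.reset_index(drop=True), page=page,
                        page_size=page_size)


def result_statistics(result: SearchResult) -> SearchStats:
    """Exact max/min/mean of the eight summary columns over ALL matches.

    An empty result yields an empty-stats marker rather than an exception.
    """
    if result.total_found == 0:
        return SearchStats(table=None)
    data = result.matches[list(STATS_COLUMNS)].astype(float)
    table = pd.DataFrame(
        {"max": data.max(), "min": data.min(), "mean": data.mean()}
    )
    return SearchStats(table=table)


def export_csv(result: SearchResult, destination) -> None:
    """Write ALL matching rows (not just the current page) as UTF-8 CSV with
    the canonical column header and RFC-4180 quoting."""
    frame = result.matches
    if list(frame.columns) != list(COLUMNS):
        frame = frame[[c for c in COLUMNS if c in frame.columns]]
    frame.to_csv(
        destination, index=False, encoding="utf-8",
        quoting=csv.QUOTE_MINIMAL, lineterminator="\r\n",
    )
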