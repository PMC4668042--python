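"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — plain Python loops and textbook
dynamic programming — so the oracles share no code path with the package
implementations they check.
"""

from __future__ import annotations

import unicodedata


def levenshtein(a: str, b: str) -> int:
    """Textbook Wagner–Fischer edit distance (unit costs)."""
    if a == b:
        return 0
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        curr = [i]
        for j, cb in enumerate(b, start=1):
            curr.append(
                min(prev[j] + 1, curr[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = curr
    return prev[-1]


def old20_bruteforce(form: str, forms, k: int = 20) -> float:
    """All-pairs distance matrix, sort, average the k smallest."""
    dists = sorted(levenshtein(form, other) for other in forms if other != form)
    nearest = dists[:k]
    return sum(nearest) / len(nearest)


def coltheart_bruteforce(form: str, forms) -> int:
    count = 0
    for other in forms:
        if other == form or len(other) != len(form):
            continue
        if sum(x != y for x, y in zip(form, other)) == 1:
            count += 1
    return count


def uniqueness_bruteforce(form: str, forms) -> int:
    others = [f for f in forms if f != form]
    for k in range(1, len(form) + 1):
        if not any(f[:k] == form[:k] for f in others):
            return k
    return len(form) + 1


def fold_naive(text: str) -> str:
    return "".join(
        ch
        for ch in unicodedata.normalize("NFD", text.lower())
        if not unicodedata.combining(ch)
    )


def wildcard_match_bruteforce(pattern: str, value: str) -> bool:
    """Recursive wildcard matcher: `_` one char, `%` any chain; folded."""
    p, v = fold_naive(pattern), fold_naive(value)

    def rec(i: int, j: int) -> bool:
        if i == len(p):
            return j == len(v)
        if p[i] == "%":
            return any(rec(i + 1, jj) for jj in range(j, len(v) + 1))
        if j == len(v):
            return False
        if p[i] == "_" or p[i] == v[j]:
            return rec(i + 1, j + 1)
        return False

    return rec(0, 0)
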