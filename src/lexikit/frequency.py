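"""Word-frequency transforms.

Raw occurrence counts are put on the scales psycholinguists actually use:
occurrences per million tokens, the common logarithm, the Zipf scale
(``log10(frequency per million) + 3``, a corpus-size-independent 1–7 scale)
and the Zipf rank (dense rank by descending frequency, ties sharing a rank).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["per_million", "log10_frequency", "zipf_scale", "zipf_rank"]


def per_million(freq, total: int):
    """Frequency per million tokens: ``freq / total * 1e6``.

    ``freq`` may be a scalar or array of raw counts; ``total`` is the corpus
    token count and must be positive.
    """
    if total <= 0:
        raise ValueError("corpus token total must be positive")
    freq = np.asarray(freq, dtype=float)
    if np.any(freq < 0):
        raise ValueError("raw frequencies must be non-negative")
    result = freq / total * 1_000_000.0
    return result.item() if result.ndim == 0 else result


def log10_frequency(freq):
    """Common logarithm of the raw count; defined only for counts ≥ 1."""
    freq = np.asarray(freq, dtype=float)
    if np.any(freq < 1):
        raise ValueError("log10 frequency is defined only for counts >= 1")
    result = np.log10(freq)
    return result.item() if result.ndim == 0 else result


def zipf_scale(freq, total: int):
    """Zipf scale value: ``log10(per-million frequency) + 3``."""
    freq = np.asarray(freq, dtype=float)
    if np.any(freq < 1):
        raise ValueError("Zipf scale is defined only for counts >= 1")
    result = np.log10(per_million(freq, total)) + 3.0
    return result.item() if result.ndim == 0 else result


def zipf_rank(freqs) -> np.ndarray:
    """Dense frequency ranks: rank 1 for the highest distinct frequency,
    incrementing by one per distinct value; equal frequencies share a rank.
    """
    freqs = np.asarray(freqs)
    if freqs.size == 0:
        raise ValueError("cannot rank an empty frequency list")
    ranks = pd.Series(freqs).rank(method="dense", ascending=False)
    return ranks.to_numpy().astype(int)
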