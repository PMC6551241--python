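"""Analytic cache-miss predictions under a single-level LRU cache model.

The model: one cache of ``l`` lines holding ``w`` words each (capacity lw
words), LRU replacement, memory transferred in line-sized blocks.  Under it
the approximate miss counts are

    DL, LS_DL       : m n (1 + 3/w)
    Strip_DL        : 2 (s+1) m n / (w q)      valid for q < lw/(s+1)
    LSDL_TRACE      : 2 m n (1 + 3/w)
    Strip_TRACE     : 4 (s+1) m n / (w q)

so the full/linear-space scorers miss (wq + 3q)/(2s + 2) times as often as
the strip scorer.  These are approximations (real-valued), intended for
what-if comparisons, not hardware measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = ["CacheParams", "predict_misses", "miss_ratio", "ALGORITHMS"]

ALGORITHMS = ("dl", "ls_dl", "strip_dl", "lsdl_trace", "strip_trace")


@dataclass(frozen=True)
class CacheParams:
    lines: int  # l: number of cache lines
    line_words: int  # w: words per line

    def __post_init__(self):
        if self.lines < 1 or self.line_words < 1:
            raise ValueError("cache must have at least one line of one word")

    @property
    def capacity(self) -> int:
        return self.lines * self.line_words


def predict_misses(
    algorithm: str,
    m: int,
    n: int,
    params: CacheParams,
    s: int | None = None,
    q: int | None = None,
) -> float:
    """Approximate cache-miss count for one algorithm on an m x n instance."""
    w = params.line_words
    if algorithm in ("dl", "ls_dl"):
        return m * n * (1 + 3 / w)
    if algorithm == "lsdl_trace":
        return 2 * m * n * (1 + 3 / w)
    if algorithm in ("strip_dl", "strip_trace"):
        if s is None or q is None:
            raise ValueError("strip predictions need the alphabet size s and q")
        if q * (s + 1) >= params.capacity:
            warnings.warn(
                f"q={q} violates q < lw/(s+1) = {params.capacity / (s + 1):.1f}; "
                "the strip buffers will not stay cache-resident and the "
                "prediction is unreliable",
                stacklevel=2,
            )
        base = 2 * (s + 1) * m * n / (w * q)
        return base if algorithm == "strip_dl" else 2 * base
    raise ValueError(f"unknown algorithm {algorithm!r}; one of {ALGORITHMS}")


def miss_ratio(s: int, w: int, q: int) -> float:
    """Predicted DL (or LS_DL) misses divided by Strip_DL misses."""
    return (w * q + 3 * q) / (2 * s + 2)
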