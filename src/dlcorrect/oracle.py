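"""Brute-force DL distance by breadth-first search over edit sequences.

Ground truth for tiny instances: explore every string reachable from ``a``
by substitutions, insertions, deletions and adjacent transpositions, level by
level, and report the first depth at which ``b`` appears.  The insertion and
substitution alphabet is the union alphabet of the two inputs — introducing a
foreign symbol can never shorten an edit sequence, because that symbol must
later be substituted away or deleted, and dropping both operations (or
replacing them by the direct edit) gives a no-longer sequence over the union
alphabet.

Intended for |a|, |b| up to about 6.  Returns None when the bound is hit.
"""

from __future__ import annotations

from typing import Iterator

__all__ = ["bfs_dl_distance", "neighbors"]


def neighbors(s: str, alphabet: str) -> Iterator[str]:
    """All strings one unit edit away from ``s`` (may repeat)."""
    L = len(s)
    for i in range(L):  # substitutions
        for c in alphabet:
            if c != s[i]:
                yield s[:i] + c + s[i + 1 :]
    for i in range(L + 1):  # insertions
        for c in alphabet:
            yield s[:i] + c + s[i:]
    for i in range(L):  # deletions
        yield s[:i] + s[i + 1 :]
    for i in range(L - 1):  # adjacent transpositions
        if s[i] != s[i + 1]:
            yield s[: i] + s[i + 1] + s[i] + s[i + 2 :]


def bfs_dl_distance(
    a: str,
    b: str,
    max_depth: int | None = None,
    *,
    prune: bool = True,
) -> int | None:
    """Exact DL distance by level-order search, or None past ``max_depth``.

    ``prune=False`` disables the visited-set (kept only to demonstrate that
    deduplication does not change the result); a length-feasibility cut —
    strings that cannot reach ``len(b)`` within the remaining depth are
    dropped — is always applied since each edit changes length by at most 1.
    """
    if max_depth is None:
        max_depth = max(len(a), len(b))
    if a == b:
        return 0
    alphabet = "".join(dict.fromkeys(a + b))
    frontier = [a]
    visited = {a}
    for depth in range(1, max_depth + 1):
        remaining = max_depth - depth
        nxt = []
        for s in frontier:
            for t in neighbors(s, alphabet):
                if t == b:
                    return depth
                if abs(len(t) - len(b)) > remaining:
                    continue
                if prune:
                    if t in visited:
                        continue
                    visited.add(t)
                nxt.append(t)
        frontier = nxt
        if not frontier:
            break
    return None
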