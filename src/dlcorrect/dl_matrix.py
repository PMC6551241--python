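"""Classical full-matrix Damerau-Levenshtein dynamic program with traceback.

The (m+1) x (n+1) table H holds the DL distance between every prefix pair:
H[i][0] = i, H[0][j] = j, and for i, j > 0

    H[i][j] = min( H[i-1][j-1] + c(a_i, b_j),          # substitute / match
                   H[i][j-1]   + 1,                     # insert b_j
                   H[i-1][j]   + 1,                     # delete a_i
                   H[k-1][l-1] + (i-k-1) + 1 + (j-l-1) )  # transposition block

where c(a_i, b_j) = 0 iff a_i == b_j, k is the rightmost occurrence of b_j in
A before row i, and l the rightmost occurrence of a_i in B before column j.
The fourth case encodes a crossing pair of balanced lines (k, j), (i, l):
delete the characters of A strictly between k and i, transpose the two now
adjacent, and insert the characters of B strictly between l and j.  It is
skipped when k or l do not exist and also when a_i == b_j (a crossing pair
with equal endpoint characters can always be uncrossed at no extra cost, so
this cannot change the minimum).

This is the unrestricted DL distance: edited substrings may be re-edited,
so e.g. d(CA, ABC) = 2 (transpose, then insert), not the restricted/optimal
string alignment value 3.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

from .seqcore import EncodedSequence
from .trace_model import Line, Trace

__all__ = [
    "DPMatrix",
    "MemoryCapError",
    "dl_distance_full",
    "dl_traceback",
    "levenshtein_distance",
    "DEFAULT_CELL_CAP",
]

#: Refuse to allocate full matrices beyond this many cells (configurable per
#: call).  Mirrors the behaviour of the quadratic-space algorithm simply not
#: being runnable on large instances, but with a clear error.
DEFAULT_CELL_CAP = 64_000_000


class MemoryCapError(MemoryError):
    def __init__(self, m: int, n: int, cap: int):
        super().__init__(
            f"full DP matrix would need ({m}+1)x({n}+1) = {(m + 1) * (n + 1)} "
            f"cells, above the cap of {cap}; use the linear-space scorers "
            "or raise max_cells"
        )


@dataclass
class DPMatrix:
    """The filled prefix-distance table H with its dimensions."""

    H: list[list[int]]
    m: int
    n: int

    def __getitem__(self, ij: tuple[int, int]) -> int:
        i, j = ij
        return self.H[i][j]

    @property
    def distance(self) -> int:
        return self.H[self.m][self.n]

    def to_array(self):
        import numpy as np

        return np.array(self.H, dtype=int)

    def to_tsv(self) -> str:
        """Debug dump of H for small instances."""
        return "\n".join("\t".join(str(x) for x in row) for row in self.H)


def dl_distance_full(
    a: EncodedSequence,
    b: EncodedSequence,
    max_cells: int = DEFAULT_CELL_CAP,
) -> tuple[int, DPMatrix]:
    """DL distance and the full prefix-distance matrix."""
    if a.alphabet is not b.alphabet and a.alphabet != b.alphabet:
        raise ValueError("sequences must share an alphabet")
    m, n = len(a), len(b)
    if (m + 1) * (n + 1) > max_cells:
        raise MemoryCapError(m, n, max_cells)
    ca, cb = a.codes, b.codes
    H = [[0] * (n + 1) for _ in range(m + 1)]
    H[0] = list(range(n + 1))
    for i in range(1, m + 1):
        H[i][0] = i
    last_row: dict[int, int] = {}  # code -> most recent row of A with that code
    for i in range(1, m + 1):
        ai = ca[i - 1]
        last_col = 0  # most recent column j' < j with b_{j'} == a_i
        Hi, Hup = H[i], H[i - 1]
        for j in range(1, n + 1):
            bj = cb[j - 1]
            if ai == bj:
                d = Hup[j - 1]
                e = Hi[j - 1] + 1
                if e < d:
                    d = e
                e = Hup[j] + 1
                if e < d:
                    d = e
            else:
                d = Hup[j - 1] + 1
                e = Hi[j - 1] + 1
                if e < d:
                    d = e
                e = Hup[j] + 1
                if e < d:
                    d = e
                k = last_row.get(bj, 0)
                if k and last_col:
                    e = H[k - 1][last_col - 1] + (i - k - 1) + 1 + (j - last_col - 1)
                    if e < d:
                        d = e
            Hi[j] = d
            if bj == ai:
                last_col = j
        last_row[ai] = i
    return H[m][n], DPMatrix(H, m, n)


def _occurrences(codes: tuple[int, ...]) -> dict[int, list[int]]:
    occ: dict[int, list[int]] = {}
    for pos, c in enumerate(codes, start=1):
        occ.setdefault(c, []).append(pos)
    return occ


def _last_before(occ: dict[int, list[int]], code: int, limit: int) -> int:
    """Rightmost occurrence position < limit, or 0."""
    lst = occ.get(code)
    if not lst:
        return 0
    idx = bisect_left(lst, limit)
    return lst[idx - 1] if idx else 0


def dl_traceback(H: DPMatrix, a: EncodedSequence, b: EncodedSequence) -> Trace:
    """An optimal trace recovered from a filled matrix in O(m+n) steps.

    Tie-break when several recurrence cases attain the minimum: the
    substitute/match case first, then the transposition block, then delete,
    then insert — any consistent order yields an optimal trace; this one is
    fixed for reproducibility.
    """
    m, n = len(a), len(b)
    if H.m != m or H.n != n:
        raise ValueError("matrix dimensions do not match the sequences")
    ca, cb = a.codes, b.codes
    occ_a, occ_b = _occurrences(ca), _occurrences(cb)
    lines: list[Line] = []
    i, j = m, n
    grid = H.H
    while i > 0 and j > 0:
        h = grid[i][j]
        ai, bj = ca[i - 1], cb[j - 1]
        cost = 0 if ai == bj else 1
        if h == grid[i - 1][j - 1] + cost:
            lines.append(Line(i, j))
            i, j = i - 1, j - 1
            continue
        if ai != bj:
            k = _last_before(occ_a, bj, i)
            l = _last_before(occ_b, ai, j)
            if k and l and h == grid[k - 1][l - 1] + (i - k - 1) + 1 + (j - l - 1):
                lines.append(Line(k, j))
                lines.append(Line(i, l))
                i, j = k - 1, l - 1
                continue
        if h == grid[i - 1][j] + 1:  # delete a_i
            i -= 1
            continue
        if h == grid[i][j - 1] + 1:  # insert b_j
            j -= 1
            continue
        raise ValueError("matrix inconsistent with the sequences")
    return Trace.make(lines, m, n)


def levenshtein_distance(a: EncodedSequence, b: EncodedSequence) -> int:
    """Plain 3-case (substitute/insert/delete) edit distance, two rows."""
    ca, cb = a.codes, b.codes
    if len(ca) < len(cb):
        ca, cb = cb, ca
    prev = list(range(len(cb) + 1))
    for i, x in enumerate(ca, start=1):
        cur = [i] + [0] * len(cb)
        for j, y in enumerate(cb, start=1):
            cur[j] = min(
                prev[j - 1] + (x != y),
                cur[j - 1] + 1,
                prev[j] + 1,
            )
        prev = cur
    return prev[-1]
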