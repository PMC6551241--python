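"""Linear-space and cache-efficient strip scorers for the DL distance.

Both scorers produce exactly the values of the full-matrix recurrence while
never materialising the (m+1) x (n+1) table.

``ls_dl_score`` keeps a one-dimensional row buffer ``U`` plus one buffer per
alphabet character: after processing row i, ``T[c]`` holds row w-1 of H where
w is the most recent row whose A-character is c.  That is precisely the row
the transposition case needs (H[k-1][l-1] with k the rightmost occurrence of
b_j in A before i), and the buffers are exchanged by constant-time handle
swaps, never copied.  Peak auxiliary storage is (s+1) buffers of n+1 ints.

``strip_dl_score`` computes H in vertical strips of q columns, running the
same row recurrence with width-q buffers.  Values crossing a strip boundary
travel through two carry arrays indexed by row: ``strip[i]`` = H[i][j0] at
the rightmost completed column j0, and ``V[c][i]`` = H[i][l-1] where l is the
rightmost completed column with B[l] = c — the exact operand of the
transposition case when its l falls left of the current strip.  Choosing q
small enough that the width-q buffers stay cache-resident (q < lw/(s+1) for
a cache of l lines of w words) makes the strip scorer's miss count
essentially independent of n per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqcore import EncodedSequence

__all__ = [
    "RowState",
    "StripState",
    "ls_dl_score",
    "strip_dl_score",
    "choose_strip_width",
    "DEFAULT_STRIP_WIDTH",
]

#: Strip width used when nothing is known about the cache.
DEFAULT_STRIP_WIDTH = 256


@dataclass
class RowState:
    """Final buffers of a linear-space run.

    U[j] = H[m][j]; T[c][j] = H[w-1][j] for w = last row of A with code c
    (codes absent from A are invalid / missing from T); last_row maps each
    code to that w.  ``allocated_ints`` is the peak count of buffer integers,
    for the space contract: at most (s+1)(n+1).
    """

    U: list[int]
    T: dict[int, list[int]]
    last_row: dict[int, int]
    width: int  # n of the (possibly swapped) run
    swapped: bool
    allocated_ints: int

    def valid(self, code: int) -> bool:
        return code in self.T


@dataclass
class StripState:
    """Carry arrays after a strip run over all of B.

    strip[i] = H[i][j1] at the rightmost computed column j1 (= n after a full
    run); V[c][i] = H[i][l-1] for l = rightmost column <= j1 with B[l] = c
    (absent codes are invalid); lastocc[c] = that l.
    """

    q: int
    strip: list[int]
    V: dict[int, list[int]]
    lastocc: dict[int, int]
    m: int
    n: int
    swapped: bool
    allocated_ints: int  # peak carry + buffer integers across strips

    def valid(self, code: int) -> bool:
        return code in self.V


def ls_dl_score(
    a: EncodedSequence, b: EncodedSequence, *, swap_to_min: bool = True
) -> tuple[int, RowState]:
    """DL distance with O((s+1) min(m,n)) auxiliary integers.

    With ``swap_to_min`` (default) the operands are exchanged when B is the
    longer string so the buffers follow the shorter dimension; the distance
    is unchanged by symmetry.
    """
    swapped = False
    if swap_to_min and len(b) > len(a):
        a, b = b, a
        swapped = True
    m, n = len(a), len(b)
    ca, cb = a.codes, b.codes
    U = list(range(n + 1))  # row 0
    T: dict[int, list[int]] = {}
    last_row: dict[int, int] = {}
    allocated = n + 1
    for i in range(1, m + 1):
        ai = ca[i - 1]
        buf = T.get(ai)
        if buf is None:
            buf = [0] * (n + 1)
            allocated += n + 1
        T[ai] = U  # row i-1: the swap is a handle exchange
        U = buf
        prev = T[ai]
        U[0] = i
        last_col = 0
        for j in range(1, n + 1):
            bj = cb[j - 1]
            if ai == bj:
                val = prev[j - 1]
                e = U[j - 1] + 1
                if e < val:
                    val = e
                e = prev[j] + 1
                if e < val:
                    val = e
            else:
                val = prev[j - 1] + 1
                e = U[j - 1] + 1
                if e < val:
                    val = e
                e = prev[j] + 1
                if e < val:
                    val = e
                k = last_row.get(bj, 0)
                if k and last_col:
                    e = T[bj][last_col - 1] + (i - k - 1) + 1 + (j - last_col - 1)
                    if e < val:
                        val = e
            U[j] = val
            if bj == ai:
                last_col = j
        last_row[ai] = i
    state = RowState(U, T, last_row, n, swapped, allocated)
    return U[n], state


def strip_dl_score(
    a: EncodedSequence,
    b: EncodedSequence,
    q: int = DEFAULT_STRIP_WIDTH,
    *,
    swap_to_min: bool = True,
) -> tuple[int, StripState]:
    """DL distance computed in strips of q columns; equals the full DP for
    every q >= 1.

    With ``swap_to_min`` the operands are exchanged when A is the longer
    string, so the row-indexed carry arrays follow min(m, n).  The last strip
    may be narrower than q.
    """
    if q < 1:
        raise ValueError("strip width q must be >= 1")
    swapped = False
    if swap_to_min and len(a) > len(b):
        a, b = b, a
        swapped = True
    m, n = len(a), len(b)
    ca, cb = a.codes, b.codes
    strip_arr = list(range(m + 1))  # H[i][0]
    V: dict[int, list[int]] = {}
    lastocc: dict[int, int] = {}
    peak = m + 1
    j0 = 0
    while j0 < n:
        j1 = min(j0 + q, n)
        qt = j1 - j0
        U = list(range(j0, j1 + 1))  # row 0 of this strip: H[0][j] = j
        T: dict[int, list[int]] = {}
        last_row: dict[int, int] = {}
        # Values bound for the next strip are staged per character and
        # committed by handle swap when the strip completes: an in-place
        # overwrite of V would clobber previous-strip values that later rows
        # of this strip still read when a character recurs inside the strip.
        V_stage: dict[int, list[int]] = {}
        stage_occ: dict[int, int] = {}
        for d in range(1, qt + 1):
            c = cb[j0 + d - 1]
            row0 = V_stage.get(c)
            if row0 is None:
                row0 = [0] * (m + 1)
                V_stage[c] = row0
            row0[0] = j0 + d - 1  # H[0][j-1] = j-1
            stage_occ[c] = j0 + d
        for i in range(1, m + 1):
            ai = ca[i - 1]
            buf = T.get(ai)
            if buf is None:
                buf = [0] * (qt + 1)
            T[ai] = U
            U = buf
            prev = T[ai]  # row i-1, columns j0..j1
            U[0] = strip_arr[i]  # H[i][j0] from the previous strip
            last_col = 0  # in-strip occurrence of a_i left of current column
            for d in range(1, qt + 1):
                j = j0 + d
                bj = cb[j - 1]
                if ai == bj:
                    val = prev[d - 1]
                    e = U[d - 1] + 1
                    if e < val:
                        val = e
                    e = prev[d] + 1
                    if e < val:
                        val = e
                else:
                    val = prev[d - 1] + 1
                    e = U[d - 1] + 1
                    if e < val:
                        val = e
                    e = prev[d] + 1
                    if e < val:
                        val = e
                    k = last_row.get(bj, 0)
                    if k:
                        if last_col:
                            # l inside this strip: row k-1 buffer has H[k-1][l-1]
                            l = last_col
                            e = (
                                T[bj][l - j0 - 1]
                                + (i - k - 1) + 1 + (j - l - 1)
                            )
                            if e < val:
                                val = e
                        else:
                            l = lastocc.get(ai, 0)
                            if l:  # l in a completed strip: carry array
                                e = V[ai][k - 1] + (i - k - 1) + 1 + (j - l - 1)
                                if e < val:
                                    val = e
                U[d] = val
                if bj == ai:
                    last_col = j
                V_stage[bj][i] = U[d - 1]  # H[i][j-1]; rightmost occurrence wins
            last_row[ai] = i
            strip_arr[i] = U[qt]
        strip_arr[0] = j1
        used = (
            (m + 1)
            + (len(V) + len(V_stage)) * (m + 1)
            + (len(T) + 1) * (qt + 1)
        )
        peak = max(peak, used)
        for c, staged in V_stage.items():
            V[c] = staged
            lastocc[c] = stage_occ[c]
        j0 = j1
    state = StripState(q, strip_arr, V, lastocc, m, n, swapped, peak)
    return strip_arr[m], state


def choose_strip_width(
    s: int,
    cache_lines: int | None = None,
    line_words: int | None = None,
) -> int:
    """Strip width from the cache bound q < lw/(s+1), clamped to >= 1.

    The width-q buffers comprise s+1 rows of q integers, so a cache of l
    lines of w words keeps them resident when q < lw/(s+1).  A slack of four
    cache lines is reserved for the portions of A, B and the carry arrays
    touched alongside.  Without cache information a fixed default of
    DEFAULT_STRIP_WIDTH is returned.
    """
    if cache_lines is None or line_words is None:
        return DEFAULT_STRIP_WIDTH
    if cache_lines < 1 or line_words < 1 or s < 1:
        raise ValueError("cache parameters and alphabet size must be >= 1")
    bound = (cache_lines * line_words) // (s + 1)
    return max(1, bound - 4 * line_words)
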