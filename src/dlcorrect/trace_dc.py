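"""Linear-space optimal-trace reconstruction by divide and conquer.

The optimal trace is rebuilt Hirschberg-style around the midpoint column
``mid = n // 2`` of B.  An optimal trace either

* has no *center crossing* — then it splits at some row i into an optimal
  trace of (A[1..i], B[1..mid]) and one of (A[i+1..m], B[mid+1..n]), at cost

      costNoCC = min_i { H[i] + H'[i+1] }

  where H[i] is the prefix cost against the left half and H'[i+1] the suffix
  cost against the right half; or

* has a center crossing: a pair of balanced crossing lines (u1, v1), (u2, v2)
  with v2 <= mid < v1 and A[u1] != A[u2].  Then

      costCC = min { H[u1-1][v2-1] + H'[u2+1][v1+1]
                     + (u2-u1-1) + 1 + (v1-v2-1) }

  enumerated over u1 (v1 = leftmost occurrence of A[u1] right of mid) and
  every other character c (v2 = rightmost occurrence of c at or left of mid,
  u2 = leftmost occurrence of c in A after u1) — (s-1)m candidates.

The H/H' values come from the final buffers of a linear-space scorer run on
each half: the ``ls`` engine reads the U/T row buffers of runs with operands
(B-half, A); the ``strip`` engine reads the strip/V carry arrays of runs with
operands (A, B-half).  Both extractions yield bit-identical arrays.  The
winning split recurses on the two sub-rectangles; crossing splits emit their
two lines directly.  Total cells computed over all levels stay below
2mn + O(m+n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .dl_matrix import dl_distance_full, dl_traceback
from .linear_scorers import DEFAULT_STRIP_WIDTH, ls_dl_score, strip_dl_score
from .seqcore import EncodedSequence
from .trace_model import Line, Trace

__all__ = [
    "BoundaryArrays",
    "SplitCandidate",
    "boundary_arrays",
    "best_split",
    "dc_trace",
]

Engine = Literal["ls", "strip"]

#: Subproblems at or below this cell count are handed to the full-matrix DP.
BASE_CASE_CELLS = 4096


@dataclass
class BoundaryArrays:
    """Prefix/suffix optimal costs around the split column ``mid``.

    U_top[i]    = d(A[1..i],   B[1..mid])              for 0 <= i <= m
    T_top[c][i] = d(A[1..i],   B[1..v2-1]),  v2 = rightmost occ. of c <= mid
    U_bot[i]    = d(A[i..m],   B[mid+1..n])            for 1 <= i <= m+1
    T_bot[c][i] = d(A[u..m]->A[i..m], B[v1+1..n]), v1 = leftmost occ. of c > mid

    U_bot/T_bot are stored in lists of length m+2 indexed directly by i;
    index 0 of U_bot is unused.  Characters with no occurrence in the
    respective half are absent from T_top/T_bot.
    """

    mid: int
    m: int
    U_top: list[int]
    T_top: dict[int, list[int]]
    U_bot: list[int]
    T_bot: dict[int, list[int]]


@dataclass(frozen=True)
class SplitCandidate:
    kind: Literal["no-crossing", "crossing"]
    cost: int
    i_star: int | None = None  # no-crossing: split row
    u1: int | None = None  # crossing line endpoints, 1-based in (a, b)
    v1: int | None = None
    u2: int | None = None
    v2: int | None = None


def _cells(m: int, n: int) -> int:
    return m * n


def boundary_arrays(
    a: EncodedSequence,
    b: EncodedSequence,
    mid: int,
    engine: Engine = "ls",
    q: int = DEFAULT_STRIP_WIDTH,
    stats: dict | None = None,
) -> BoundaryArrays:
    """Boundary cost arrays at split column ``mid``, from either engine."""
    if not (0 <= mid <= len(b)):
        raise ValueError("mid must be within 0..n")
    m = len(a)
    b_left = b.slice(1, mid)
    b_right_rev = b.slice(mid + 1, len(b)).reverse()
    a_rev = a.reverse()
    if engine == "ls":
        # Rows = B-half, columns = A: the final U row is d(half, A[1..i]).
        _, top = ls_dl_score(b_left, a, swap_to_min=False)
        _, bot = ls_dl_score(b_right_rev, a_rev, swap_to_min=False)
        u_top, t_top = top.U, top.T
        u_bot_rev, t_bot_rev = bot.U, bot.T
    elif engine == "strip":
        # Rows = A, columns = B-half: the strip/V carry arrays are indexed
        # by rows of A and already hold the same values.
        _, top = strip_dl_score(a, b_left, q, swap_to_min=False)
        _, bot = strip_dl_score(a_rev, b_right_rev, q, swap_to_min=False)
        u_top, t_top = top.strip, top.V
        u_bot_rev, t_bot_rev = bot.strip, bot.V
    else:
        raise ValueError(f"unknown engine {engine!r}")
    if stats is not None:
        stats["cells"] = stats.get("cells", 0) + m * mid + m * (len(b) - mid)

    # Reverse-run arrays are indexed by suffix length t = m+1-i.
    U_bot = [0] * (m + 2)
    for i in range(1, m + 2):
        U_bot[i] = u_bot_rev[m + 1 - i]
    T_bot = {}
    for c, arr in t_bot_rev.items():
        rev = [0] * (m + 2)
        for i in range(1, m + 2):
            rev[i] = arr[m + 1 - i]
        T_bot[c] = rev
    return BoundaryArrays(mid, m, list(u_top), dict(t_top), U_bot, T_bot)


def _occurrence_tables(codes: tuple[int, ...], mid: int):
    """(rightmost occ. <= mid, leftmost occ. > mid) per code of B."""
    last_left: dict[int, int] = {}
    for j in range(1, mid + 1):
        last_left[codes[j - 1]] = j
    first_right: dict[int, int] = {}
    for j in range(len(codes), mid, -1):
        first_right[codes[j - 1]] = j
    return last_left, first_right


def best_split(
    arrays: BoundaryArrays,
    a: EncodedSequence,
    b: EncodedSequence,
    mid: int,
) -> SplitCandidate:
    """Minimum-cost split: all no-crossing rows and all crossing candidates.

    Ties prefer the no-crossing kind, and among no-crossing splits the
    smallest row.  Every candidate's cost is an achievable trace cost, and
    one candidate always attains the true distance.
    """
    m = len(a)
    ca, cb = a.codes, b.codes
    best_cost = None
    best_i = None
    for i in range(0, m + 1):
        c = arrays.U_top[i] + arrays.U_bot[i + 1]
        if best_cost is None or c < best_cost:
            best_cost, best_i = c, i
    best = SplitCandidate("no-crossing", best_cost, i_star=best_i)

    last_left, first_right = _occurrence_tables(cb, mid)
    # u2 = leftmost occurrence of c in A after u1, maintained while u1
    # sweeps downward.
    next_in_a: dict[int, int] = {}
    if m >= 1:
        cand_chars = [c for c in last_left if c in arrays.T_top]
    for u1 in range(m - 1, 0, -1):
        next_in_a[ca[u1]] = u1 + 1  # position u1+1 enters the suffix
        c1 = ca[u1 - 1]  # A[u1]
        v1 = first_right.get(c1)
        if v1 is None or c1 not in arrays.T_bot:
            continue
        t_bot_c1 = arrays.T_bot[c1]
        for c in cand_chars:
            if c == c1:
                continue
            u2 = next_in_a.get(c)
            if u2 is None:
                continue
            v2 = last_left[c]
            cost = (
                arrays.T_top[c][u1 - 1]
                + t_bot_c1[u2 + 1]
                + (u2 - u1 - 1) + 1 + (v1 - v2 - 1)
            )
            if cost < best.cost:
                best = SplitCandidate(
                    "crossing", cost, u1=u1, v1=v1, u2=u2, v2=v2
                )
    return best


def _full_matrix_trace(
    a: EncodedSequence, b: EncodedSequence, stats: dict | None
) -> Trace:
    if stats is not None:
        stats["cells"] = stats.get("cells", 0) + (len(a) + 1) * (len(b) + 1)
        stats["base_cases"] = stats.get("base_cases", 0) + 1
    _, H = dl_distance_full(a, b)
    return dl_traceback(H, a, b)


def _dc(
    a: EncodedSequence,
    b: EncodedSequence,
    engine: Engine,
    q: int,
    stats: dict | None,
) -> Trace:
    m, n = len(a), len(b)
    if min(m, n) <= 1 or (m + 1) * (n + 1) <= BASE_CASE_CELLS:
        return _full_matrix_trace(a, b, stats)
    if m < n:
        # Split the shorter string: swap and transpose the reported lines.
        t = _dc(b, a, engine, q, stats)
        return Trace.make([(v, u) for (u, v) in t.lines], m, n)
    mid = n // 2
    arrays = boundary_arrays(a, b, mid, engine, q, stats)
    cand = best_split(arrays, a, b, mid)
    lines: list[tuple[int, int]] = []
    if cand.kind == "no-crossing":
        i_star = cand.i_star
        left = _dc(a.slice(1, i_star), b.slice(1, mid), engine, q, stats)
        right = _dc(
            a.slice(i_star + 1, m), b.slice(mid + 1, n), engine, q, stats
        )
        lines += [(u, v) for (u, v) in left.lines]
        lines += [(u + i_star, v + mid) for (u, v) in right.lines]
    else:
        u1, v1, u2, v2 = cand.u1, cand.v1, cand.u2, cand.v2
        lines += [(u1, v1), (u2, v2)]
        left = _dc(a.slice(1, u1 - 1), b.slice(1, v2 - 1), engine, q, stats)
        right = _dc(a.slice(u2 + 1, m), b.slice(v1 + 1, n), engine, q, stats)
        lines += [(u, v) for (u, v) in left.lines]
        lines += [(u + u2, v + v1) for (u, v) in right.lines]
    return Trace.make(lines, m, n)


def dc_trace(
    a: EncodedSequence,
    b: EncodedSequence,
    engine: Engine = "ls",
    q: int = DEFAULT_STRIP_WIDTH,
    stats: dict | None = None,
) -> Trace:
    """Optimal trace in linear space; cost always equals the DL distance.

    ``stats`` (optional dict) accumulates ``cells`` — DP cells computed over
    all recursion levels — and ``base_cases``.
    """
    if engine not in ("ls", "strip"):
        raise ValueError(f"unknown engine {engine!r}")
    return _dc(a, b, engine, q, stats)
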