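"""Traces, their cost, validity properties, and executable edit scripts.

A *trace* between strings ``A`` (length m) and ``B`` (length n) is a set of
lines ``(u, v)`` pairing a position of A with a position of B, no two lines
sharing a u or sharing a v.  A line is *balanced* when ``A[u] == B[v]``; two
lines ``(u1, v1)``, ``(u2, v2)`` *cross* when ``u1 < u2`` and ``v1 > v2``.

The cost of a trace is

    (# unbalanced lines) + (# A positions untouched by any line)
    + (# B positions untouched) + (# crossing pairs)

which equals the length of the edit sequence the trace encodes: an unbalanced
line is a substitution, untouched A positions are deletions, untouched B
positions are insertions, and each crossing pair of balanced lines is a block
of deletions, one adjacent transposition, and insertions.  The minimum trace
cost over all traces is the Damerau-Levenshtein distance.

Validity levels:

* hard axioms — endpoints in range, u's distinct, v's distinct;
* P3 — every line crosses at most one other, and crossing lines are balanced
  (some optimal trace always satisfies this);
* P4 — for each crossing pair, u1 is the rightmost occurrence of B[v1] in A
  before u2 and v2 the rightmost occurrence of A[u2] in B before v1.

Arbitrary user traces may legitimately violate P3/P4 while still being valid
traces, so :func:`validate_trace` reports them separately from the axioms.
Edit-script conversion requires P3 (crossing pairs must be contiguous blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .seqcore import EncodedSequence

__all__ = [
    "Line",
    "Trace",
    "EditOp",
    "EditScript",
    "TraceReport",
    "trace_cost",
    "validate_trace",
    "trace_to_edits",
    "apply_edits",
]


class Line(NamedTuple):
    u: int  # 1-based position in A
    v: int  # 1-based position in B


@dataclass(frozen=True)
class Trace:
    lines: tuple[Line, ...]
    m: int
    n: int

    @classmethod
    def make(cls, lines: Iterable[tuple[int, int]], m: int, n: int) -> "Trace":
        return cls(tuple(sorted(Line(u, v) for (u, v) in lines)), m, n)

    def __len__(self) -> int:
        return len(self.lines)


class EditOp(NamedTuple):
    """One unit edit; ``pos`` is 1-based on the working string at apply time.

    op is one of "substitute" (char replaces position pos), "insert" (char
    inserted so it lands at position pos), "delete" (remove position pos),
    "transpose" (swap positions pos and pos+1; char is None).
    """

    op: str
    pos: int
    char: str | None = None


@dataclass(frozen=True)
class EditScript:
    ops: tuple[EditOp, ...]

    def __len__(self) -> int:
        return len(self.ops)

    def __iter__(self):
        return iter(self.ops)


@dataclass
class TraceReport:
    ok: bool  # hard axioms
    p3_ok: bool | None = None  # None when strict checks were not requested
    p4_ok: bool | None = None
    violations: list[str] = field(default_factory=list)

    @property
    def strict_ok(self) -> bool:
        return self.ok and bool(self.p3_ok) and bool(self.p4_ok)


def _check_axioms(t: Trace) -> list[str]:
    bad = []
    us, vs = set(), set()
    for u, v in t.lines:
        if not (1 <= u <= t.m):
            bad.append(f"line ({u},{v}): u out of range 1..{t.m}")
        if not (1 <= v <= t.n):
            bad.append(f"line ({u},{v}): v out of range 1..{t.n}")
        if u in us:
            bad.append(f"duplicate u={u}")
        if v in vs:
            bad.append(f"duplicate v={v}")
        us.add(u)
        vs.add(v)
    return bad


def _crossing_pairs(lines: tuple[Line, ...]) -> list[tuple[Line, Line]]:
    """All pairs (L1, L2) with u1 < u2 and v1 > v2, by quadratic scan."""
    srt = sorted(lines)
    out = []
    for i, l1 in enumerate(srt):
        for l2 in srt[i + 1 :]:
            if l1.v > l2.v:
                out.append((l1, l2))
    return out


def trace_cost(t: Trace, a: EncodedSequence, b: EncodedSequence) -> int:
    """Trace cost: unbalanced + untouched in A + untouched in B + crossings."""
    if len(a) != t.m or len(b) != t.n:
        raise ValueError("trace dimensions do not match the sequences")
    bad = _check_axioms(t)
    if bad:
        raise ValueError("invalid trace: " + "; ".join(bad))
    unbalanced = sum(1 for u, v in t.lines if a.codes[u - 1] != b.codes[v - 1])
    untouched_a = t.m - len(t.lines)
    untouched_b = t.n - len(t.lines)
    crossings = len(_crossing_pairs(t.lines))
    return unbalanced + untouched_a + untouched_b + crossings


def cost_breakdown(
    t: Trace, a: EncodedSequence, b: EncodedSequence
) -> dict[str, int]:
    """The four cost components, by the same rules as :func:`trace_cost`."""
    return {
        "unbalanced": sum(1 for u, v in t.lines if a.codes[u - 1] != b.codes[v - 1]),
        "untouched_a": t.m - len(t.lines),
        "untouched_b": t.n - len(t.lines),
        "crossings": len(_crossing_pairs(t.lines)),
    }


def validate_trace(
    t: Trace, a: EncodedSequence, b: EncodedSequence, strict: bool = False
) -> TraceReport:
    """Check trace axioms, and P3/P4 in strict mode; never raises."""
    violations = _check_axioms(t)
    if len(a) != t.m or len(b) != t.n:
        violations.append("trace dimensions do not match the sequences")
    report = TraceReport(ok=not violations, violations=violations)
    if not strict or not report.ok:
        return report

    pairs = _crossing_pairs(t.lines)
    per_line: dict[Line, int] = {}
    p3_bad: list[str] = []
    for l1, l2 in pairs:
        for ln in (l1, l2):
            per_line[ln] = per_line.get(ln, 0) + 1
            if a.codes[ln.u - 1] != b.codes[ln.v - 1]:
                p3_bad.append(f"crossing line {tuple(ln)} is unbalanced")
    for ln, k in per_line.items():
        if k > 1:
            p3_bad.append(f"line {tuple(ln)} crosses {k} others")
    report.p3_ok = not p3_bad

    p4_bad: list[str] = []
    for l1, l2 in pairs:
        u1, v1 = l1
        u2, v2 = l2
        # u1 must be the rightmost occurrence of B[v1] in A before u2.
        cu = b.codes[v1 - 1]
        if any(a.codes[i - 1] == cu for i in range(u1 + 1, u2)):
            p4_bad.append(f"pair {tuple(l1)},{tuple(l2)}: u1 not rightmost")
        cv = a.codes[u2 - 1]
        if any(b.codes[j - 1] == cv for j in range(v2 + 1, v1)):
            p4_bad.append(f"pair {tuple(l1)},{tuple(l2)}: v2 not rightmost")
    report.p4_ok = not p4_bad
    report.violations += p3_bad + p4_bad
    return report


def _blocks(t: Trace) -> list[tuple[int, int, int, int, bool]]:
    """Decompose a P3-valid trace into blocks (us, ue, vs, ve, is_crossing).

    Straight lines become singleton blocks; each crossing pair becomes the
    block [u1..u2] x [v2..v1].  P3 guarantees no third line falls inside a
    crossing block in either coordinate, so blocks are consistently ordered
    by both u and v.
    """
    pairs = _crossing_pairs(t.lines)
    in_pair = {ln for p in pairs for ln in p}
    blocks = []
    for l1, l2 in pairs:
        blocks.append((l1.u, l2.u, l2.v, l1.v, True))
    for ln in t.lines:
        if ln not in in_pair:
            blocks.append((ln.u, ln.u, ln.v, ln.v, False))
    blocks.sort()
    return blocks


def trace_to_edits(
    t: Trace, a: EncodedSequence, b: EncodedSequence
) -> EditScript:
    """Convert a trace into an executable edit script of length trace_cost.

    Operations are emitted left-to-right over A.  For a crossing pair
    (u1,v1),(u2,v2): the characters between u1 and u2 are deleted (right to
    left), u1 and u2 (now adjacent) are transposed, then B[v2+1..v1-1] is
    inserted between them.  Positions always refer to the working string at
    the moment the operation is applied.
    """
    report = validate_trace(t, a, b, strict=True)
    if not report.ok or not report.p3_ok:
        raise ValueError("trace_to_edits needs a P3-valid trace: "
                         + "; ".join(report.violations))
    ops: list[EditOp] = []
    out = 0       # characters of B already finalized
    a_ptr = 1     # next unprocessed position of A
    for us, ue, vs, ve, crossing in _blocks(t):
        # Gap before the block: untouched A positions are deletions, untouched
        # B positions insertions.
        for _ in range(a_ptr, us):
            ops.append(EditOp("delete", out + 1))
        a_ptr = us
        for j in range(out + 1, vs):
            ops.append(EditOp("insert", j, b.raw[j - 1]))
        out = vs - 1
        if not crossing:
            if a.codes[us - 1] != b.codes[vs - 1]:
                ops.append(EditOp("substitute", out + 1, b.raw[vs - 1]))
            out += 1
            a_ptr = us + 1
        else:
            u1, u2, v2, v1 = us, ue, vs, ve
            # middles of A, deleted right to left
            for d in range(u2 - u1 - 1, 0, -1):
                ops.append(EditOp("delete", out + 1 + d))
            ops.append(EditOp("transpose", out + 1))
            for j in range(v2 + 1, v1):
                ops.append(EditOp("insert", out + 1 + (j - v2), b.raw[j - 1]))
            out += v1 - v2 + 1
            a_ptr = u2 + 1
    for _ in range(a_ptr, t.m + 1):
        ops.append(EditOp("delete", out + 1))
    for j in range(out + 1, t.n + 1):
        ops.append(EditOp("insert", j, b.raw[j - 1]))
    return EditScript(tuple(ops))


def apply_edits(a: str, script: EditScript) -> str:
    """Apply an edit script to ``a``, operation by operation."""
    s = list(a)
    for op, pos, char in script:
        if op == "substitute":
            if not (1 <= pos <= len(s)):
                raise IndexError(f"substitute position {pos} out of range")
            s[pos - 1] = char
        elif op == "insert":
            if not (1 <= pos <= len(s) + 1):
                raise IndexError(f"insert position {pos} out of range")
            s.insert(pos - 1, char)
        elif op == "delete":
            if not (1 <= pos <= len(s)):
                raise IndexError(f"delete position {pos} out of range")
            del s[pos - 1]
        elif op == "transpose":
            if not (1 <= pos <= len(s) - 1):
                raise IndexError(f"transpose position {pos} out of range")
            s[pos - 1], s[pos] = s[pos], s[pos - 1]
        else:
            raise ValueError(f"unknown edit operation {op!r}")
    return "".join(s)
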