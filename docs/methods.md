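# Methods

## Problem and model

Given strings `A = a_1..a_m` and `B = b_1..b_n` over an alphabet of size
`s`, the Damerau-Levenshtein (DL) distance is the length of a shortest edit
sequence over four unit-cost operations: substitute a character, insert a
character, delete a character, transpose two *adjacent* characters.  We
compute the unrestricted distance — edited substrings may be re-edited — so
`d(CA, ABC) = 2`; this version is a true metric (non-negative, identity,
symmetric, triangle inequality), unlike the restricted variant that forbids
re-editing.

All reasoning goes through *traces*: sets of lines `(u, v)` pairing
positions of A with positions of B, distinct on each side.  A line is
balanced when `a_u = b_v`; lines `(u1,v1)`, `(u2,v2)` cross when `u1 < u2`
and `v1 > v2`.  The cost of a trace is

    (#unbalanced lines) + (#untouched positions of A)
    + (#untouched positions of B) + (#crossing pairs),

and the minimum over traces equals the DL distance.  Some optimal trace has
each line crossing at most one other, all crossing lines balanced, and each
crossing pair in "rightmost occurrence" position (the P3/P4 properties
checked by `validate_trace`).  A crossing pair encodes a transposition
block: delete the A-characters strictly between the pair, transpose the two
now-adjacent characters, insert the B-characters strictly between.

## Algorithms

**Full matrix** (`dl_matrix`).  The classical recurrence over the
`(m+1)x(n+1)` prefix-distance table, four cases: diagonal substitution,
insertion, deletion, and the transposition block
`H[k-1][l-1] + (i-k-1) + 1 + (j-l-1)` with `k = lastA[i][b_j]`,
`l = lastB[j][a_i]`.  The block case is skipped when `k` or `l` is missing
— and also when `a_i = b_j`: a crossing pair with equal endpoint characters
can be uncrossed into two balanced straight lines at no greater cost, so the
skip never changes the minimum (the linear-space scorer additionally relies
on this, because after its buffer swap the row for the current character is
no longer the one the block case would want).  `last_col` bookkeeping is
reset at the start of every row.  Traceback recovers an optimal trace in
O(m+n) steps with a fixed tie-break (substitute > transposition block >
delete > insert); any consistent order is optimal, this one makes outputs
reproducible.  A configurable cell cap (default 64e6) refuses instances
whose full matrix would be unreasonably large, with a clear error rather
than memory exhaustion.

**Linear-space scorer** (`ls_dl_score`).  Buffers: `U` (row being computed)
and `T[c]` for each character `c`, holding row `w-1` of H where `w` is the
last row so far with `A[w] = c` — exactly the row the block case reads.
Before row `i`, `T[A[i]]` and `U` exchange *handles* (O(1), never copied),
after which `T[A[i]]` holds row `i-1` for the 3 classical cases and the
freed buffer receives row `i`.  Peak auxiliary storage is at most
`(s+1)(n+1)` integers; operands are swapped when B is longer so the buffers
follow `min(m, n)` (the distance is symmetric).  The `allocated_ints`
counter on the returned state records the actual allocation for the space
contract tests.

**Strip scorer** (`strip_dl_score`).  The same row recurrence walks
vertical strips of `q` columns (the last strip may be narrower).  Two carry
arrays pass values across strip boundaries: `strip[i] = H[i][j0]` at the
rightmost completed column, and `V[c][i] = H[i][l-1]` for `l` the rightmost
completed column with `B[l] = c` — precisely the operand the block case
needs when its `l` falls left of the current strip (`l` itself is tracked
separately as the rightmost completed occurrence per character, plus an
in-row scan for in-strip occurrences).  Values bound for the next strip are
staged per character and committed by handle swap when the strip completes:
committing in place would clobber previous-strip values that later rows of
the same strip still read whenever a character recurs inside the strip.
Peak storage is bounded by `2(s+1)(m+q+2)` integers; operands are swapped
when A is longer so the row-indexed arrays follow `min(m, n)`.

**Strip width** (`choose_strip_width`).  Under a single-level LRU cache of
`l` lines of `w` words, the width-q buffers stay resident when
`q < lw/(s+1)`; we return `floor(lw/(s+1))` minus four cache lines of slack
(for the touched portions of A, B and the carry arrays), clamped to at
least 1.  With no cache information the default is `q = 256`, a round figure
that keeps `(s+1)q` words comfortably inside typical per-core L2 caches for
s up to 20.

**Cache-miss predictor** (`cache_model`).  Analytic approximations under
the same model, returned as floats: `mn(1+3/w)` for the full and
linear-space scorers (three streamed row accesses per cell plus one
irregular block-case read), `2(s+1)mn/(wq)` for the strip scorer (carry
arrays re-streamed once per strip), twice each for the corresponding trace
algorithms.  The predicted full/strip ratio is identically
`(wq+3q)/(2s+2)`.  A warning is issued when `q` violates the residency
bound.  No hardware measurement is attempted.

**Divide-and-conquer trace** (`trace_dc`).  Hirschberg-style recursion on
`mid = floor(n/2)`.  Boundary arrays give prefix costs `U_top`/`T_top`
against the left half and suffix costs `U_bot`/`T_bot` against the right
half; they are read off the final buffers of a linear-space run per half
(ls engine: operands (B-half, A), the U/T buffers are indexed by A; strip
engine: operands (A, B-half), the strip/V carry arrays are indexed by A and
hold the same values — the two extractions are asserted bit-identical in
tests).  The best split is the cheaper of

* no-crossing: `min over 0 <= i <= m of U_top[i] + U_bot[i+1]` (the range
  includes i = 0 and i = m; every term is an achievable trace cost, so
  widening the range is safe, and the boundary terms cover traces entirely
  in one half);
* center-crossing: for each `u1` take `v1` = leftmost occurrence of
  `A[u1]` after mid, and for each other character `c`: `v2` = rightmost
  occurrence of `c` at or before mid, `u2` = leftmost occurrence of `c` in A
  after `u1`, at cost `T_top[c][u1-1] + T_bot[A[u1]][u2+1] + (u2-u1-1) + 1
  + (v1-v2-1)` — at most `(s-1)m` candidates, enumerated with descending-u1
  next-occurrence tables in O(m + sm).

Ties prefer the no-crossing kind (simpler recursion), then the smallest
split row.  Crossing splits emit their two lines directly and recurse on
the outer rectangles.  Recursion stops when the smaller dimension is <= 1
or the subproblem has at most 4096 cells, where the full-matrix DP plus
traceback takes over — the cap bounds base-case memory at a few dozen KB
while keeping the recursion shallow.  At each level the driver swaps
operands when A is shorter, so the *shorter* string is always the one
split, shortening the recursion; reported lines are transposed back.  Total
cells computed stay below `2mn + O(m+n)` (geometric series over levels; a
counter verifies the bound in tests).  The resulting trace's cost is
asserted equal to the independent full-matrix distance across the test
suite — optimal traces are not unique, so cost equality plus validity plus
edit-script replay is the correctness surface.

**Edit scripts** (`trace_model`).  A P3-valid trace decomposes into blocks
(straight lines and crossing pairs — P3 forces crossing pairs to be
contiguous in both coordinates), ordered consistently by u and v.  The
converter walks blocks left to right, emitting deletions for untouched A
positions, insertions for untouched B positions, substitutions for
unbalanced lines, and for each crossing pair: interior deletions (right to
left), one transposition, interior insertions (left to right) — positions
always refer to the working string at apply time.  The script length equals
the trace cost by construction, and `apply_edits` replays it.

**Oracle** (`oracle`).  Breadth-first search over all four edit operations
from A, level by level, deduplicated by string, insertion/substitution
alphabet restricted to the union alphabet of the pair (a foreign symbol
must later be removed or replaced, so it never shortens a sequence).  A
length-feasibility cut drops strings that cannot reach `|B|` in the
remaining depth.  Exact by construction; usable to lengths around 6.

## Synthetic data

`random_pair(m, n, s, seed)` draws i.i.d. uniform symbols — DNA letters at
s = 4, the 20 amino-acid letters at s = 20, generic symbols otherwise —
with a fixed numpy generator per seed.  This emulates the random
DNA/RNA/protein test sequences the algorithms are aimed at, at desk scale.
It does *not* emulate compositional bias, repeats, homopolymer runs or
local similarity structure of real genomic data; passing tests therefore
demonstrate algorithmic correctness and the space/work contracts on
arbitrary symbol streams, not biological performance claims.  Correctness
is alphabet- and distribution-agnostic (every path is additionally
exercised by exhaustive enumeration at tiny sizes and by hypothesis-driven
string generation), so this limitation affects only runtime
representativeness.

## Problem sizes and test design

The verification suite runs full cross-checks at moderate sizes chosen to
exercise every code path many times while keeping the suite quick: an
exhaustive sweep of all 961 ordered pairs of strings of length <= 4 over a
binary alphabet against the BFS oracle; 200 random pairs of lengths <= 64
over s in {2, 4, 20} for scorer equality across strip widths
q in {1, 2, 3, 7, 16, 63, 64, 200} (boundary, interior and beyond-n
widths); 100 random pairs of lengths <= 100 for trace optimality on both
engines; metric properties on 200 random triples of lengths <= 20.  The
divide-and-conquer recursion is additionally stress-tested with the base
case shrunk to 16 cells so splits (including center crossings) carry the
full load.  Space contracts are asserted both structurally (allocation
counters on the returned states) and by `tracemalloc` measurement at
m = n = 1000.

## Known limitations

* Unit costs only; the weighted substitution/insertion/deletion/
  transposition generalization is out of scope.
* Single-core only; no parallel row-pipelined or strip-pipelined variants.
* The cache-miss predictor is an analytic single-level LRU approximation
  for what-if comparisons, not a measurement, and real multi-level caches
  with prefetching will deviate in absolute counts (the *ranking* of
  algorithms is what the model is for).
* The full-matrix reference refuses very large instances by design; use
  the linear-space scorers and `dc_trace` there, which is the point of the
  package.
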