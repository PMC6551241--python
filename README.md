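# dlcorrect

Space- and cache-efficient string correction under the **Damerau-Levenshtein
(DL) distance** — the minimum number of substitutions, insertions, deletions
and adjacent transpositions that turn one string into another.

The package is aimed at anyone comparing long symbolic sequences — DNA/RNA
(alphabet size s = 4), proteins (s = 20), spelling variants, packet traces —
where the classical quadratic-space dynamic program stops fitting in memory
long before it stops fitting in time.

This is the *unrestricted* DL distance: edited substrings may be edited
again, so `d(CA, ABC) = 2` (transpose `CA → AC`, insert `B`), whereas the
restricted "optimal string alignment" variant would report 3.  The
unrestricted distance is a true metric.

## What is inside

For strings `A` (length m) and `B` (length n) over an alphabet of size s,
with prefix distances `H[i][j] = d(A[1..i], B[1..j])`:

```
H[i][0] = i,  H[0][j] = j
H[i][j] = min( H[i-1][j-1] + c(a_i, b_j),                # substitute/match
               H[i][j-1] + 1,                             # insert
               H[i-1][j] + 1,                             # delete
               H[k-1][l-1] + (i-k-1) + 1 + (j-l-1) )      # transposition block
```

where `k`/`l` are the rightmost occurrences of `b_j` in `A` before `i` and of
`a_i` in `B` before `j`.

* `dl_distance_full` — the O(mn)-space reference dynamic program, with
  `dl_traceback` for an optimal *trace* (a set of lines pairing positions of
  A and B; the diagrammatic form of an edit sequence).
* `ls_dl_score` — the same distance in O((s+1)·min(m,n)) space, keeping one
  row buffer per alphabet character and swapping buffer handles in O(1).
* `strip_dl_score` — a cache-efficient variant that walks the matrix in
  vertical strips of width q, passing boundary values through two
  row-indexed carry arrays; with q below lw/(s+1) for a cache of l lines of
  w words, its working set stays cache-resident.
* `dc_trace` — an optimal trace in linear space by Hirschberg-style divide
  and conquer around B's midpoint, including the *center-crossing* split a
  transposition straddling the midpoint requires; runs on either scorer
  ("ls" or "strip" engine) in under 2mn total cell computations.
* `trace_cost` / `validate_trace` / `trace_to_edits` / `apply_edits` — the
  trace algebra: cost (unbalanced lines + untouched positions + crossings),
  validity properties, and conversion to an executable edit script.
* `bfs_dl_distance` — a brute-force breadth-first oracle for toy instances,
  the package's independent ground truth.
* `predict_misses` — analytic cache-miss counts under a single-level LRU
  cache model (e.g. mn(1+3/w) for the full DP vs 2(s+1)mn/(wq) for strips).

## Worked example

```python
>>> from dlcorrect import encode_pair, dl_distance_full, dc_trace
>>> from dlcorrect import trace_cost, trace_to_edits, apply_edits
>>> a, b, alphabet = encode_pair("CA", "ABC")
>>> dl_distance_full(a, b)[0]
2
>>> t = dc_trace(a, b, engine="strip", q=1)
>>> t.lines
(Line(u=1, v=3), Line(u=2, v=1))
>>> trace_cost(t, a, b)
2
>>> [(op.op, op.pos, op.char) for op in trace_to_edits(t, a, b)]
[('transpose', 1, None), ('insert', 2, 'B')]
>>> apply_edits("CA", trace_to_edits(t, a, b))
'ABC'
```

The two crossing lines pair `C` (position 1 of A) with `C` (position 3 of B)
and `A` with `A` — a transposition — and the untouched `B` of the target is
an insertion: distance 2.

The same from the shell:

```console
$ dlcorrect dist --text CA ABC --algo strip
2
$ dlcorrect trace --text CA ABC --algo stripdc
# cost	2
u	v	balanced
1	3	1
2	1	1
step	op	pos	char
1	TRA	1
2	INS	2	B
$ dlcorrect model --m 1000 --n 1000 --s 4 --q 100
# m=1000 n=1000 s=4 l=512 w=8 q=100
algorithm	predicted_misses
dl	1375000.0
ls_dl	1375000.0
strip_dl	12500.0
lsdl_trace	2750000.0
strip_trace	25000.0
# DL/Strip_DL ratio = (wq+3q)/(2s+2) = 110.000
```

`dlcorrect gen` writes random FASTA pairs and `dlcorrect verify` cross-checks
all algorithms against each other (and the oracle at toy sizes).

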