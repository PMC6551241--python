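import random

import pytest

import dlcorrect.trace_dc as trace_dc_mod
from dlcorrect.dl_matrix import dl_distance_full
from dlcorrect.seqcore import encode_pair, random_pair
from dlcorrect.trace_dc import best_split, boundary_arrays, dc_trace
from dlcorrect.trace_model import (
    apply_edits,
    trace_cost,
    trace_to_edits,
    validate_trace,
)


def brute(a, b, alphabet):
    ea, eb, _ = encode_pair(a, b, alphabet)
    return dl_distance_full(ea, eb)[0]


def test_boundary_arrays_at_mid_zero(enc):
    ea, eb = enc("ACGTA", "GATTA")
    arrays = boundary_arrays(ea, eb, 0)
    assert arrays.U_top == list(range(6))  # cost against an empty left half


def test_boundary_arrays_at_mid_n(enc):
    ea, eb = enc("ACGTA", "GATTA")
    arrays = boundary_arrays(ea, eb, 5)
    assert arrays.U_top[5] == dl_distance_full(ea, eb)[0]


def test_boundary_arrays_match_their_definitions():
    a, b = random_pair(9, 11, 3, seed=5)
    ea, eb, al = encode_pair(a, b)
    mid = 5
    arrays = boundary_arrays(ea, eb, mid)
    for i in range(len(a) + 1):
        assert arrays.U_top[i] == brute(a[:i], b[:mid], al)
    for i in range(1, len(a) + 2):
        assert arrays.U_bot[i] == brute(a[i - 1 :], b[mid:], al)
    for c, arr in arrays.T_top.items():
        ch = al.char(c)
        v2 = max(j for j in range(1, mid + 1) if b[j - 1] == ch)
        for i in range(len(a) + 1):
            assert arr[i] == brute(a[:i], b[: v2 - 1], al)
    for c, arr in arrays.T_bot.items():
        ch = al.char(c)
        v1 = min(j for j in range(mid + 1, len(b) + 1) if b[j - 1] == ch)
        for i in range(1, len(a) + 2):
            assert arr[i] == brute(a[i - 1 :], b[v1:], al)


@pytest.mark.parametrize("mid", [0, 3, 32, 61, 64])
def test_boundary_arrays_identical_across_engines(enc, mid):
    a, b = random_pair(64, 64, 4, seed=11)
    ea, eb = enc(a, b)
    ls = boundary_arrays(ea, eb, mid, "ls")
    st = boundary_arrays(ea, eb, mid, "strip", q=7)
    assert ls.U_top == st.U_top
    assert ls.U_bot == st.U_bot
    assert ls.T_top == st.T_top
    assert ls.T_bot == st.T_bot


def test_best_split_identical_strings_no_crossing(enc):
    ea, eb = enc("ACGTACGT", "ACGTACGT")
    mid = 4
    cand = best_split(boundary_arrays(ea, eb, mid), ea, eb, mid)
    assert cand.kind == "no-crossing"
    assert cand.cost == 0


def test_best_split_worked_example(enc):
    ea, eb = enc("CA", "ABC")
    mid = 1
    cand = best_split(boundary_arrays(ea, eb, mid), ea, eb, mid)
    assert cand.cost == 2


def test_best_split_cost_is_the_distance_on_random_pairs(enc):
    rng = random.Random(3)
    for trial in range(40):
        m, n = rng.randint(2, 48), rng.randint(2, 48)
        a, b = random_pair(m, n, rng.choice([2, 4, 20]), seed=4000 + trial)
        ea, eb = enc(a, b)
        mid = n // 2
        cand = best_split(boundary_arrays(ea, eb, mid), ea, eb, mid)
        assert cand.cost == dl_distance_full(ea, eb)[0]
        if cand.kind == "crossing":
            assert cand.u1 < cand.u2
            assert cand.v2 <= mid < cand.v1
            assert a[cand.u1 - 1] == b[cand.v1 - 1]
            assert a[cand.u2 - 1] == b[cand.v2 - 1]
            assert a[cand.u1 - 1] != a[cand.u2 - 1]


def test_dc_trace_worked_example(enc):
    ea, eb = enc("CA", "ABC")
    for engine in ("ls", "strip"):
        t = dc_trace(ea, eb, engine, q=1)
        assert trace_cost(t, ea, eb) == 2
        assert apply_edits("CA", trace_to_edits(t, ea, eb)) == "ABC"


def test_dc_trace_all_deletions(enc):
    ea, eb = enc("ACGT", "")
    t = dc_trace(ea, eb)
    assert len(t.lines) == 0
    assert trace_cost(t, ea, eb) == 4


def test_dc_trace_end_to_end_random(enc):
    rng = random.Random(9)
    for trial in range(35):
        m, n = rng.randint(0, 100), rng.randint(0, 100)
        s = rng.choice([4, 20])
        a, b = random_pair(m, n, s, seed=5000 + trial)
        ea, eb = enc(a, b)
        ref = dl_distance_full(ea, eb)[0]
        for engine in ("ls", "strip"):
            t = dc_trace(ea, eb, engine, q=7)
            assert trace_cost(t, ea, eb) == ref
            assert validate_trace(t, ea, eb, strict=True).strict_ok
            assert apply_edits(a, trace_to_edits(t, ea, eb)) == b


def test_dc_trace_exercises_recursion_deeply(enc, monkeypatch):
    """With a tiny base case the recursion and its crossing splits carry the
    full load; optimality must be unaffected."""
    monkeypatch.setattr(trace_dc_mod, "BASE_CASE_CELLS", 16)
    rng = random.Random(10)
    for trial in range(20):
        a, b = random_pair(rng.randint(2, 50), rng.randint(2, 50),
                           rng.choice([2, 4]), seed=6000 + trial)
        ea, eb = enc(a, b)
        ref = dl_distance_full(ea, eb)[0]
        for engine in ("ls", "strip"):
            t = dc_trace(ea, eb, engine, q=3)
            assert trace_cost(t, ea, eb) == ref


def test_dc_trace_work_bound(enc):
    a, b = random_pair(200, 180, 4, seed=3)
    ea, eb = enc(a, b)
    stats = {}
    dc_trace(ea, eb, "ls", stats=stats)
    m, n = 200, 180
    assert stats["cells"] <= 2 * m * n + 64 * (m + n)


def test_dc_trace_swap_invariance(enc):
    a, b = random_pair(30, 70, 4, seed=44)
    ea, eb = enc(a, b)
    t_ab = dc_trace(ea, eb)
    t_ba = dc_trace(eb, ea)
    assert trace_cost(t_ab, ea, eb) == trace_cost(t_ba, eb, ea)
    assert t_ab.lines == tuple(
        sorted((v, u) for (u, v) in t_ba.lines)
    )


def test_dc_trace_rejects_unknown_engine(enc):
    ea, eb = enc("A", "B")
    with pytest.raises(ValueError):
        dc_trace(ea, eb, engine="quantum")
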