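import random

import pytest

from dlcorrect.dl_matrix import dl_distance_full, dl_traceback
from dlcorrect.seqcore import random_pair
from dlcorrect.trace_model import (
    EditOp,
    EditScript,
    Trace,
    apply_edits,
    trace_cost,
    trace_to_edits,
    validate_trace,
)
from dlcorrect.trace_model import cost_breakdown


FIG_LINES = [(1, 2), (3, 1), (4, 3), (5, 6)]


@pytest.fixture
def fig_pair(enc):
    return enc("dafac", "fdbbec")


def test_worked_trace_cost_is_five(fig_pair):
    a, b = fig_pair
    t = Trace.make(FIG_LINES, 5, 6)
    assert trace_cost(t, a, b) == 5
    parts = cost_breakdown(t, a, b)
    assert parts["unbalanced"] == 1
    assert parts["untouched_a"] + parts["untouched_b"] == 3
    assert parts["crossings"] == 1


def test_worked_trace_passes_strict_validation(fig_pair):
    a, b = fig_pair
    report = validate_trace(Trace.make(FIG_LINES, 5, 6), a, b, strict=True)
    assert report.ok and report.p3_ok and report.p4_ok


def test_empty_trace_costs_all_positions(enc):
    a, b = enc("AB", "ABC")
    assert trace_cost(Trace.make([], 2, 3), a, b) == 5


def test_identity_trace_costs_zero(enc):
    a, b = enc("ACGT", "ACGT")
    t = Trace.make([(i, i) for i in range(1, 5)], 4, 4)
    assert trace_cost(t, a, b) == 0


def test_duplicate_endpoint_fails_validation(enc):
    a, b = enc("AB", "AB")
    report = validate_trace(Trace.make([(1, 1), (1, 2)], 2, 2), a, b)
    assert not report.ok
    assert any("duplicate u" in v for v in report.violations)
    with pytest.raises(ValueError):
        trace_cost(Trace.make([(1, 1), (1, 2)], 2, 2), a, b)


def test_out_of_range_line_fails_validation(enc):
    a, b = enc("A", "A")
    report = validate_trace(Trace.make([(2, 1)], 1, 1), a, b)
    assert not report.ok


def test_p4_reported_separately_from_axioms(enc):
    # Valid trace whose crossing pair is balanced but u1 is not the
    # rightmost occurrence of B[v1] before u2: legal trace, P4-violating.
    a, b = enc("AAB", "BA")
    t = Trace.make([(1, 2), (3, 1)], 3, 2)
    report = validate_trace(t, a, b, strict=True)
    assert report.ok and report.p3_ok
    assert not report.p4_ok


def test_worked_trace_edit_script_narration(fig_pair):
    a, b = fig_pair
    script = trace_to_edits(Trace.make(FIG_LINES, 5, 6), a, b)
    assert [op.op for op in script] == [
        "delete", "transpose", "substitute", "insert", "insert",
    ]
    assert len(script) == 5
    assert apply_edits("dafac", script) == "fdbbec"


def test_identity_trace_gives_empty_script(enc):
    a, b = enc("ACGT", "ACGT")
    t = Trace.make([(i, i) for i in range(1, 5)], 4, 4)
    assert len(trace_to_edits(t, a, b)) == 0


def test_apply_edits_edge_cases():
    assert apply_edits("xyz", EditScript(())) == "xyz"
    assert apply_edits("A", EditScript((EditOp("delete", 1),))) == ""
    with pytest.raises(IndexError):
        apply_edits("AB", EditScript((EditOp("transpose", 2),)))
    with pytest.raises(IndexError):
        apply_edits("AB", EditScript((EditOp("delete", 3),)))
    with pytest.raises(ValueError):
        apply_edits("AB", EditScript((EditOp("frobnicate", 1),)))


def test_scripts_from_optimal_traces_replay_b(enc):
    rng = random.Random(8)
    for trial in range(30):
        a, b = random_pair(rng.randint(0, 25), rng.randint(0, 25),
                           rng.choice([2, 4]), seed=300 + trial)
        ea, eb = enc(a, b)
        d, H = dl_distance_full(ea, eb)
        t = dl_traceback(H, ea, eb)
        script = trace_to_edits(t, ea, eb)
        assert len(script) == trace_cost(t, ea, eb) == d
        assert apply_edits(a, script) == b


def test_random_valid_traces_never_beat_the_optimum(enc):
    """Any trace's cost is an upper bound on the DL distance, and its edit
    script replays B with exactly trace_cost operations."""
    rng = random.Random(17)
    for trial in range(40):
        a, b = random_pair(rng.randint(0, 12), rng.randint(0, 12), 3,
                           seed=700 + trial)
        ea, eb = enc(a, b)
        d, _ = dl_distance_full(ea, eb)
        m, n = len(a), len(b)
        k = rng.randint(0, min(m, n))
        us = rng.sample(range(1, m + 1), k)
        vs = rng.sample(range(1, n + 1), k)
        t = Trace.make(zip(us, vs), m, n)
        c = trace_cost(t, ea, eb)
        assert c >= d
        report = validate_trace(t, ea, eb, strict=True)
        if report.ok and report.p3_ok:
            script = trace_to_edits(t, ea, eb)
            assert len(script) == c
            assert apply_edits(a, script) == b
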