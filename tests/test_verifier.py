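"""Verdicts, counterexample localization, and object blame."""

import json

import numpy as np
import pytest

from vericlust import ctl
from vericlust.errors import InputError
from vericlust.model import trace_to_ts
from vericlust.synth import make_blobs, BlobSpec, make_synthetic_trace, plant_blame
from vericlust.traces import trace_from_assignments
from vericlust.verifier import (ValidityProperty, check_iteration,
                                get_satisfy_trace, render_report, validate,
                                validity_formulas, verify_trace)

from conftest import make_chain_ts


def test_validity_formula_set():
    props = {p.name: p for p in validity_formulas()}
    assert set(props) == {"eventually_optimal",
                          "always_optimal_at_convergence", "until_monotone"}
    ef = props["eventually_optimal"]
    assert str(ef.formula) == "EF (converge & handled -> maxDunn & minDiam)"
    assert not ef.in_verdict
    until = props["until_monotone"]
    assert str(until.formula) == ("E[DunnUp U maxDunn] & "
                                  "E[diamDown U minDiam]")
    assert until.in_verdict


def test_obligations_on_monotone_and_dip_fixtures():
    mono_ts = trace_to_ts(make_synthetic_trace("monotone", 8, seed=0))
    dip_ts = trace_to_ts(make_synthetic_trace("dip", 8, seed=0, t_star=5))
    for prop in validity_formulas():
        assert all(ctl.eval_state(mono_ts, prop.obligation, s)
                   for s in mono_ts.states)
    until = next(p for p in validity_formulas() if p.name == "until_monotone")
    truth = [ctl.eval_state(dip_ts, until.obligation, s)
             for s in dip_ts.states]
    assert truth == [True] * 4 + [False] * 4


def test_worked_counterexample_walkthrough():
    """Dunn rises through S4, falls after: invalid, C=(S1..S4), cause=(S5..S8)."""
    trace = make_synthetic_trace("dip", 8, seed=0, t_star=5)
    report = verify_trace(trace)
    assert not report.valid
    until = next(r for r in report.results if r.name == "until_monotone")
    assert not until.holds
    assert until.error_trace == tuple(f"S{t}" for t in range(1, 9))
    assert until.satisfying_states == ("S1", "S2", "S3", "S4")
    assert until.satisfying_transitions == (
        ("S1", "S2"), ("S2", "S3"), ("S3", "S4"))
    assert until.cause == ("S5", "S6", "S7", "S8")
    assert report.real_causes == ("S5", "S6", "S7", "S8")


def test_monotone_and_plateau_traces_are_valid():
    for pattern in ("monotone", "plateau"):
        report = verify_trace(make_synthetic_trace(pattern, 8, seed=0))
        assert report.valid
        assert report.real_causes == ()
        assert all(r.holds for r in report.results if r.in_verdict)


def test_validate_empty_formula_list_is_valid():
    ts = trace_to_ts(make_synthetic_trace("dip", 6, seed=0, t_star=4))
    assert validate(ts, formulas=[]).valid


# ---------------------------------------------------------------------------
# satisfying-trace extraction (backward closure)
# ---------------------------------------------------------------------------

def test_get_satisfy_trace_prefix_region():
    labels = [{"p"}] * 4 + [set()] * 4
    ts = make_chain_ts(labels)
    transitions, c_states = get_satisfy_trace(ts, ctl.Atom("p"))
    assert c_states == {"S1", "S2", "S3", "S4"}
    assert transitions == {("S1", "S2"), ("S2", "S3"), ("S3", "S4")}


def test_get_satisfy_trace_degenerate_regions():
    ts = make_chain_ts([set()] * 3)
    transitions, c_states = get_satisfy_trace(ts, ctl.Atom("p"))
    assert transitions == frozenset() and c_states == frozenset()
    full_ts = make_chain_ts([{"p"}] * 3)
    transitions, c_states = get_satisfy_trace(full_ts, ctl.Atom("p"))
    assert transitions == {("S1", "S2"), ("S2", "S3"), ("S3", "S3")}
    assert c_states == {"S1", "S2", "S3"}


def test_get_satisfy_trace_closure_runs_backwards_only():
    # seed mid-chain: predecessors are pulled in, successors are not
    ts = make_chain_ts([set(), {"p"}, set(), set()])
    transitions, c_states = get_satisfy_trace(ts, ctl.Atom("p"))
    assert c_states == {"S1", "S2"}
    assert transitions == {("S1", "S2")}


# ---------------------------------------------------------------------------
# object blame
# ---------------------------------------------------------------------------

def blame_fixture():
    """6-iteration, 16-object, 2-cluster trace with known switches.

    Objects 7 and 12 switch at t=5; object 3 additionally switches at t=6.
    Obligation fails from t=5 on.
    """
    base = [0] * 8 + [1] * 8
    a = [list(base) for _ in range(6)]
    for t in (4, 5):
        a[t][6] = 1 - a[t][6]      # object 7
        a[t][11] = 1 - a[t][11]    # object 12
    a[5][2] = 1 - a[5][2]          # object 3 at the last iteration
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(size=(8, 2)),
                   rng.normal(size=(8, 2)) + [12, 0]])
    return trace_from_assignments(X, a, k=2)


def test_check_iteration_hand_traced_branches():
    trace = blame_fixture()
    ok = [True] * 4 + [False, False]
    blamed = check_iteration(trace, ok, 5)
    assert blamed == {7, 12, 3}


def test_check_iteration_no_changes_yields_empty():
    base = [0] * 4 + [1] * 4
    X = np.random.default_rng(1).normal(size=(8, 2))
    trace = trace_from_assignments(X, [base] * 5, k=2)
    assert check_iteration(trace, [True, True, False, False, False], 3) == set()


def test_check_iteration_settled_movers_are_exonerated():
    # objects move at t=3; trend normal at t=4 and the movers stay put
    base = [0] * 6 + [1] * 6
    moved = list(base)
    moved[0] = 1
    a = [base, base, moved, moved, moved]
    X = np.random.default_rng(2).normal(size=(12, 2))
    trace = trace_from_assignments(X, a, k=2)
    assert check_iteration(trace, [True, True, False, True, True], 3) == set()


def test_check_iteration_first_iteration_seeds_from_empty_allocation():
    trace = blame_fixture()
    blamed = check_iteration(trace, [False] + [True] * 5, 1)
    # every object "changed" from the empty allocation, then all settle at
    # t=2 under a normal trend
    assert blamed == set()
    with pytest.raises(InputError):
        check_iteration(trace, [True] * 6, 0)


def test_planted_blame_end_to_end():
    X, truth = make_blobs(BlobSpec(k=2, n_per_cluster=10, seed=5,
                                   separation=12.0))
    base = trace_from_assignments(X, [truth] * 6, k=2)
    planted = plant_blame(base, 4, [2, 9, 15], X, oscillate=True)
    report = verify_trace(planted.trace)
    assert not report.valid
    assert set(report.blamed_objects) & {2, 9, 15}


def test_plant_zero_objects_keeps_trace_valid():
    X, truth = make_blobs(BlobSpec(k=2, n_per_cluster=10, seed=6,
                                   separation=12.0))
    base = trace_from_assignments(X, [truth] * 5, k=2)
    planted = plant_blame(base, 3, [], X)
    assert planted.trace.records == base.records
    assert verify_trace(planted.trace).valid


# ---------------------------------------------------------------------------
# report invariants and rendering
# ---------------------------------------------------------------------------

def test_cause_and_subtrace_partition_error_trace():
    report = verify_trace(make_synthetic_trace("dip", 8, seed=1, t_star=5))
    for r in report.results:
        if r.holds:
            continue
        assert set(r.cause).isdisjoint(r.satisfying_states)
        assert set(r.cause) | set(r.satisfying_states) == set(r.error_trace)
        assert r.cause   # invalid verdict formulas carry a non-empty cause


def test_verdict_consistency():
    for pattern, t_star in (("monotone", None), ("dip", 5)):
        trace = make_synthetic_trace(pattern, 8, seed=2, t_star=t_star)
        report = verify_trace(trace)
        verdict_results = [r for r in report.results if r.in_verdict]
        assert report.valid == all(r.holds for r in verdict_results)
        assert report.valid == (not report.real_causes)


def test_render_report_json_and_text():
    valid = verify_trace(make_synthetic_trace("monotone", 6, seed=0))
    doc = json.loads(render_report(valid, "json"))
    assert doc["valid"] is True
    assert doc["real_causes"] == []
    invalid = verify_trace(make_synthetic_trace("dip", 8, seed=0, t_star=5))
    doc = json.loads(render_report(invalid, "json"))
    assert doc["valid"] is False
    until = next(f for f in doc["formulas"] if f["name"] == "until_monotone")
    assert until["cause"] == ["S5", "S6", "S7", "S8"]
    assert doc["blamed_objects"] == sorted(doc["blamed_objects"])
    text = render_report(invalid, "text")
    assert "INVALID" in text and "cause" in text
    with pytest.raises(InputError):
        render_report(valid, "pdf")


def test_custom_property_via_validate():
    ts = trace_to_ts(make_synthetic_trace("monotone", 6, seed=0))
    prop = ValidityProperty(name="user", formula=ctl.parse("AG handled"),
                            obligation=ctl.Atom("handled"))
    assert validate(ts, [prop]).valid
    prop_bad = ValidityProperty(name="user", formula=ctl.parse("AG converge"),
                                obligation=ctl.Atom("converge"))
    report = validate(ts, [prop_bad])
    assert not report.valid
    # obligation true only at the terminal state: the backward closure
    # absorbs the whole chain, so the empty cause must be flagged
    assert report.real_causes == ()
    assert any("empty cause" in note for note in report.notes)
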