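"""Validity verification with counterexample and blame localization.

The verifier checks a labeled transition system (normally the linear Kripke
structure of one clustering run) against the CTL validity properties built
from the Dunn / maximum-diameter series:

* ``until_monotone`` — ``E[DunnUp U maxDunn] & E[diamDown U minDiam]``:
  the Dunn index rises step by step until it peaks at the converged end of
  the run, and the diameter falls until it bottoms out.
* ``eventually_optimal`` — ``EF[(converge & handled) -> (maxDunn & minDiam)]``:
  the literal "eventually the converged, fully-handled state is optimal"
  form. Because an implication under EF is satisfied by any state that
  falsifies its antecedent, this form is vacuously true on almost every
  trace; it is checked and reported for fidelity but excluded from the
  verdict.
* ``always_optimal_at_convergence`` — the AG form of the same implication,
  which is the universal reading of "when the run converges and every
  object is handled, the indices are at their extrema"; this drives the
  verdict together with ``until_monotone``.

When a verdict formula fails, the error trace ``T`` is the full execution
path; the satisfying sub-trace ``C`` is extracted by seeding the states
where the formula's per-state *obligation* holds and closing backwards over
incoming transitions; the cause is ``T - C``. Object-level blame then
compares each violating iteration with its successor: objects that switched
clusters into a violating iteration are implicated unless the trend
recovers and they settle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from . import ctl
from .errors import InputError
from .indices import UNASSIGNED
from .model import TransitionSystem, trace_to_ts
from .traces import IterationTrace

__all__ = [
    "ValidityProperty",
    "FormulaResult",
    "VerificationReport",
    "validity_formulas",
    "get_satisfy_trace",
    "check_iteration",
    "validate",
    "verify_trace",
    "render_report",
]


@dataclass(frozen=True)
class ValidityProperty:
    """A CTL property together with its per-state obligation.

    The obligation is the boolean state formula whose truth marks an
    iteration as behaving well with respect to the property; it seeds the
    satisfying-trace extraction.
    """

    name: str
    formula: ctl.Formula
    obligation: ctl.Formula
    in_verdict: bool = True


def validity_formulas() -> list[ValidityProperty]:
    """The validity property set over the six trace atomic propositions."""
    converge, handled = ctl.Atom("converge"), ctl.Atom("handled")
    dunn_up, max_dunn = ctl.Atom("DunnUp"), ctl.Atom("maxDunn")
    diam_down, min_diam = ctl.Atom("diamDown"), ctl.Atom("minDiam")
    optimal = ctl.Implies(ctl.And(converge, handled),
                          ctl.And(max_dunn, min_diam))
    return [
        ValidityProperty(
            name="eventually_optimal",
            formula=ctl.EF(optimal),
            obligation=optimal,
            in_verdict=False,   # vacuous under EF; reported for fidelity
        ),
        ValidityProperty(
            name="always_optimal_at_convergence",
            formula=ctl.AG(optimal),
            obligation=optimal,
        ),
        ValidityProperty(
            name="until_monotone",
            formula=ctl.And(ctl.EU(dunn_up, max_dunn),
                            ctl.EU(diam_down, min_diam)),
            obligation=ctl.And(ctl.Or(dunn_up, max_dunn),
                               ctl.Or(diam_down, min_diam)),
        ),
    ]


@dataclass(frozen=True)
class FormulaResult:
    """Outcome of checking one property: verdict plus T / C / cause."""

    name: str
    formula: str
    obligation: str
    holds: bool
    in_verdict: bool
    error_trace: tuple[str, ...] = ()           # T
    satisfying_states: tuple[str, ...] = ()     # C (states)
    satisfying_transitions: tuple[tuple[str, str], ...] = ()
    cause: tuple[str, ...] = ()                 # T \ C


@dataclass(frozen=True)
class VerificationReport:
    """Full verdict for one transition system / clustering run."""

    valid: bool
    results: tuple[FormulaResult, ...]
    real_causes: tuple[str, ...]
    blamed_objects: tuple[int, ...] = ()
    notes: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict, compare=False)


# ---------------------------------------------------------------------------
# satisfying-trace extraction (backward closure from obligation states)
# ---------------------------------------------------------------------------

def get_satisfy_trace(
    ts: TransitionSystem,
    obligation: ctl.Formula,
    states=None,
) -> tuple[frozenset[tuple[str, str]], frozenset[str]]:
    """Transitions and states of the obligation-satisfying sub-structure.

    Seeds every state of ``states`` (default: all) where the obligation
    holds, then repeatedly pulls in each incoming transition of a worklist
    state, adding its source to the worklist (backward closure). Returns
    ``(transitions, C)`` where ``C`` is the seed set united with the
    endpoints of the collected transitions.
    """
    if states is None:
        states = ts.states
    seeds = {s for s in states if ctl.eval_state(ts, obligation, s)}
    pre = ts.predecessors()
    worklist = list(seeds)
    visited: set[str] = set()
    transitions: set[tuple[str, str]] = set()
    while worklist:
        vj = worklist.pop()
        if vj in visited:
            continue
        visited.add(vj)
        for vi in pre[vj]:
            worklist.append(vi)
            transitions.add((vi, vj))
    c_states = set(seeds)
    for vi, vj in transitions:
        c_states.update((vi, vj))
    return frozenset(transitions), frozenset(c_states)


# ---------------------------------------------------------------------------
# object blame (iteration comparison)
# ---------------------------------------------------------------------------

def _changed_objects(trace: IterationTrace, t: int) -> set[int]:
    """1-based ids of objects whose cluster at iteration ``t`` differs from
    ``t - 1``; iteration 0 is the empty allocation (everything UNASSIGNED)."""
    current = trace.records[t - 1].assignment
    if t == 1:
        previous = (UNASSIGNED,) * trace.n_objects
    else:
        previous = trace.records[t - 2].assignment
    return {
        trace.object_ids[i]
        for i in range(trace.n_objects)
        if current[i] != previous[i]
    }


def check_iteration(
    trace: IterationTrace,
    obligation_ok,
    start: int,
) -> set[int]:
    """Blame objects for the violation starting at iteration ``start``.

    ``obligation_ok[t-1]`` tells whether the per-state obligation holds at
    iteration ``t``. The procedure collects the objects that switched
    clusters into the first violating iteration; if the trend is back to
    normal at the next iteration, movers that have settled there are
    exonerated (their move was beneficial); if the trend is still abnormal,
    the next iteration is examined the same way and its movers are added,
    and at the final iteration any freshly moved objects join the set.
    Runtime is O(r * n) for r examined iterations and n objects.
    """
    T = len(trace.records)
    if not 1 <= start <= T:
        raise InputError(f"start iteration {start} outside 1..{T}")
    obligation_ok = list(obligation_ok)
    if len(obligation_ok) != T:
        raise InputError("obligation_ok must have one entry per record")

    def walk(t: int) -> set[int]:
        object_set = _changed_objects(trace, t)
        if t == T:
            return object_set
        if obligation_ok[t]:  # trend normal at t + 1
            settled = {
                trace.object_ids[i]
                for i in range(trace.n_objects)
                if trace.records[t - 1].assignment[i]
                == trace.records[t].assignment[i]
            }
            return object_set - settled
        if t + 1 < T:
            return object_set | walk(t + 1)
        return object_set | (_changed_objects(trace, t + 1) - object_set)

    return walk(start)


# ---------------------------------------------------------------------------
# top-level verdict
# ---------------------------------------------------------------------------

def validate(
    ts: TransitionSystem,
    formulas: list[ValidityProperty] | None = None,
    *,
    trace: IterationTrace | None = None,
    blame: bool = True,
) -> VerificationReport:
    """Check every validity property and localize violations.

    For each failing property the error trace ``T`` is the execution path
    (all states in canonical order), the satisfying sub-trace ``C`` comes
    from :func:`get_satisfy_trace`, and the cause is the states of ``T``
    absent from ``C``. ``real_causes`` is the order-preserving union of all
    causes; the verdict is valid exactly when every verdict property holds
    (equivalently, when ``real_causes`` restricted to verdict properties is
    empty). With a trace attached (or recoverable from ``ts.meta``), object
    blame is computed from the first violating iteration.
    """
    if formulas is None:
        formulas = validity_formulas()
    if trace is None:
        trace = ts.meta.get("trace")

    results: list[FormulaResult] = []
    notes: list[str] = []
    cause_union: list[str] = []
    verdict = True
    first_violation: int | None = None
    blame_series: list[bool] | None = None
    state_order = {s: i for i, s in enumerate(ts.states)}

    for prop in formulas:
        holds = ctl.check(ts, prop.formula)
        if holds:
            results.append(FormulaResult(
                name=prop.name, formula=str(prop.formula),
                obligation=str(prop.obligation), holds=True,
                in_verdict=prop.in_verdict))
            continue
        T = tuple(ts.states)
        transitions, c_states = get_satisfy_trace(ts, prop.obligation, T)
        cause = tuple(s for s in T if s not in c_states)
        results.append(FormulaResult(
            name=prop.name, formula=str(prop.formula),
            obligation=str(prop.obligation), holds=False,
            in_verdict=prop.in_verdict,
            error_trace=T,
            satisfying_states=tuple(s for s in T if s in c_states),
            satisfying_transitions=tuple(sorted(transitions)),
            cause=cause,
        ))
        if not prop.in_verdict:
            continue
        verdict = False
        for s in cause:
            if s not in cause_union:
                cause_union.append(s)
        # Blame anchors at the first iteration whose obligation fails (on
        # prefix-shaped obligation regions this is exactly the first cause
        # state; on non-prefix regions the backward closure can empty the
        # cause even though violating states exist).
        series = [ctl.eval_state(ts, prop.obligation, s) for s in ts.states]
        record_index = ts.meta.get("record_index")
        violating = [record_index[s] for s, ok in zip(ts.states, series)
                     if not ok] if record_index is not None else []
        if not cause:
            notes.append(
                f"{prop.name}: property fails but the backward closure "
                "left an empty cause; consistent with an initial-allocation "
                "error carried through the run, which is outside the scope "
                "of iteration blame.")
        if not violating:
            notes.append(
                f"{prop.name}: property fails but every state satisfies its "
                "obligation; consistent with an initial-allocation error, "
                "which is outside the scope of iteration blame.")
        elif trace is not None:
            t0 = min(violating)
            if first_violation is None or t0 < first_violation:
                first_violation = t0
                blame_series = series

    cause_union.sort(key=state_order.get)
    blamed: tuple[int, ...] = ()
    if blame and trace is not None and first_violation is not None:
        blamed = tuple(sorted(check_iteration(
            trace, blame_series, first_violation)))
        if not blamed:
            notes.append(
                "no object-level blame: no membership changes in the "
                "violating suffix (consistent with an initial-allocation "
                "error, outside the scope of iteration blame).")

    return VerificationReport(
        valid=verdict,
        results=tuple(results),
        real_causes=tuple(cause_union),
        blamed_objects=blamed,
        notes=tuple(notes),
        meta={"ts": ts, "trace": trace},
    )


def verify_trace(
    trace: IterationTrace,
    formulas: list[ValidityProperty] | None = None,
    *,
    blame: bool = True,
) -> VerificationReport:
    """Convenience wrapper: build the linear Kripke structure and validate."""
    return validate(trace_to_ts(trace), formulas, trace=trace, blame=blame)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

REPORT_SCHEMA_VERSION = 1


def report_to_document(report: VerificationReport) -> dict:
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "valid": report.valid,
        "formulas": [
            {
                "name": r.name,
                "formula": r.formula,
                "obligation": r.obligation,
                "holds": r.holds,
                "in_verdict": r.in_verdict,
                "error_trace": list(r.error_trace),
                "satisfying_states": list(r.satisfying_states),
                "satisfying_transitions": [list(e) for e in
                                           r.satisfying_transitions],
                "cause": list(r.cause),
            }
            for r in report.results
        ],
        "real_causes": list(report.real_causes),
        "blamed_objects": [int(o) for o in report.blamed_objects],
        "notes": list(report.notes),
    }


def render_report(report: VerificationReport, fmt: str = "json") -> str:
    """Serialize a report deterministically as JSON or readable text."""
    if fmt == "json":
        return json.dumps(report_to_document(report), indent=2) + "\n"
    if fmt == "text":
        lines = [f"verdict: {'valid' if report.valid else 'INVALID'}"]
        for r in report.results:
            tag = "" if r.in_verdict else " (reported only)"
            lines.append(f"  [{'ok' if r.holds else 'FAIL'}] {r.name}{tag}: "
                         f"{r.formula}")
            if not r.holds:
                lines.append(f"      T     = ({', '.join(r.error_trace)})")
                lines.append(
                    f"      C     = ({', '.join(r.satisfying_states)})")
                lines.append(f"      cause = ({', '.join(r.cause)})")
        if report.real_causes:
            lines.append(f"  real causes: ({', '.join(report.real_causes)})")
        if report.blamed_objects:
            lines.append("  blamed objects: "
                         + ", ".join(str(o) for o in report.blamed_objects))
        for note in report.notes:
            lines.append(f"  note: {note}")
        return "\n".join(lines) + "\n"
    raise InputError(f"unknown report format: {fmt!r}")
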