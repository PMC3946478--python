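"""Program graphs, transition systems, and trace labeling.

A clustering run is modeled at two levels:

* A **program graph** over binary variables describes the algorithm itself:
  locations, the two clustering actions ``compare`` (distance evaluation;
  never changes any variable) and ``allocate`` (cluster assignment), guarded
  transitions, and an initial condition. Unfolding a program graph yields
  every reachable (location, valuation) state — a finite transition system
  whose size is bounded by ``|Loc| * 2^t * 2^k`` where ``t`` counts binary
  condition variables and ``k`` per-cluster change flags.

* A concrete run (an :class:`~vericlust.traces.IterationTrace`) is one path
  through that system: :func:`trace_to_ts` builds the linear Kripke
  structure ``S1 -> S2 -> ... -> ST`` (with a self-loop at ``ST`` so the
  structure is total, as CTL semantics requires), labeling each state with
  the six validity atomic propositions::

      converge   the run's convergence flag is set
      handled    every object has been allocated
      DunnUp     the Dunn index did not decrease from the previous state
      diamDown   the maximum diameter did not increase
      maxDunn    converged, fully-handled state attaining the trace-wide
                 maximum of the Dunn series
      minDiam    likewise for the trace-wide minimum of the diameter series

  ``DunnUp``/``diamDown`` are non-strict and vacuously true at the first
  state and wherever the index is undefined (early DBSCAN rounds with fewer
  than two clusters must not spuriously violate the properties).
  ``maxDunn``/``minDiam`` require the converged terminal phase to attain
  the extremum; ties all receive the label.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

from .errors import CTLError, InputError, StateBoundError
from .traces import IterationTrace

VALIDITY_ATOMS = ("converge", "handled", "DunnUp", "maxDunn",
                  "diamDown", "minDiam")

__all__ = [
    "VALIDITY_ATOMS",
    "GuardedTransition",
    "ProgramGraph",
    "TransitionSystem",
    "kmeans_program_graph",
    "dbscan_program_graph",
    "unfold",
    "label_atomic_props",
    "trace_to_ts",
]


# ---------------------------------------------------------------------------
# program graphs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuardedTransition:
    """One conditional transition ``source --g:action--> target``.

    ``guard`` is a conjunction of variable=value requirements (empty =
    always enabled); ``effect`` is the partial assignment the action applies
    to the valuation (empty = identity, as for ``compare``).
    """

    source: str
    guard: tuple[tuple[str, int], ...]
    action: str
    effect: tuple[tuple[str, int], ...]
    target: str

    def enabled(self, valuation: dict) -> bool:
        return all(valuation[v] == val for v, val in self.guard)

    def apply(self, valuation: dict) -> dict:
        out = dict(valuation)
        out.update(self.effect)
        return out


@dataclass(frozen=True)
class ProgramGraph:
    """Guarded-transition graph over binary variables.

    ``cluster_flags`` are the per-cluster change variables (rs);
    ``condition_flags`` the remaining binary condition variables (conv,
    deal). All domains are {0, 1}.
    """

    locations: tuple[str, ...]
    actions: tuple[str, ...]
    cluster_flags: tuple[str, ...]
    condition_flags: tuple[str, ...]
    transitions: tuple[GuardedTransition, ...]
    initial_locations: tuple[str, ...]
    initial_condition: tuple[tuple[str, int], ...]

    @property
    def variables(self) -> tuple[str, ...]:
        return self.cluster_flags + self.condition_flags

    def __post_init__(self):
        declared = set(self.variables)
        for tr in self.transitions:
            for v, _ in tr.guard + tr.effect:
                if v not in declared:
                    raise InputError(
                        f"transition references undeclared variable {v!r}")
        for v, _ in self.initial_condition:
            if v not in declared:
                raise InputError(
                    f"initial condition references undeclared variable {v!r}")

    def effect(self, action: str, valuation: dict) -> list[dict]:
        """All valuations reachable by ``action`` from ``valuation``.

        The effect function of the formalism; nondeterministic actions
        (allocate under non-convergence) return several outcomes,
        ``compare`` returns the valuation unchanged.
        """
        out = []
        for tr in self.transitions:
            if tr.action == action and tr.enabled(valuation):
                nxt = tr.apply(valuation)
                if nxt not in out:
                    out.append(nxt)
        return out


def kmeans_program_graph(k: int) -> ProgramGraph:
    """Program graph of K-Means with ``k`` clusters.

    Variables: ``rs0 .. rs{k-1}`` (per-cluster membership-changed flags) and
    ``conv``. Initially nothing is allocated: all rs = 0, conv = 0. The
    first ``allocate`` leaves the initial location; thereafter, while not
    convergent, ``compare`` changes nothing and ``allocate``
    nondeterministically flips any subset of the rs flags and may or may not
    reach convergence (the outcome depends on the data, which the graph
    abstracts away). Once convergent, clusters stop changing: ``allocate``
    clears every rs flag and the valuation is frozen.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    rs = tuple(f"rs{i}" for i in range(k))
    transitions: list[GuardedTransition] = []

    def alloc_outcomes(source: str):
        # any rs pattern, convergence reached or not
        for pattern in itertools.product((0, 1), repeat=k):
            for conv in (0, 1):
                effect = tuple(zip(rs, pattern)) + (("conv", conv),)
                transitions.append(GuardedTransition(
                    source, (("conv", 0),), "allocate", effect, "loop"))

    alloc_outcomes("init")
    alloc_outcomes("loop")
    transitions.append(GuardedTransition(
        "loop", (("conv", 0),), "compare", (), "loop"))
    transitions.append(GuardedTransition(
        "loop", (("conv", 1),), "compare", (), "loop"))
    transitions.append(GuardedTransition(
        "loop", (("conv", 1),), "allocate",
        tuple((v, 0) for v in rs), "loop"))
    return ProgramGraph(
        locations=("init", "loop"),
        actions=("compare", "allocate"),
        cluster_flags=rs,
        condition_flags=("conv",),
        transitions=tuple(transitions),
        initial_locations=("init",),
        initial_condition=tuple((v, 0) for v in rs) + (("conv", 0),),
    )


def dbscan_program_graph() -> ProgramGraph:
    """Program graph of DBSCAN.

    Variables: ``conv`` (the current core object's density-reachable set is
    exhausted) and ``deal`` (every object has been allocated). While
    ``deal`` = 0, ``allocate`` nondeterministically finishes the current
    expansion and possibly the whole run; ``deal`` can only become 1
    together with ``conv`` (the run cannot complete mid-expansion). With
    ``conv`` = 1 and ``deal`` = 0 a new core object starts the next round.
    Once ``conv`` = ``deal`` = 1, no action changes anything.
    """
    outcomes = (((("conv", 0), ("deal", 0))),
                ((("conv", 1), ("deal", 0))),
                ((("conv", 1), ("deal", 1))))
    transitions = []
    for source in ("init", "loop"):
        for effect in outcomes:
            transitions.append(GuardedTransition(
                source, (("deal", 0),), "allocate", effect, "loop"))
    transitions += [
        GuardedTransition("loop", (("deal", 0),), "compare", (), "loop"),
        GuardedTransition("loop", (("conv", 1), ("deal", 1)),
                          "compare", (), "loop"),
        GuardedTransition("loop", (("conv", 1), ("deal", 1)),
                          "allocate", (), "loop"),
    ]
    return ProgramGraph(
        locations=("init", "loop"),
        actions=("compare", "allocate"),
        cluster_flags=(),
        condition_flags=("conv", "deal"),
        transitions=tuple(transitions),
        initial_locations=("init",),
        initial_condition=(("conv", 0), ("deal", 0)),
    )


# ---------------------------------------------------------------------------
# transition systems
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionSystem:
    """Finite Kripke structure.

    ``states`` fixes a canonical order (trace order for linear systems);
    ``transitions`` maps each state to its successor set. Every produced
    system is total: terminal states carry a self-loop.
    """

    states: tuple[str, ...]
    transitions: dict[str, frozenset[str]]
    initial: frozenset[str]
    ap: frozenset[str]
    labels: dict[str, frozenset[str]]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        known = set(self.states)
        if not self.initial <= known:
            raise InputError("initial states must be states")
        for s in self.states:
            if not self.labels.get(s, frozenset()) <= self.ap:
                raise InputError(f"labels of {s} not a subset of AP")
            if not self.transitions.get(s, frozenset()) <= known:
                raise InputError(f"successors of {s} include unknown states")

    def successors(self, state: str) -> frozenset[str]:
        return self.transitions[state]

    def predecessors(self) -> dict[str, frozenset[str]]:
        pre: dict[str, set[str]] = {s: set() for s in self.states}
        for s, succs in self.transitions.items():
            for t in succs:
                pre[t].add(s)
        return {s: frozenset(v) for s, v in pre.items()}

    def edges(self) -> list[tuple[str, str]]:
        return [(s, t) for s in self.states
                for t in sorted(self.transitions[s])]

    @property
    def is_total(self) -> bool:
        return all(self.transitions[s] for s in self.states)

    def require_total(self) -> None:
        for s in self.states:
            if not self.transitions[s]:
                raise CTLError(f"transition system is not total: {s} has "
                               "no outgoing transition")

    # -- export -------------------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "states": list(self.states),
            "initial": sorted(self.initial),
            "ap": sorted(self.ap),
            "labels": {s: sorted(self.labels[s]) for s in self.states},
            "edges": [list(e) for e in self.edges()],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=2)

    def to_dot(self) -> str:
        """GraphViz rendering; labels listed under each state name."""
        lines = ["digraph ts {", "  rankdir=LR;"]
        for s in self.states:
            props = ",".join(sorted(self.labels[s])) or "-"
            shape = "doublecircle" if s in self.initial else "circle"
            lines.append(
                f'  "{s}" [shape={shape} label="{s}\\n{{{props}}}"];')
        for s, t in self.edges():
            lines.append(f'  "{s}" -> "{t}";')
        lines.append("}")
        return "\n".join(lines)


def unfold(pg: ProgramGraph, *, max_states: int = 1_000_000) -> TransitionSystem:
    """Unfold a program graph into its reachable transition system.

    States are (location, valuation) pairs reachable from the initial
    locations under the initial condition, closed under enabled guarded
    transitions; terminal states self-loop. Atomic propositions are the
    location names plus one proposition per variable (labeling the states
    where the variable is 1). The state count can never exceed
    ``|Loc| * 2^t * 2^k``; ``max_states`` is an additional safety cap.
    """
    init_valuation = dict(pg.initial_condition)
    missing = set(pg.variables) - set(init_valuation)
    if missing:
        raise InputError(f"initial condition leaves variables unset: {missing}")

    def state_id(loc: str, valuation: dict) -> str:
        bits = ",".join(f"{v}={valuation[v]}" for v in pg.variables)
        return f"{loc}[{bits}]"

    frontier = [(loc, dict(init_valuation)) for loc in pg.initial_locations]
    seen: dict[str, tuple[str, dict]] = {
        state_id(loc, val): (loc, val) for loc, val in frontier}
    order = list(seen)
    succ: dict[str, set[str]] = {s: set() for s in seen}
    queue = list(seen)
    while queue:
        sid = queue.pop(0)
        loc, valuation = seen[sid]
        for tr in pg.transitions:
            if tr.source != loc or not tr.enabled(valuation):
                continue
            nxt_val = tr.apply(valuation)
            nxt_id = state_id(tr.target, nxt_val)
            if nxt_id not in seen:
                if len(seen) >= max_states:
                    raise StateBoundError(
                        f"unfolding exceeded max_states={max_states}")
                seen[nxt_id] = (tr.target, nxt_val)
                order.append(nxt_id)
                succ[nxt_id] = set()
                queue.append(nxt_id)
            succ[sid].add(nxt_id)
    for sid in order:  # totality
        if not succ[sid]:
            succ[sid].add(sid)
    ap = frozenset(pg.locations) | frozenset(pg.variables)
    labels = {
        sid: frozenset({loc}) | frozenset(v for v in pg.variables
                                          if valuation[v] == 1)
        for sid, (loc, valuation) in seen.items()
    }
    return TransitionSystem(
        states=tuple(order),
        transitions={s: frozenset(t) for s, t in succ.items()},
        initial=frozenset(state_id(loc, init_valuation)
                          for loc in pg.initial_locations),
        ap=ap,
        labels=labels,
        meta={"valuations": seen},
    )


# ---------------------------------------------------------------------------
# trace labeling
# ---------------------------------------------------------------------------

def _trend_flags(series, *, up: bool) -> list[bool]:
    """Non-strict monotone-step flags, vacuous at t=1 and undefined values."""
    flags = []
    for t, value in enumerate(series):
        if t == 0 or value is None or series[t - 1] is None:
            flags.append(True)
        elif up:
            flags.append(value >= series[t - 1])
        else:
            flags.append(value <= series[t - 1])
    return flags


def _extremum_flags(series, terminal_mask, *, maximum: bool) -> list[bool]:
    defined = [v for v in series if v is not None]
    if not defined:
        return [False] * len(series)
    target = max(defined) if maximum else min(defined)
    return [
        bool(term) and value is not None and value == target
        for value, term in zip(series, terminal_mask)
    ]


def label_atomic_props(trace: IterationTrace) -> list[frozenset[str]]:
    """Per-record subsets of the six validity atomic propositions.

    See the module docstring for the exact conventions.
    """
    if not trace.records:
        raise InputError("cannot label an empty trace")
    dunn_series = [r.dunn for r in trace.records]
    diam_series = [r.diam for r in trace.records]
    converged = [r.conv == 1 for r in trace.records]
    handled = [r.deal == 1 for r in trace.records]
    terminal = [c and h for c, h in zip(converged, handled)]
    dunn_up = _trend_flags(dunn_series, up=True)
    diam_down = _trend_flags(diam_series, up=False)
    max_dunn = _extremum_flags(dunn_series, terminal, maximum=True)
    min_diam = _extremum_flags(diam_series, terminal, maximum=False)
    out = []
    for t in range(len(trace.records)):
        props = set()
        if converged[t]:
            props.add("converge")
        if handled[t]:
            props.add("handled")
        if dunn_up[t]:
            props.add("DunnUp")
        if diam_down[t]:
            props.add("diamDown")
        if max_dunn[t]:
            props.add("maxDunn")
        if min_diam[t]:
            props.add("minDiam")
        out.append(frozenset(props))
    return out


def trace_to_ts(trace: IterationTrace) -> TransitionSystem:
    """Linear Kripke structure of one clustering run.

    States ``S1 .. ST`` in iteration order, chained, with a self-loop at the
    terminal state; initial state ``S1``; labels from
    :func:`label_atomic_props`.
    """
    labels = label_atomic_props(trace)
    T = len(trace.records)
    states = tuple(f"S{t}" for t in range(1, T + 1))
    transitions = {
        states[t]: frozenset({states[min(t + 1, T - 1)]})
        for t in range(T)
    }
    return TransitionSystem(
        states=states,
        transitions=transitions,
        initial=frozenset({states[0]}),
        ap=frozenset(VALIDITY_ATOMS),
        labels=dict(zip(states, labels)),
        meta={"trace": trace,
              "record_index": {s: t + 1 for t, s in enumerate(states)}},
    )
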