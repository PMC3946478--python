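"""Brute-force CTL reference semantics and random-instance generators.

:func:`sat_bounded` evaluates CTL directly from the path semantics by
bounded path enumeration: existential reachability is loop-free depth-first
search, and the "can a path avoid / stay inside a region forever" questions
behind AF/EG/AU are answered by asking whether a path of length ``|S|`` can
survive inside the region (pigeonhole: such a path must revisit a state,
hence a lasso exists). This shares no code with the fixpoint labeling
algorithm in :mod:`vericlust.ctl` and serves as its independent
cross-check on small systems.

The random generators produce seeded Kripke structures (total by
construction) and CTL formulas of bounded depth for equivalence testing.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from . import ctl
from .model import TransitionSystem

__all__ = ["sat_bounded", "random_transition_system", "random_formula"]


def sat_bounded(ts: TransitionSystem, f: ctl.Formula) -> frozenset[str]:
    """Satisfaction set of ``f`` computed from path semantics.

    Intended for small systems (the cost is polynomial but with worse
    constants than the labeling algorithm).
    """
    ts.require_total()
    horizon = len(ts.states)
    succ = ts.transitions

    def holds(state: str, node: ctl.Formula) -> bool:
        if isinstance(node, ctl.TrueF):
            return True
        if isinstance(node, ctl.FalseF):
            return False
        if isinstance(node, ctl.Atom):
            return node.name in ts.labels[state]
        if isinstance(node, ctl.Not):
            return not holds(state, node.operand)
        if isinstance(node, ctl.And):
            return holds(state, node.left) and holds(state, node.right)
        if isinstance(node, ctl.Or):
            return holds(state, node.left) or holds(state, node.right)
        if isinstance(node, ctl.Implies):
            return not holds(state, node.left) or holds(state, node.right)
        if isinstance(node, ctl.EX):
            return any(holds(t, node.operand) for t in succ[state])
        if isinstance(node, ctl.AX):
            return all(holds(t, node.operand) for t in succ[state])
        if isinstance(node, ctl.EF):
            return _reach(state, lambda s: holds(s, node.operand),
                          lambda s: True)
        if isinstance(node, ctl.AG):
            # AG p == no path reaches !p
            return not _reach(state, lambda s: not holds(s, node.operand),
                              lambda s: True)
        if isinstance(node, ctl.EU):
            return _reach(state, lambda s: holds(s, node.right),
                          lambda s: holds(s, node.left))
        if isinstance(node, ctl.EG):
            # exists an infinite path inside p: survive |S| steps in p
            return _survive(state, lambda s: holds(s, node.operand), horizon)
        if isinstance(node, ctl.AF):
            # AF p fails iff some path avoids p for |S| steps (lasso in !p)
            return not _survive(state,
                                lambda s: not holds(s, node.operand), horizon)
        if isinstance(node, ctl.AU):
            # A[p U q] fails iff a q-avoiding path reaches !p or lives forever
            return not _violates_au(state, node.left, node.right)
        raise TypeError(f"unknown formula node: {node!r}")

    def _reach(state, target, through) -> bool:
        # loop-free DFS: is a target-state reachable along through-states?
        stack, seen = [state], {state}
        while stack:
            s = stack.pop()
            if target(s):
                return True
            if not through(s):
                continue
            for t in succ[s]:
                if t not in seen:
                    seen.add(t)
                    stack.append(t)
        return False

    def _survive(state, inside, budget) -> bool:
        # can some path stay in `inside` for `budget` more steps?
        @lru_cache(maxsize=None)
        def go(s: str, d: int) -> bool:
            if not inside(s):
                return False
            if d == 0:
                return True
            return any(go(t, d - 1) for t in succ[s])
        return go(state, budget)

    def _violates_au(state, left, right) -> bool:
        @lru_cache(maxsize=None)
        def bad(s: str, d: int) -> bool:
            if holds(s, right):
                return False
            if not holds(s, left):
                return True       # stuck before reaching right
            if d == 0:
                return True       # survived |S| steps: lasso avoiding right
            return any(bad(t, d - 1) for t in succ[s])
        return bad(state, horizon)

    return frozenset(s for s in ts.states if holds(s, f))


# ---------------------------------------------------------------------------
# random instances
# ---------------------------------------------------------------------------

def random_transition_system(
    rng: np.random.Generator,
    *,
    max_states: int = 8,
    atom_names: tuple[str, ...] = ("p", "q", "r"),
) -> TransitionSystem:
    """Seeded random total Kripke structure with <= ``max_states`` states."""
    n = int(rng.integers(1, max_states + 1))
    states = tuple(f"S{i}" for i in range(1, n + 1))
    transitions = {}
    for s in states:
        out_degree = int(rng.integers(1, min(n, 3) + 1))
        succ = rng.choice(n, size=out_degree, replace=False)
        transitions[s] = frozenset(states[j] for j in succ)
    labels = {
        s: frozenset(a for a in atom_names if rng.random() < 0.5)
        for s in states
    }
    n_init = int(rng.integers(1, n + 1))
    initial = frozenset(states[j] for j in rng.choice(n, size=n_init,
                                                      replace=False))
    return TransitionSystem(
        states=states,
        transitions=transitions,
        initial=initial,
        ap=frozenset(atom_names),
        labels=labels,
    )


def random_formula(
    rng: np.random.Generator,
    *,
    atom_names: tuple[str, ...] = ("p", "q", "r"),
    depth: int = 3,
) -> ctl.Formula:
    """Seeded random CTL formula of nesting depth <= ``depth``."""
    if depth == 0 or rng.random() < 0.25:
        roll = rng.random()
        if roll < 0.8:
            return ctl.Atom(str(rng.choice(atom_names)))
        return ctl.TRUE if roll < 0.9 else ctl.FALSE
    unary = (ctl.Not, ctl.EX, ctl.AX, ctl.EF, ctl.AF, ctl.EG, ctl.AG)
    binary = (ctl.And, ctl.Or, ctl.Implies, ctl.EU, ctl.AU)
    if rng.random() < 0.55:
        op = unary[int(rng.integers(len(unary)))]
        return op(random_formula(rng, atom_names=atom_names, depth=depth - 1))
    op = binary[int(rng.integers(len(binary)))]
    return op(
        random_formula(rng, atom_names=atom_names, depth=depth - 1),
        random_formula(rng, atom_names=atom_names, depth=depth - 1),
    )
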