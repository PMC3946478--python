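"""Computation Tree Logic: syntax, parsing, rewriting, model checking.

Concrete syntax (conventional textbook CTL):

* atoms are identifiers (``converge``, ``DunnUp``, ...); ``true``/``false``
  are constants;
* boolean connectives ``!``, ``&``, ``|``, ``->`` with precedence
  ``!`` > ``&`` > ``|`` > ``->`` (``->`` right-associative);
* unary temporal operators ``EX AX EF AF EG AG`` prefix;
* until in bracket form ``E[phi U psi]`` / ``A[phi U psi]``.

The model checker :func:`sat` computes exact satisfaction sets with the
standard fixpoint labeling algorithm (least fixpoints for EF/AF/EU/AU,
greatest for EG/AG, pre-images for EX/AX); every operator is implemented
natively, so :func:`to_adequate` — which rewrites any formula into the
adequate set {EX, EU, AF} plus ``!``/``&``/``true`` — can be validated
against it. Runtime is linear in ``|S| + |transitions|`` per subformula.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import CTLError, CTLSyntaxError
from .model import TransitionSystem

__all__ = [
    "Formula", "Atom", "TrueF", "FalseF", "Not", "And", "Or", "Implies",
    "EX", "AX", "EF", "AF", "EG", "AG", "EU", "AU",
    "TRUE", "FALSE",
    "parse", "to_adequate", "atoms_of", "sat", "check", "eval_state",
]


# ---------------------------------------------------------------------------
# abstract syntax
# ---------------------------------------------------------------------------

class Formula:
    """Base class of CTL formula nodes; immutable and hashable."""

    def __and__(self, other):  # convenience for building formulas in code
        return And(self, other)

    def __or__(self, other):
        return Or(self, other)

    def __invert__(self):
        return Not(self)


@dataclass(frozen=True)
class Atom(Formula):
    name: str

    def __str__(self):
        return self.name


@dataclass(frozen=True)
class TrueF(Formula):
    def __str__(self):
        return "true"


@dataclass(frozen=True)
class FalseF(Formula):
    def __str__(self):
        return "false"


TRUE = TrueF()
FALSE = FalseF()


def _paren(f: Formula) -> str:
    if isinstance(f, (Atom, TrueF, FalseF, Not, EX, AX, EF, AF, EG, AG, EU, AU)):
        return str(f)
    return f"({f})"


@dataclass(frozen=True)
class Not(Formula):
    operand: Formula

    def __str__(self):
        return f"!{_paren(self.operand)}"


@dataclass(frozen=True)
class And(Formula):
    left: Formula
    right: Formula

    def __str__(self):
        # right operand parenthesized when it is itself an And so the
        # left-associative parser reconstructs the same tree
        def side(f, right):
            lower = (Or, Implies) + ((And,) if right else ())
            return f"({f})" if isinstance(f, lower) else str(f)
        return f"{side(self.left, False)} & {side(self.right, True)}"


@dataclass(frozen=True)
class Or(Formula):
    left: Formula
    right: Formula

    def __str__(self):
        def side(f, right):
            lower = (Implies,) + ((Or,) if right else ())
            return f"({f})" if isinstance(f, lower) else str(f)
        return f"{side(self.left, False)} | {side(self.right, True)}"


@dataclass(frozen=True)
class Implies(Formula):
    left: Formula
    right: Formula

    def __str__(self):
        left = f"({self.left})" if isinstance(self.left, Implies) else str(self.left)
        return f"{left} -> {self.right}"


def _unary(op_name: str):
    @dataclass(frozen=True)
    class _Op(Formula):
        operand: Formula

        def __str__(self):
            return f"{op_name} {_paren(self.operand)}"
    _Op.__name__ = _Op.__qualname__ = op_name
    return _Op


EX = _unary("EX")
AX = _unary("AX")
EF = _unary("EF")
AF = _unary("AF")
EG = _unary("EG")
AG = _unary("AG")


@dataclass(frozen=True)
class EU(Formula):
    left: Formula
    right: Formula

    def __str__(self):
        return f"E[{self.left} U {self.right}]"


@dataclass(frozen=True)
class AU(Formula):
    left: Formula
    right: Formula

    def __str__(self):
        return f"A[{self.left} U {self.right}]"


def atoms_of(f: Formula) -> frozenset[str]:
    """Names of all atomic propositions occurring in ``f``."""
    if isinstance(f, Atom):
        return frozenset({f.name})
    if isinstance(f, (TrueF, FalseF)):
        return frozenset()
    if isinstance(f, (Not, EX, AX, EF, AF, EG, AG)):
        return atoms_of(f.operand)
    return atoms_of(f.left) | atoms_of(f.right)


# ---------------------------------------------------------------------------
# parser (recursive descent)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(->|[!&|()\[\]]|[A-Za-z_][A-Za-z0-9_]*)")
_UNARY_OPS = {"EX": EX, "AX": AX, "EF": EF, "AF": AF, "EG": EG, "AG": AG}
_RESERVED = set(_UNARY_OPS) | {"E", "A", "U", "true", "false"}


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens: list[tuple[str, int]] = []
        pos = 0
        while pos < len(text):
            if not text[pos:].strip():
                break
            m = _TOKEN_RE.match(text, pos)
            if m is None:
                stripped = text[pos:].lstrip()
                at = len(text) - len(stripped)
                raise CTLSyntaxError(
                    f"unexpected character {stripped[0]!r}", at)
            self.tokens.append((m.group(1), m.start(1)))
            pos = m.end()
        self.i = 0

    def peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def pos(self) -> int:
        if self.i < len(self.tokens):
            return self.tokens[self.i][1]
        return len(self.text)

    def take(self, expected: str | None = None) -> str:
        tok = self.peek()
        if tok is None:
            raise CTLSyntaxError(
                f"unexpected end of formula"
                + (f", expected {expected!r}" if expected else ""),
                len(self.text))
        if expected is not None and tok != expected:
            raise CTLSyntaxError(
                f"expected {expected!r}, found {tok!r}", self.pos())
        self.i += 1
        return tok

    # precedence:  ->  <  |  <  &  <  unary
    def formula(self) -> Formula:
        left = self.disjunction()
        if self.peek() == "->":
            self.take()
            return Implies(left, self.formula())  # right-associative
        return left

    def disjunction(self) -> Formula:
        node = self.conjunction()
        while self.peek() == "|":
            self.take()
            node = Or(node, self.conjunction())
        return node

    def conjunction(self) -> Formula:
        node = self.unary()
        while self.peek() == "&":
            self.take()
            node = And(node, self.unary())
        return node

    def unary(self) -> Formula:
        tok = self.peek()
        if tok is None:
            raise CTLSyntaxError("unexpected end of formula", len(self.text))
        if tok == "!":
            self.take()
            return Not(self.unary())
        if tok in _UNARY_OPS:
            self.take()
            return _UNARY_OPS[tok](self.unary())
        if tok in ("E", "A"):
            self.take()
            self.take("[")
            left = self.formula()
            self.take("U")
            right = self.formula()
            self.take("]")
            return EU(left, right) if tok == "E" else AU(left, right)
        if tok == "(":
            self.take()
            node = self.formula()
            self.take(")")
            return node
        if tok == "true":
            self.take()
            return TRUE
        if tok == "false":
            self.take()
            return FALSE
        if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", tok) and tok not in _RESERVED:
            self.take()
            return Atom(tok)
        raise CTLSyntaxError(f"unexpected token {tok!r}", self.pos())


def parse(text: str) -> Formula:
    """Parse a CTL formula string into its AST.

    Raises :class:`~vericlust.errors.CTLSyntaxError` with the character
    position on malformed input.
    """
    parser = _Parser(text)
    if parser.peek() is None:
        raise CTLSyntaxError("empty formula", 0)
    node = parser.formula()
    if parser.peek() is not None:
        raise CTLSyntaxError(
            f"trailing input {parser.peek()!r}", parser.pos())
    return node


# ---------------------------------------------------------------------------
# adequate-set rewriting:  {EX, EU, AF} plus !, &, true
# ---------------------------------------------------------------------------

def to_adequate(f: Formula) -> Formula:
    """Rewrite into the adequate operator set {EX, EU, AF}.

    Boolean connectives are reduced to ``!``/``&``/``true``; the rewrite is
    semantics-preserving and idempotent::

        EF p        ==  E[true U p]
        AX p        ==  !EX !p
        EG p        ==  !AF !p
        AG p        ==  !E[true U !p]
        A[p U q]    ==  !E[!q U (!p & !q)] & AF q
    """
    if isinstance(f, (Atom, TrueF)):
        return f
    if isinstance(f, FalseF):
        return Not(TRUE)
    if isinstance(f, Not):
        return Not(to_adequate(f.operand))
    if isinstance(f, And):
        return And(to_adequate(f.left), to_adequate(f.right))
    if isinstance(f, Or):
        return Not(And(Not(to_adequate(f.left)), Not(to_adequate(f.right))))
    if isinstance(f, Implies):
        return Not(And(to_adequate(f.left), Not(to_adequate(f.right))))
    if isinstance(f, EX):
        return EX(to_adequate(f.operand))
    if isinstance(f, AX):
        return Not(EX(Not(to_adequate(f.operand))))
    if isinstance(f, EF):
        return EU(TRUE, to_adequate(f.operand))
    if isinstance(f, AF):
        return AF(to_adequate(f.operand))
    if isinstance(f, EG):
        return Not(AF(Not(to_adequate(f.operand))))
    if isinstance(f, AG):
        return Not(EU(TRUE, Not(to_adequate(f.operand))))
    if isinstance(f, EU):
        return EU(to_adequate(f.left), to_adequate(f.right))
    if isinstance(f, AU):
        left, right = to_adequate(f.left), to_adequate(f.right)
        return And(
            Not(EU(Not(right), And(Not(left), Not(right)))),
            AF(right),
        )
    raise CTLError(f"unknown formula node: {f!r}")


# ---------------------------------------------------------------------------
# fixpoint labeling model checker
# ---------------------------------------------------------------------------

def sat(ts: TransitionSystem, f: Formula) -> frozenset[str]:
    """Exact satisfaction set of ``f`` over the states of ``ts``.

    Standard labeling algorithm: boolean cases are set operations, EX/AX
    are pre-images, EF/EU least fixpoints by backward reachability, AF/AU
    least fixpoints by successor counting, EG/AG greatest fixpoints by
    duality — all O(|S| + |transitions|) per subformula. Requires a total
    system; unknown atoms raise :class:`~vericlust.errors.CTLError`.
    """
    ts.require_total()
    for name in atoms_of(f):
        if name not in ts.ap:
            raise CTLError(f"unknown atomic proposition: {name!r}")
    pre = ts.predecessors()
    all_states = frozenset(ts.states)
    cache: dict[Formula, frozenset[str]] = {}

    def pre_exists(target: frozenset[str]) -> frozenset[str]:
        out = set()
        for s in target:
            out |= pre[s]
        return frozenset(out)

    def pre_all(target: frozenset[str]) -> frozenset[str]:
        return frozenset(
            s for s in ts.states if ts.transitions[s] <= target)

    # Least fixpoints are evaluated with backward worklists, which touch
    # each transition a bounded number of times (O(|S| + |transitions|)).

    def lfp_exists(phi: frozenset[str], psi: frozenset[str]) -> frozenset[str]:
        """E[phi U psi]: backward reachability of psi through phi."""
        result = set(psi)
        worklist = list(psi)
        while worklist:
            s = worklist.pop()
            for t in pre[s]:
                if t in phi and t not in result:
                    result.add(t)
                    worklist.append(t)
        return frozenset(result)

    def lfp_all(phi: frozenset[str], psi: frozenset[str]) -> frozenset[str]:
        """A[phi U psi] via the successor-counting algorithm."""
        remaining = {s: len(ts.transitions[s]) for s in ts.states}
        result = set(psi)
        worklist = list(psi)
        while worklist:
            s = worklist.pop()
            for t in pre[s]:
                if t in result:
                    continue
                remaining[t] -= 1
                if remaining[t] == 0 and t in phi:
                    result.add(t)
                    worklist.append(t)
        return frozenset(result)

    def rec(node: Formula) -> frozenset[str]:
        if node in cache:
            return cache[node]
        if isinstance(node, TrueF):
            result = all_states
        elif isinstance(node, FalseF):
            result = frozenset()
        elif isinstance(node, Atom):
            result = frozenset(
                s for s in ts.states if node.name in ts.labels[s])
        elif isinstance(node, Not):
            result = all_states - rec(node.operand)
        elif isinstance(node, And):
            result = rec(node.left) & rec(node.right)
        elif isinstance(node, Or):
            result = rec(node.left) | rec(node.right)
        elif isinstance(node, Implies):
            result = (all_states - rec(node.left)) | rec(node.right)
        elif isinstance(node, EX):
            result = pre_exists(rec(node.operand))
        elif isinstance(node, AX):
            result = pre_all(rec(node.operand))
        elif isinstance(node, EF):
            result = lfp_exists(all_states, rec(node.operand))
        elif isinstance(node, AF):
            result = lfp_all(all_states, rec(node.operand))
        elif isinstance(node, EG):
            # greatest fixpoint by duality with the AF least fixpoint
            result = all_states - lfp_all(all_states,
                                          all_states - rec(node.operand))
        elif isinstance(node, AG):
            # complement of backward reachability of the complement
            result = all_states - lfp_exists(all_states,
                                             all_states - rec(node.operand))
        elif isinstance(node, EU):
            result = lfp_exists(rec(node.left), rec(node.right))
        elif isinstance(node, AU):
            result = lfp_all(rec(node.left), rec(node.right))
        else:
            raise CTLError(f"unknown formula node: {node!r}")
        cache[node] = result
        return result

    return rec(f)


def check(ts: TransitionSystem, f: Formula | str) -> bool:
    """True iff every initial state of ``ts`` satisfies ``f``."""
    if isinstance(f, str):
        f = parse(f)
    return ts.initial <= sat(ts, f)


def eval_state(ts: TransitionSystem, f: Formula, state: str) -> bool:
    """Evaluate a purely boolean (state) formula at one state.

    Used for per-state obligations; temporal operators are rejected.
    """
    if isinstance(f, TrueF):
        return True
    if isinstance(f, FalseF):
        return False
    if isinstance(f, Atom):
        if f.name not in ts.ap:
            raise CTLError(f"unknown atomic proposition: {f.name!r}")
        return f.name in ts.labels[state]
    if isinstance(f, Not):
        return not eval_state(ts, f.operand, state)
    if isinstance(f, And):
        return eval_state(ts, f.left, state) and eval_state(ts, f.right, state)
    if isinstance(f, Or):
        return eval_state(ts, f.left, state) or eval_state(ts, f.right, state)
    if isinstance(f, Implies):
        return (not eval_state(ts, f.left, state)
                or eval_state(ts, f.right, state))
    raise CTLError(
        f"obligation must be a boolean state formula, found {type(f).__name__}")
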