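"""Boolean network model and the BoolNet ``.bnet`` text format.

A synchronous Boolean network is a pair ⟨V, F⟩: an ordered list of named
binary nodes and one update rule per node.  At every time step all nodes
update simultaneously, each from the current values of its regulators.  A
*fixed point* (steady state) is a global state mapped to itself by this
synchronous update.

The ``.bnet`` dialect accepted here is the common denominator of the
BoolNet ecosystem: an optional ``targets, factors`` header, one
``name, expression`` line per node, expressions over identifiers, ``!``,
``&``, ``|``, parentheses and the constants ``0``/``1``; ``#`` starts a
comment.  Operator precedence is NOT > AND > OR.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping

from .expr import And, BoolExpr, Const, Not, Or, Var
from .states import PartialState

__all__ = [
    "BooleanNetwork",
    "BnetError",
    "BnetSyntaxError",
    "DuplicateNodeError",
    "UndeclaredNodeError",
    "EmptyNetworkError",
    "parse_bnet",
    "write_bnet",
    "evaluate_rule",
    "global_step",
    "is_fixed_point",
]


class BnetError(ValueError):
    """Base class for ``.bnet`` parse failures; carries the offending line."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class BnetSyntaxError(BnetError):
    pass


class DuplicateNodeError(BnetError):
    pass


class UndeclaredNodeError(BnetError):
    pass


class EmptyNetworkError(BnetError):
    pass


class BooleanNetwork:
    """A synchronous Boolean network ⟨V, F⟩.

    Parameters
    ----------
    nodes:
        Distinct node names in declaration order (fixes vector rendering).
    rules:
        One update rule per declared node.  Every name referenced by any
        rule must itself be declared.
    """

    __slots__ = ("nodes", "rules", "_regulators")

    def __init__(self, nodes: Iterable[str], rules: Mapping[str, BoolExpr]):
        nodes = tuple(nodes)
        if not nodes:
            raise EmptyNetworkError("network must declare at least one node")
        seen: set[str] = set()
        for name in nodes:
            if not name:
                raise ValueError("node names must be non-empty")
            if name in seen:
                raise DuplicateNodeError(f"duplicate node name {name!r}")
            seen.add(name)
        if set(rules) != seen:
            missing = seen - set(rules)
            extra = set(rules) - seen
            raise ValueError(
                f"rules must cover exactly the declared nodes "
                f"(missing: {sorted(missing)}, undeclared: {sorted(extra)})"
            )
        regulators = {}
        for name in nodes:
            refs = rules[name].refs()
            bad = refs - seen
            if bad:
                raise UndeclaredNodeError(
                    f"rule for {name!r} references undeclared node(s) {sorted(bad)}"
                )
            regulators[name] = refs
        self.nodes = nodes
        self.rules = dict(rules)
        self._regulators = regulators

    @property
    def n(self) -> int:
        return len(self.nodes)

    def regulators(self, node: str) -> frozenset[str]:
        """Nodes referenced (syntactically) by ``node``'s update rule."""
        return self._regulators[node]

    def indegree(self, node: str) -> int:
        return len(self._regulators[node])

    @property
    def max_indegree(self) -> int:
        """K, the maximum indegree over all nodes."""
        return max(len(r) for r in self._regulators.values())

    def state(self, bits: Iterable[int]) -> PartialState:
        """Build a global state from a bit vector in declared node order."""
        return PartialState.from_bits(self.nodes, bits)

    def __repr__(self) -> str:
        return f"BooleanNetwork(n={self.n}, K={self.max_indegree})"


# ---------------------------------------------------------------------------
# .bnet parsing

_IDENT = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_TOKEN = re.compile(r"\s*(?:([A-Za-z_][A-Za-z0-9_]*)|([01])|([!&|()]))")


def _tokenize(text: str, line_no: int) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            rest = text[pos:].strip()
            if not rest:
                break
            raise BnetSyntaxError(f"unexpected character {rest[0]!r} in expression", line_no)
        tokens.append(m.group(1) or m.group(2) or m.group(3))
        pos = m.end()
    return tokens


class _ExprParser:
    """Recursive-descent parser for: or := and ('|' and)*; and := not ('&' not)*;
    not := '!' not | '(' or ')' | ident | 0 | 1."""

    def __init__(self, tokens: list[str], line_no: int):
        self.tokens = tokens
        self.pos = 0
        self.line_no = line_no

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise BnetSyntaxError("unexpected end of expression", self.line_no)
        self.pos += 1
        return tok

    def parse(self) -> BoolExpr:
        e = self.parse_or()
        if self.peek() is not None:
            raise BnetSyntaxError(f"trailing token {self.peek()!r}", self.line_no)
        return e

    def parse_or(self) -> BoolExpr:
        parts = [self.parse_and()]
        while self.peek() == "|":
            self.take()
            parts.append(self.parse_and())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_and(self) -> BoolExpr:
        parts = [self.parse_not()]
        while self.peek() == "&":
            self.take()
            parts.append(self.parse_not())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_not(self) -> BoolExpr:
        tok = self.take()
        if tok == "!":
            return Not(self.parse_not())
        if tok == "(":
            e = self.parse_or()
            if self.take() != ")":
                raise BnetSyntaxError("expected ')'", self.line_no)
            return e
        if tok in ("0", "1"):
            return Const(int(tok))
        if _IDENT.fullmatch(tok):
            return Var(tok)
        raise BnetSyntaxError(f"unexpected token {tok!r}", self.line_no)


def parse_expression(text: str, line_no: int | None = None) -> BoolExpr:
    """Parse a single rule expression in the ``.bnet`` dialect."""
    tokens = _tokenize(text, line_no or 0)
    if not tokens:
        raise BnetSyntaxError("empty expression", line_no or 0)
    return _ExprParser(tokens, line_no or 0).parse()


def parse_bnet(text: str) -> BooleanNetwork:
    """Parse a network from ``.bnet`` text.

    Node order follows line order.  Raises a :class:`BnetError` subclass
    naming the offending line on duplicate names, undeclared references,
    empty input or malformed expressions.
    """
    nodes: list[str] = []
    rules: dict[str, BoolExpr] = {}
    lines_seen: dict[str, int] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "," not in line:
            raise BnetSyntaxError("expected 'name, expression'", line_no)
        name, _, rhs = line.partition(",")
        name = name.strip()
        if name.lower() == "targets" and rhs.strip().lower() == "factors":
            continue  # header
        if not _IDENT.fullmatch(name):
            raise BnetSyntaxError(f"invalid node name {name!r}", line_no)
        if name in lines_seen:
            raise DuplicateNodeError(
                f"node {name!r} already declared on line {lines_seen[name]}", line_no
            )
        lines_seen[name] = line_no
        nodes.append(name)
        rules[name] = parse_expression(rhs, line_no)
    if not nodes:
        raise EmptyNetworkError("no rules found in input")
    declared = set(nodes)
    for name in nodes:
        bad = rules[name].refs() - declared
        if bad:
            raise UndeclaredNodeError(
                f"rule for {name!r} references undeclared node(s) {sorted(bad)}",
                lines_seen[name],
            )
    return BooleanNetwork(nodes, rules)


def write_bnet(net: BooleanNetwork) -> str:
    """Serialise to ``.bnet`` text (reparses to a semantically equal network)."""
    lines = ["targets, factors"]
    for name in net.nodes:
        lines.append(f"{name}, {net.rules[name].to_bnet()}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# dynamics

def evaluate_rule(expr: BoolExpr, assignment: Mapping[str, int]) -> int:
    """Value of a rule under an assignment covering its referenced nodes."""
    return expr.evaluate(assignment)


def global_step(net: BooleanNetwork, state: PartialState) -> PartialState:
    """One synchronous update: every node recomputed from the current state."""
    return PartialState(
        {v: net.rules[v].evaluate(state) for v in net.nodes}, order=net.nodes
    )


def is_fixed_point(net: BooleanNetwork, state: PartialState) -> bool:
    """True iff the state is a steady state of the synchronous dynamics."""
    return all(net.rules[v].evaluate(state) == state[v] for v in net.nodes)
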