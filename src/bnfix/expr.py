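"""Boolean update-rule expression trees.

A rule is a recursive expression over node names, the constants 0/1 and the
connectives NOT, AND, OR, XOR and IFF (logical equivalence).  The ``.bnet``
text dialect only knows ``!``, ``&``, ``|`` — XOR and IFF are available for
programmatic construction and are expanded into the core operators when a
rule is serialised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = ["BoolExpr", "Var", "Const", "Not", "And", "Or", "Xor", "Iff"]


class BoolExpr:
    """Base class for rule expressions."""

    __slots__ = ()

    def refs(self) -> frozenset[str]:
        """Names of all nodes referenced (syntactically) by this expression."""
        raise NotImplementedError

    def evaluate(self, assignment: Mapping[str, int]) -> int:
        """Value in {0, 1} under a total assignment of the referenced nodes."""
        raise NotImplementedError

    def to_bnet(self) -> str:
        """Serialise using only ``!``, ``&``, ``|`` and parentheses."""
        return self._render(0)

    def _render(self, prec: int) -> str:
        raise NotImplementedError

    # convenience operators for building rules in code
    def __and__(self, other: "BoolExpr") -> "BoolExpr":
        return And((self, other))

    def __or__(self, other: "BoolExpr") -> "BoolExpr":
        return Or((self, other))

    def __invert__(self) -> "BoolExpr":
        return Not(self)


# rendering precedence: OR < AND < NOT/atom
_P_OR, _P_AND, _P_NOT = 1, 2, 3


def _paren(s: str, inner: int, outer: int) -> str:
    return f"({s})" if inner < outer else s


@dataclass(frozen=True, slots=True)
class Var(BoolExpr):
    name: str

    def refs(self) -> frozenset[str]:
        return frozenset((self.name,))

    def evaluate(self, assignment: Mapping[str, int]) -> int:
        try:
            return 1 if assignment[self.name] else 0
        except KeyError:
            raise KeyError(
                f"assignment does not define referenced node {self.name!r}"
            ) from None

    def _render(self, prec: int) -> str:
        return self.name


@dataclass(frozen=True, slots=True)
class Const(BoolExpr):
    value: int

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError(f"constant must be 0 or 1, got {self.value!r}")

    def refs(self) -> frozenset[str]:
        return frozenset()

    def evaluate(self, assignment: Mapping[str, int]) -> int:
        return self.value

    def _render(self, prec: int) -> str:
        return str(self.value)


@dataclass(frozen=True, slots=True)
class Not(BoolExpr):
    child: BoolExpr

    def refs(self) -> frozenset[str]:
        return self.child.refs()

    def evaluate(self, assignment: Mapping[str, int]) -> int:
        return 1 - self.child.evaluate(assignment)

    def _render(self, prec: int) -> str:
        return "!" + _paren(self.child._render(_P_NOT), _P_NOT, _P_NOT) \
            if isinstance(self.child, (Var, Const, Not)) \
            else "!(" + self.child._render(0) + ")"


@dataclass(frozen=True, slots=True)
class And(BoolExpr):
    children: tuple[BoolExpr, ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise ValueError("AND needs at least one operand")

    def refs(self) -> frozenset[str]:
        return frozenset().union(*(c.refs() for c in self.children))

    def evaluate(self, assignment: Mapping[str, int]) -> int:
        return 1 if all(c.evaluate(assignment) for c in self.children) else 0

    def _render(self, prec: int) -> str:
        s = " & ".join(c._render(_P_AND) for c in self.children)
        return _paren(s, _P_AND, prec)


@dataclass(frozen=True, slots=True)
class Or(BoolExpr):
    children: tuple[BoolExpr, ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise ValueError("OR needs at least one operand")

    def refs(self) -> frozenset[str]:
        return frozenset().union(*(c.refs() for c in self.children))

    def evaluate(self, assignment: Mapping[str, int]) -> int:
        return 1 if any(c.evaluate(assignment) for c in self.children) else 0

    def _render(self, prec: int) -> str:
        s = " | ".join(c._render(_P_OR) for c in self.children)
        return _paren(s, _P_OR, prec)


@dataclass(frozen=True, slots=True)
class Xor(BoolExpr):
    a: BoolExpr
    b: BoolExpr

    def refs(self) -> frozenset[str]:
        return self.a.refs() | self.b.refs()

    def evaluate(self, assignment: Mapping[str, int]) -> int:
        return self.a.evaluate(assignment) ^ self.b.evaluate(assignment)

    def _expand(self) -> BoolExpr:
        return Or((And((self.a, Not(self.b))), And((Not(self.a), self.b))))

    def _render(self, prec: int) -> str:
        return self._expand()._render(prec)


@dataclass(frozen=True, slots=True)
class Iff(BoolExpr):
    """Logical equivalence: 1 iff both operands agree."""

    a: BoolExpr
    b: BoolExpr

    def refs(self) -> frozenset[str]:
        return self.a.refs() | self.b.refs()

    def evaluate(self, assignment: Mapping[str, int]) -> int:
        return 1 if self.a.evaluate(assignment) == self.b.evaluate(assignment) else 0

    def _expand(self) -> BoolExpr:
        return Or((And((self.a, self.b)), And((Not(self.a), Not(self.b)))))

    def _render(self, prec: int) -> str:
        return self._expand()._render(prec)
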