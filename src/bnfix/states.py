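"""Partial and global network states.

A :class:`PartialState` is an immutable 0/1 assignment over an explicit
domain of named nodes, together with a *stated order* used whenever the
assignment is rendered as a vector.  Equality and hashing compare the
name→value mapping only, so two states over the same nodes are equal even
if their stated orders differ — vectors are a presentation, the assignment
is the datum.  A global state is simply a partial state whose domain is the
whole node set, ordered by the network's declared node order.
"""

from __future__ import annotations

from collections.abc import Mapping
from typing import Iterable, Iterator

__all__ = ["PartialState"]


class PartialState(Mapping):
    """Immutable assignment of 0/1 values to a set of named nodes."""

    __slots__ = ("_map", "_order", "_hash")

    def __init__(
        self,
        assignment: Mapping[str, int] | Iterable[tuple[str, int]],
        order: Iterable[str] | None = None,
    ) -> None:
        m = {k: (1 if v else 0) for k, v in
             (assignment.items() if isinstance(assignment, Mapping) else assignment)}
        if order is None:
            o = tuple(m)
        else:
            o = tuple(order)
            if len(o) != len(m) or set(o) != set(m):
                raise ValueError("order must be a permutation of the assigned nodes")
        object.__setattr__(self, "_map", m)
        object.__setattr__(self, "_order", o)
        object.__setattr__(self, "_hash", None)

    @classmethod
    def from_bits(cls, order: Iterable[str], bits: Iterable[int]) -> "PartialState":
        o = tuple(order)
        b = tuple(bits)
        if len(o) != len(b):
            raise ValueError("order and bits must have equal length")
        return cls(zip(o, b), order=o)

    # -- mapping protocol -------------------------------------------------
    def __getitem__(self, name: str) -> int:
        return self._map[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._order)

    def __len__(self) -> int:
        return len(self._map)

    # -- identity ---------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if isinstance(other, PartialState):
            return self._map == other._map
        if isinstance(other, Mapping):
            return dict(self._map) == dict(other)
        return NotImplemented

    def __hash__(self) -> int:
        h = self._hash
        if h is None:
            h = hash(frozenset(self._map.items()))
            object.__setattr__(self, "_hash", h)
        return h

    def __setattr__(self, name: str, value: object) -> None:
        raise AttributeError("PartialState is immutable")

    # -- views ------------------------------------------------------------
    @property
    def domain(self) -> frozenset[str]:
        return frozenset(self._map)

    @property
    def order(self) -> tuple[str, ...]:
        """The stated node order used for vector rendering."""
        return self._order

    def vector(self, order: Iterable[str] | None = None) -> tuple[int, ...]:
        o = self._order if order is None else tuple(order)
        return tuple(self._map[name] for name in o)

    def bitstring(self, order: Iterable[str] | None = None) -> str:
        return "".join(str(b) for b in self.vector(order))

    def restrict(
        self, targets: Iterable[str], order: Iterable[str] | None = None
    ) -> "PartialState":
        """Subvector over ``targets`` (the SV operator).

        ``order`` fixes the rendering order of the result; by default the
        targets keep their relative order in this state's stated order.
        """
        t = set(targets)
        bad = t - self._map.keys()
        if bad:
            raise KeyError(f"targets outside state domain: {sorted(bad)}")
        o = tuple(n for n in self._order if n in t) if order is None else tuple(order)
        return PartialState({n: self._map[n] for n in t}, order=o)

    def __repr__(self) -> str:
        body = ", ".join(f"{n}={self._map[n]}" for n in self._order)
        return f"PartialState({body})"
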