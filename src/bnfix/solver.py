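"""Local steady-state enumeration for a subnetwork.

A local steady state is an assignment over the subnetwork's scope in
which every owned node equals its rule's output; control nodes are free
inputs.  The fixed-point condition of a node with k regulators is the
constraint v ↔ f(regulators), whose truth-table CNF has clauses of width
at most k+1 — so a network with maximum indegree K yields a (K+1)-SAT
instance, and under the single-node (MEB) partition each instance is as
small as the condition can be stated.

Two enumeration paths with an identical contract are provided: the
all-solutions SAT path used by the pipeline, and an exhaustive
enumerator over the 2^|scope| assignments that serves as its oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from . import _sat
from .partition import Subnetwork
from .states import PartialState

__all__ = [
    "CnfFormula",
    "ScopeTooLargeError",
    "encode_cnf",
    "local_fixed_points_sat",
    "local_fixed_points_bruteforce",
    "to_dimacs",
]

DEFAULT_REGULATOR_CAP = 16
DEFAULT_BRUTEFORCE_CAP = 22


class ScopeTooLargeError(RuntimeError):
    """Raised when an encoding or enumeration cap would be exceeded."""


@dataclass(frozen=True)
class CnfFormula:
    """CNF over one variable per scope node (1-based, in scope order).

    The models, projected onto the scope variables, are exactly the local
    steady states of the subnetwork it encodes.
    """

    variables: tuple[str, ...]
    clauses: tuple[tuple[int, ...], ...]

    @property
    def num_vars(self) -> int:
        return len(self.variables)

    def var(self, name: str) -> int:
        return self.variables.index(name) + 1


def encode_cnf(
    sub: Subnetwork, max_regulators: int = DEFAULT_REGULATOR_CAP
) -> CnfFormula:
    """Truth-table CNF of the fixed-point constraints of a subnetwork.

    For each owned node v with rule f over regulators R, one clause is
    emitted per total assignment of R ∪ {v} that falsifies v ↔ f(R)
    (width ≤ |R|+1).  Control nodes occur only as free variables.
    """
    variables = sub.scope_order
    index = {name: i + 1 for i, name in enumerate(variables)}
    clauses: list[tuple[int, ...]] = []
    for v in sorted(sub.block, key=variables.index):
        rule = sub.rules[v]
        regs = sorted(rule.refs(), key=variables.index)
        if len(regs) > max_regulators:
            raise ScopeTooLargeError(
                f"rule for {v!r} has {len(regs)} regulators; "
                f"truth-table expansion capped at {max_regulators}"
            )
        local = regs if v in regs else regs + [v]
        for bits in product((0, 1), repeat=len(local)):
            row = dict(zip(local, bits))
            if rule.evaluate(row) != row[v]:
                clauses.append(
                    tuple(-index[n] if row[n] else index[n] for n in local)
                )
    return CnfFormula(variables, tuple(clauses))


def _sorted_states(states: set[PartialState], order: tuple[str, ...]) -> list[PartialState]:
    return sorted(states, key=lambda s: s.vector(order))


def local_fixed_points_sat(
    sub: Subnetwork, max_regulators: int = DEFAULT_REGULATOR_CAP
) -> list[PartialState]:
    """All local steady states, by all-solutions SAT with blocking clauses.

    Returned sorted lexicographically by the scope-order bit vector.
    """
    cnf = encode_cnf(sub, max_regulators=max_regulators)
    models = _sat.enumerate_models(cnf.num_vars, cnf.clauses)
    states = {
        PartialState.from_bits(
            cnf.variables, (1 if m[i + 1] else 0 for i in range(cnf.num_vars))
        )
        for m in models
    }
    return _sorted_states(states, sub.scope_order)


def local_fixed_points_bruteforce(
    sub: Subnetwork, cap: int = DEFAULT_BRUTEFORCE_CAP
) -> list[PartialState]:
    """All local steady states by exhaustive scan of 2^|scope| assignments.

    Identical contract to :func:`local_fixed_points_sat`; serves as its
    independent oracle.
    """
    order = sub.scope_order
    if len(order) > cap:
        raise ScopeTooLargeError(
            f"scope of size {len(order)} exceeds brute-force cap {cap}"
        )
    out: set[PartialState] = set()
    rules = [(v, sub.rules[v]) for v in sub.block]
    for bits in product((0, 1), repeat=len(order)):
        assignment = dict(zip(order, bits))
        if all(rule.evaluate(assignment) == assignment[v] for v, rule in rules):
            out.add(PartialState(assignment, order=order))
    return _sorted_states(out, order)


def to_dimacs(cnf: CnfFormula) -> str:
    """DIMACS CNF text with variable-name comments (debug/interop)."""
    lines = [f"c vars: {' '.join(cnf.variables)}",
             f"p cnf {cnf.num_vars} {len(cnf.clauses)}"]
    lines += [" ".join(map(str, c)) + " 0" for c in cnf.clauses]
    return "\n".join(lines) + "\n"
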