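"""A compact DPLL SAT solver with all-solutions enumeration.

Variables are positive integers 1..num_vars; a literal is a signed
integer; a clause is a sequence of literals.  The solver does unit
propagation with chronological backtracking and always returns *total*
models (free variables are branched, not defaulted), which is what the
blocking-clause all-SAT loop requires.  Formulas produced by the
fixed-point encoding are tiny — clause width is bounded by the node
indegree plus one — so no watched-literal machinery is needed.
"""

from __future__ import annotations

from typing import Iterable, Sequence

__all__ = ["solve", "enumerate_models"]


def _simplify(
    clauses: list[tuple[int, ...]], lit: int
) -> list[tuple[int, ...]] | None:
    """Assert ``lit``: drop satisfied clauses, shorten the rest.

    Returns None on conflict (an empty clause was produced).
    """
    out: list[tuple[int, ...]] = []
    for c in clauses:
        if lit in c:
            continue
        if -lit in c:
            c = tuple(x for x in c if x != -lit)
            if not c:
                return None
        out.append(c)
    return out


def _dpll(
    clauses: list[tuple[int, ...]], assign: dict[int, bool], num_vars: int
) -> dict[int, bool] | None:
    # unit propagation
    while True:
        unit = next((c[0] for c in clauses if len(c) == 1), None)
        if unit is None:
            break
        assign[abs(unit)] = unit > 0
        simplified = _simplify(clauses, unit)
        if simplified is None:
            return None
        clauses = simplified
    if len(assign) == num_vars:
        return assign
    # branch: prefer a variable from a shortest clause, else any free one
    if clauses:
        var = abs(min(clauses, key=len)[0])
    else:
        var = next(v for v in range(1, num_vars + 1) if v not in assign)
    for value in (False, True):
        lit = var if value else -var
        simplified = _simplify(clauses, lit)
        if simplified is None:
            continue
        branch = dict(assign)
        branch[var] = value
        result = _dpll(simplified, branch, num_vars)
        if result is not None:
            return result
    return None


def solve(
    num_vars: int, clauses: Iterable[Sequence[int]]
) -> dict[int, bool] | None:
    """Return one total model (var → bool), or None if unsatisfiable."""
    cls = [tuple(c) for c in clauses]
    if any(not c for c in cls):
        return None
    return _dpll(cls, {}, num_vars)


def enumerate_models(
    num_vars: int,
    clauses: Iterable[Sequence[int]],
    project: Sequence[int] | None = None,
) -> list[dict[int, bool]]:
    """All models, projected onto ``project`` (default: all variables).

    Iterates solve → record projection → add a blocking clause over the
    projection literals → resolve, until unsatisfiable.  Projection keeps
    the enumeration free of duplicates should the formula ever contain
    auxiliary variables.
    """
    if project is None:
        project = list(range(1, num_vars + 1))
    cls = [tuple(c) for c in clauses]
    models: list[dict[int, bool]] = []
    while True:
        m = solve(num_vars, cls)
        if m is None:
            return models
        proj = {v: m[v] for v in project}
        models.append(proj)
        cls.append(tuple(-v if proj[v] else v for v in project))
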