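"""Composing local steady states into global fixed points.

Two partial states can be composed when they agree on their common
nodes; the composition is their union.  Joining the local steady-state
sets of all subnetworks of a partition, in any order, yields exactly the
global fixed points — but the *order* controls how many intermediate
composed states are built and later discarded.  The greedy heuristic
implemented here seeds with the largest-scope subnetwork and repeatedly
appends the subnetwork sharing the most nodes with the accumulated
scope, which tends to filter incompatible combinations early.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .partition import Subnetwork
from .states import PartialState

__all__ = [
    "restrict",
    "compose_pair",
    "join_sets",
    "determine_order",
    "frontier_order",
    "attractor_composition",
    "JoinStep",
    "IntermediateCapExceeded",
]

DEFAULT_INTERMEDIATE_CAP = 10**6


class IntermediateCapExceeded(RuntimeError):
    """An intermediate composed set grew past the configured cap."""


def restrict(
    state: PartialState, targets: Iterable[str], order: Iterable[str] | None = None
) -> PartialState:
    """The subvector of ``state`` over ``targets`` (the SV operator)."""
    return state.restrict(targets, order=order)


def compose_pair(a1: PartialState, a2: PartialState) -> PartialState | None:
    """Compose two partial states, or return None if they disagree.

    When the states agree on their common nodes the result assigns
    a1's values plus a2's values on a2-only nodes (domain union);
    disjoint domains compose unconditionally.
    """
    m1, m2 = dict(a1.items()), dict(a2.items())
    for name in m1.keys() & m2.keys():
        if m1[name] != m2[name]:
            return None
    merged = m1 | m2
    order = a1.order + tuple(n for n in a2.order if n not in m1)
    return PartialState(merged, order=order)


def join_sets(
    left: Iterable[PartialState], right: Iterable[PartialState]
) -> list[PartialState]:
    """All pairwise compatible compositions of two sets of states.

    All states in each input must share one domain.  Implemented as a
    hash join keyed on the restriction to the common nodes; the output
    equals the quadratic double loop over all pairs.
    """
    left, right = list(left), list(right)
    if not left or not right:
        return []
    common = tuple(sorted(left[0].domain & right[0].domain))
    buckets: dict[tuple[int, ...], list[PartialState]] = defaultdict(list)
    for b in right:
        buckets[b.vector(common)].append(b)
    out: list[PartialState] = []
    for a in left:
        for b in buckets.get(a.vector(common), ()):
            merged = compose_pair(a, b)
            assert merged is not None  # keyed on the common restriction
            out.append(merged)
    return out


def determine_order(subs: Sequence[Subnetwork]) -> tuple[int, ...]:
    """Greedy composition order over subnetwork positions (0-based).

    Seed with the largest scope (ties to the smallest position), then
    repeatedly append the unplaced subnetwork whose scope overlaps the
    accumulated scope the most.  Overlap ties go to the candidate adding
    the fewest new scope nodes, then to the smallest position: the size
    of an intermediate composed set is governed by how many scope nodes
    are not yet owned, so among equally overlapping candidates the one
    that grows the scope least keeps intermediates smallest.  With zero
    overlap everywhere (disconnected network) this appends the smallest
    remaining subnetwork and the join degenerates to a product.
    """
    if not subs:
        raise ValueError("need at least one subnetwork")
    scopes = [s.scope for s in subs]
    begin = max(range(len(subs)), key=lambda i: (len(scopes[i]), -i))
    order = [begin]
    current = set(scopes[begin])
    remaining = set(range(len(subs))) - {begin}
    while remaining:
        nxt = max(
            remaining,
            key=lambda i: (len(current & scopes[i]), -len(scopes[i] - current), -i),
        )
        order.append(nxt)
        current |= scopes[nxt]
        remaining.discard(nxt)
    return tuple(order)


def frontier_order(subs: Sequence[Subnetwork]) -> tuple[int, ...]:
    """Frontier-minimising greedy order (robust fallback).

    Same largest-scope seed as :func:`determine_order`, but each step
    appends the subnetwork adding the *fewest* new scope nodes (ties:
    most overlap, then smallest position).  Since an intermediate set
    can hold up to one state per assignment of the unowned scope nodes,
    keeping that frontier narrow bounds intermediate growth far more
    aggressively than maximising overlap; the final composed set is the
    same for every order.
    """
    if not subs:
        raise ValueError("need at least one subnetwork")
    scopes = [s.scope for s in subs]
    begin = max(range(len(subs)), key=lambda i: (len(scopes[i]), -i))
    order = [begin]
    current = set(scopes[begin])
    remaining = set(range(len(subs))) - {begin}
    while remaining:
        nxt = max(
            remaining,
            key=lambda i: (-len(scopes[i] - current), len(current & scopes[i]), -i),
        )
        order.append(nxt)
        current |= scopes[nxt]
        remaining.discard(nxt)
    return tuple(order)


@dataclass(frozen=True)
class JoinStep:
    """Bookkeeping for one join during composition (redundancy audit).

    ``discarded_left`` counts accumulated states that found no compatible
    partner — work done earlier that this step throws away.
    """

    sub_index: int
    common: tuple[str, ...]
    left_size: int
    right_size: int
    out_size: int
    discarded_left: int


def attractor_composition(
    subs: Sequence[Subnetwork],
    local_sets: Sequence[Iterable[PartialState]],
    order: Sequence[int],
    *,
    cap: int | None = DEFAULT_INTERMEDIATE_CAP,
    trace: list[JoinStep] | None = None,
) -> list[PartialState]:
    """Left-fold join of the local steady-state sets along ``order``.

    Returns the composed states over the union of all scopes (the global
    fixed points when the subnetworks come from a partition of the whole
    network), sorted by bit vector over the accumulated scope order.
    ``trace`` (if given) receives one :class:`JoinStep` per join.
    """
    if sorted(order) != list(range(len(subs))):
        raise ValueError("order must be a permutation of subnetwork positions")
    if len(local_sets) != len(subs):
        raise ValueError("local_sets must align with subs")
    # internal fast path: states as packed byte strings aligned to the
    # accumulated scope order (one byte per node); PartialState objects
    # are materialised only at the end.  The cap is enforced inside the
    # join loop so a blowing-up join aborts before exhausting memory.
    seed = order[0]
    acc_order = list(subs[seed].scope_order)
    acc_pos = {n: j for j, n in enumerate(acc_order)}
    acc = [bytes(s.vector(acc_order)) for s in local_sets[seed]]
    for i in order[1:]:
        r_order = subs[i].scope_order
        right = [bytes(s.vector(r_order)) for s in local_sets[i]]
        common = tuple(sorted(acc_pos.keys() & subs[i].scope))
        li = tuple(acc_pos[n] for n in common)
        r_pos = {n: j for j, n in enumerate(r_order)}
        ri = tuple(r_pos[n] for n in common)
        new_names = [n for n in r_order if n not in acc_pos]
        ni = tuple(r_pos[n] for n in new_names)
        buckets: dict[bytes, list[bytes]] = defaultdict(list)
        for b in right:
            buckets[bytes(b[j] for j in ri)].append(bytes(b[j] for j in ni))
        out: list[bytes] = []
        discarded = 0
        for a in acc:
            partners = buckets.get(bytes(a[j] for j in li))
            if partners:
                out.extend(a + tail for tail in partners)
                if cap is not None and len(out) > cap:
                    if trace is not None:
                        trace.append(
                            JoinStep(i, common, len(acc), len(right),
                                     len(out), discarded)
                        )
                    raise IntermediateCapExceeded(
                        f"intermediate composed set exceeded the cap of {cap} "
                        f"states while joining subnetwork {i}"
                    )
            else:
                discarded += 1
        if trace is not None:
            trace.append(
                JoinStep(i, common, len(acc), len(right), len(out), discarded)
            )
        acc = out
        for n in new_names:
            acc_pos[n] = len(acc_order)
            acc_order.append(n)
        if not acc:
            break
    full_order = tuple(acc_order)
    uniq = dict.fromkeys(acc)  # joins of consistent sets cannot duplicate, but be safe
    # canonical output ordering, independent of the join order taken
    canon = sorted(range(len(full_order)), key=lambda j: full_order[j])
    return [
        PartialState.from_bits(full_order, bits)
        for bits in sorted(uniq, key=lambda b: bytes(b[j] for j in canon))
    ]
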