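"""End-to-end fixed-point detection and the exhaustive whole-network oracle.

The pipeline is: partition the network (MEB by default — one block per
node), enumerate each subnetwork's local steady states (all-solutions
SAT by default), pick a composition order (greedy overlap heuristic by
default), then join the local sets along that order.  The result is
exactly the set of global fixed points of the synchronous dynamics; the
exhaustive 2^n scan is kept as an independent oracle for small networks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

from .compose import (
    IntermediateCapExceeded,
    JoinStep,
    attractor_composition,
    determine_order,
    frontier_order,
)
from .model import BooleanNetwork, is_fixed_point
from .partition import Subnetwork, meb_partition, partition_from_blocks
from .solver import (
    ScopeTooLargeError,
    local_fixed_points_bruteforce,
    local_fixed_points_sat,
)
from .states import PartialState

__all__ = [
    "RunOptions",
    "find_fixed_points",
    "enumerate_fixed_points_oracle",
    "format_tsv",
    "format_json",
]

logger = logging.getLogger("bnfix")

DEFAULT_ORACLE_CAP = 20


@dataclass
class RunOptions:
    """Knobs of the detection pipeline.

    solver: "sat" or "bruteforce" (identical contract, SAT is the fast
    path).  order: "heuristic" (overlap-greedy with automatic fallback
    to the frontier-minimising order if the cap trips), "frontier",
    "index", or an explicit permutation of subnetwork positions.
    partition: "meb" or an explicit list of blocks.  cap bounds the size
    any intermediate composed set may reach before the run aborts with a
    diagnostic.
    """

    solver: str = "sat"
    order: str | Sequence[int] = "heuristic"
    partition: str | Sequence[Iterable[str]] = "meb"
    fmt: str = "tsv"
    cap: int = 10**6
    verbose: bool = False
    debug_check: bool = False
    trace: list[JoinStep] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.solver not in ("sat", "bruteforce"):
            raise ValueError(f"unknown solver {self.solver!r}")
        if isinstance(self.order, str) and self.order not in (
            "heuristic", "frontier", "index",
        ):
            raise ValueError(f"unknown order {self.order!r}")
        if isinstance(self.partition, str) and self.partition != "meb":
            raise ValueError(f"unknown partition {self.partition!r}")
        if self.cap < 1:
            raise ValueError("cap must be >= 1")
        if self.fmt not in ("tsv", "json"):
            raise ValueError(f"unknown output format {self.fmt!r}")


def _subnetworks(net: BooleanNetwork, opts: RunOptions) -> list[Subnetwork]:
    if isinstance(opts.partition, str):
        return meb_partition(net)
    return partition_from_blocks(net, [set(b) for b in opts.partition])


def find_fixed_points(
    net: BooleanNetwork, opts: RunOptions | None = None
) -> list[PartialState]:
    """All global fixed points, sorted by bit vector in declared node order.

    Sound and complete: every returned state satisfies F(S) = S and no
    fixed point is missed (the per-subnetwork local sets are exhaustive
    and the join preserves exactly the mutually consistent combinations).
    """
    opts = opts or RunOptions()
    subs = _subnetworks(net, opts)
    solve = local_fixed_points_sat if opts.solver == "sat" else local_fixed_points_bruteforce
    local_sets = []
    for sub in subs:
        states = solve(sub)
        local_sets.append(states)
        if opts.verbose:
            logger.info(
                "subnetwork %d: block=%s controls=%s -> %d local steady states",
                sub.index, sorted(sub.block), sorted(sub.controls), len(states),
            )
    if isinstance(opts.order, str):
        if opts.order == "heuristic":
            order = determine_order(subs)
        elif opts.order == "frontier":
            order = frontier_order(subs)
        else:
            order = tuple(range(len(subs)))
    else:
        order = tuple(opts.order)
    trace: list[JoinStep] = []
    try:
        result = attractor_composition(
            subs, local_sets, order, cap=opts.cap, trace=trace
        )
    except IntermediateCapExceeded:
        if opts.order != "heuristic":
            raise
        # the overlap-greedy order let an intermediate set blow up; the
        # final set is order-independent, so retry with the
        # frontier-minimising order before giving up
        logger.warning(
            "intermediate cap hit with the overlap-greedy order; "
            "retrying with the frontier-minimising order"
        )
        trace = []
        result = attractor_composition(
            subs, local_sets, frontier_order(subs), cap=opts.cap, trace=trace
        )
    opts.trace = trace
    if opts.verbose:
        for step in trace:
            logger.info(
                "join sub %d: |common|=%d, %d x %d -> %d (%d discarded)",
                step.sub_index, len(step.common), step.left_size,
                step.right_size, step.out_size, step.discarded_left,
            )
    if result and result[0].domain != set(net.nodes):
        raise ValueError("composition did not cover the full node set; invalid partition")
    fixed = [PartialState(s, order=net.nodes) for s in result]
    if opts.debug_check:
        assert all(is_fixed_point(net, s) for s in fixed)
    return sorted(fixed, key=lambda s: s.vector(net.nodes))


def enumerate_fixed_points_oracle(
    net: BooleanNetwork, cap: int = DEFAULT_ORACLE_CAP
) -> list[PartialState]:
    """Scan all 2^n global states and return those with F(S) = S."""
    if net.n > cap:
        raise ScopeTooLargeError(f"n={net.n} exceeds exhaustive-scan cap {cap}")
    out = []
    rules = [(v, net.rules[v]) for v in net.nodes]
    for bits in product((0, 1), repeat=net.n):
        s = dict(zip(net.nodes, bits))
        if all(rule.evaluate(s) == s[v] for v, rule in rules):
            out.append(PartialState(s, order=net.nodes))
    return out


def format_tsv(net: BooleanNetwork, states: Iterable[PartialState]) -> str:
    """Header = node names in declared order; one sorted 0/1 row per state."""
    rows = sorted(s.vector(net.nodes) for s in states)
    lines = ["\t".join(net.nodes)]
    lines += ["\t".join(map(str, row)) for row in rows]
    return "\n".join(lines) + "\n"


def format_json(net: BooleanNetwork, states: Iterable[PartialState]) -> str:
    """JSON list of name→value maps, sorted like the TSV rows."""
    rows = sorted(states, key=lambda s: s.vector(net.nodes))
    return json.dumps(
        [{name: s[name] for name in net.nodes} for s in rows], indent=2
    ) + "\n"
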