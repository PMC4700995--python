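"""Network partitioning into subnetworks.

A partition splits the node set V into disjoint blocks.  Each block V_i
induces a subnetwork G_i = ⟨V_i ∪ C_i, F_i⟩ where the *control set* C_i
collects every regulator of a block member that lies outside the block;
controls are treated as free inputs (their own rules are ignored inside
the subnetwork).  The minimum-essential-block (MEB) partition puts every
node in its own block, so each subnetwork consists of one node plus its
regulators — the smallest scope on which that node's fixed-point
constraint can be stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .expr import BoolExpr
from .model import BooleanNetwork

__all__ = [
    "Subnetwork",
    "PartitionReport",
    "make_subnetwork",
    "meb_partition",
    "validate_partition",
    "parse_partition_file",
]


@dataclass(frozen=True)
class Subnetwork:
    """One block of a partition with its induced local model.

    ``block`` holds the owned nodes (whose rules constrain the local
    steady states), ``controls`` the free input nodes, and ``scope_order``
    a canonical rendering order for local state vectors: scope members in
    the parent network's declared node order.
    """

    index: int
    block: frozenset[str]
    controls: frozenset[str]
    rules: Mapping[str, BoolExpr]
    scope_order: tuple[str, ...]

    @property
    def scope(self) -> frozenset[str]:
        return self.block | self.controls

    def __repr__(self) -> str:
        return (
            f"Subnetwork({self.index}, block={sorted(self.block)}, "
            f"controls={sorted(self.controls)})"
        )


def make_subnetwork(
    net: BooleanNetwork, block: Iterable[str], index: int = 0
) -> Subnetwork:
    """Construct the subnetwork induced by a block of nodes.

    Controls are the regulators of block members that fall outside the
    block; a self-regulating block member is not a control of itself.
    """
    block = frozenset(block)
    if not block:
        raise ValueError("block must be non-empty")
    unknown = block - set(net.nodes)
    if unknown:
        raise ValueError(f"block contains unknown node(s): {sorted(unknown)}")
    controls = frozenset().union(*(net.regulators(v) for v in block)) - block
    scope = block | controls
    scope_order = tuple(v for v in net.nodes if v in scope)
    rules = {v: net.rules[v] for v in block}
    return Subnetwork(index, block, controls, rules, scope_order)


def meb_partition(net: BooleanNetwork) -> list[Subnetwork]:
    """The minimum-essential-block partition: one subnetwork per node.

    Subnetwork i owns node v_i with controls = regulators(v_i) \\ {v_i};
    its scope therefore has at most indegree(v_i) + 1 members.
    """
    return [make_subnetwork(net, {v}, i) for i, v in enumerate(net.nodes)]


def partition_from_blocks(
    net: BooleanNetwork, blocks: Sequence[Iterable[str]]
) -> list[Subnetwork]:
    """Build subnetworks for a user-supplied partition (validated first)."""
    report = validate_partition(net, blocks)
    if not report.ok:
        raise ValueError(f"invalid partition: {report.summary()}")
    return [make_subnetwork(net, b, i) for i, b in enumerate(blocks)]


@dataclass
class PartitionReport:
    """Outcome of checking that blocks disjointly cover the node set."""

    ok: bool
    missing: list[str] = field(default_factory=list)
    duplicated: list[str] = field(default_factory=list)
    unknown: list[str] = field(default_factory=list)
    empty_blocks: list[int] = field(default_factory=list)

    def summary(self) -> str:
        if self.ok:
            return "ok"
        parts = []
        if self.missing:
            parts.append(f"missing nodes: {self.missing}")
        if self.duplicated:
            parts.append(f"duplicated nodes: {self.duplicated}")
        if self.unknown:
            parts.append(f"unknown nodes: {self.unknown}")
        if self.empty_blocks:
            parts.append(f"empty blocks at positions: {self.empty_blocks}")
        return "; ".join(parts)


def validate_partition(
    net: BooleanNetwork, blocks: Sequence[Iterable[str]]
) -> PartitionReport:
    """Check that blocks are non-empty, pairwise disjoint and cover V."""
    seen: set[str] = set()
    duplicated: set[str] = set()
    unknown: set[str] = set()
    empty: list[int] = []
    declared = set(net.nodes)
    for i, b in enumerate(blocks):
        b = set(b)
        if not b:
            empty.append(i)
        duplicated |= seen & b
        unknown |= b - declared
        seen |= b
    missing = declared - seen
    ok = not (missing or duplicated or unknown or empty)
    return PartitionReport(
        ok,
        missing=sorted(missing),
        duplicated=sorted(duplicated),
        unknown=sorted(unknown),
        empty_blocks=empty,
    )


def parse_partition_file(text: str) -> list[set[str]]:
    """Read a partition: one block per line, comma-separated node names."""
    blocks = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        blocks.append({name.strip() for name in line.split(",") if name.strip()})
    return blocks
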