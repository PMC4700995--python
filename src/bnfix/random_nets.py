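"""Seeded generation of N–K random Boolean networks with scale-free indegree.

The generator emulates the benchmark regime used for stress-testing
partition-based fixed-point detection: each node draws its indegree k
from a power law P(k) ∝ k^(−gamma) truncated to {1..K}, picks k distinct
regulators uniformly (self-loops allowed), and gets a random truth table
with a configurable bias toward 1.  Scale-free indegree means the
maximum indegree K greatly exceeds the average, the regime reported for
real gene-regulatory models.

Truth tables are rendered to ``.bnet`` expressions by minterm expansion,
so the syntactic regulator set equals the drawn regulator set unless the
table is constant (then the rule collapses to ``0``/``1``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import product

import numpy as np

from .expr import And, BoolExpr, Const, Not, Or, Var
from .model import BooleanNetwork, parse_bnet

__all__ = [
    "RandomBNConfig",
    "indegree_pmf",
    "generate_random_bn",
    "fixture_worked_example",
    "truth_table_to_expr",
]


@dataclass(frozen=True)
class RandomBNConfig:
    """Parameters of the random-network generator.

    n: node count; K: maximum indegree; gamma: power-law exponent of the
    truncated indegree distribution; bias: probability that a truth-table
    row outputs 1; seed: RNG seed (full determinism).

    With ``require_relevant`` (the default) a node's truth table is
    redrawn until its output depends on every drawn regulator, so the
    syntactic indegree equals the drawn indegree and no rule collapses
    to a constant; switch it off to admit degenerate tables.
    """

    n: int
    K: int = 2
    gamma: float = 2.5
    bias: float = 0.5
    seed: int = 0
    require_relevant: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (1 <= self.K <= self.n):
            raise ValueError("K must satisfy 1 <= K <= n")
        if self.gamma <= 1:
            raise ValueError("gamma must be > 1")
        if not (0 < self.bias < 1):
            raise ValueError("bias must lie strictly between 0 and 1")


def indegree_pmf(K: int, gamma: float) -> np.ndarray:
    """P(k) ∝ k^(−gamma) on k = 1..K, exactly normalised."""
    k = np.arange(1, K + 1, dtype=float)
    w = k ** (-gamma)
    return w / w.sum()


def truth_table_to_expr(regulators: list[str], outputs: list[int]) -> BoolExpr:
    """Render a truth table as an OR of minterms (constant if degenerate).

    ``outputs`` is indexed by the regulator bit pattern read as a binary
    number, first regulator = most significant bit.
    """
    if len(outputs) != 2 ** len(regulators):
        raise ValueError("outputs must have length 2^len(regulators)")
    if all(outputs):
        return Const(1)
    if not any(outputs):
        return Const(0)
    minterms = []
    for row, bits in enumerate(product((0, 1), repeat=len(regulators))):
        if outputs[row]:
            lits = [Var(r) if b else Not(Var(r)) for r, b in zip(regulators, bits)]
            minterms.append(lits[0] if len(lits) == 1 else And(tuple(lits)))
    return minterms[0] if len(minterms) == 1 else Or(tuple(minterms))


def _all_inputs_relevant(outputs: list[int], k: int) -> bool:
    """Does the table's output depend on every one of its k inputs?"""
    for pos in range(k):
        stride = 1 << (k - 1 - pos)
        if all(
            outputs[row] == outputs[row | stride]
            for row in range(len(outputs))
            if not row & stride
        ):
            return False
    return True


def generate_random_bn(cfg: RandomBNConfig) -> BooleanNetwork:
    """Generate one random network, fully determined by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    names = [f"v{i + 1}" for i in range(cfg.n)]
    pmf = indegree_pmf(cfg.K, cfg.gamma)
    rules: dict[str, BoolExpr] = {}
    for name in names:
        k = int(rng.choice(np.arange(1, cfg.K + 1), p=pmf))
        regs = sorted(rng.choice(cfg.n, size=k, replace=False).tolist())
        reg_names = [names[j] for j in regs]
        while True:
            outputs = (rng.random(2 ** k) < cfg.bias).astype(int).tolist()
            if not cfg.require_relevant or _all_inputs_relevant(outputs, k):
                break
        rules[name] = truth_table_to_expr(reg_names, outputs)
    return BooleanNetwork(names, rules)


def fixture_worked_example() -> BooleanNetwork:
    """The 6-node example network shipped with the package.

    Nodes v1..v6; the equivalence in v4's rule is written expanded as
    (v5 & v6) | (!v5 & !v6).  Its two fixed points are 000001 and 111010.
    """
    text = resources.files("bnfix.data").joinpath("worked_example.bnet").read_text()
    return parse_bnet(text)
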