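"""Shared fixtures: the 6-node example network and random-model helpers."""

import pytest

from bnfix import (
    BooleanNetwork,
    PartialState,
    RandomBNConfig,
    compose_pair,
    fixture_worked_example,
    generate_random_bn,
    make_subnetwork,
    partition_from_blocks,
)

THREE_BLOCKS = [{"v1", "v2", "v3"}, {"v5"}, {"v4", "v6"}]
FIXED_POINTS = ["000001", "111010"]


@pytest.fixture(scope="session")
def worked_example() -> BooleanNetwork:
    return fixture_worked_example()


@pytest.fixture(scope="session")
def three_block_subs(worked_example):
    """The 3-block partition {v1,v2,v3} | {v5} | {v4,v6} as subnetworks."""
    return partition_from_blocks(worked_example, THREE_BLOCKS)


def random_network(seed: int, n: int, K: int) -> BooleanNetwork:
    return generate_random_bn(RandomBNConfig(n=n, K=K, seed=seed))


def random_subnetworks(seed: int, count: int, max_scope: int):
    """Yield ``count`` seeded subnetworks with bounded scope.

    Blocks of size 1..3 are cut from random networks; subnetworks whose
    scope exceeds ``max_scope`` are skipped and regenerated.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    produced = 0
    while produced < count:
        n = int(rng.integers(5, 15))
        K = int(rng.integers(1, 6))
        net = random_network(int(rng.integers(0, 2**31 - 1)), n, K)
        size = int(rng.integers(1, 4))
        block = {net.nodes[j] for j in rng.choice(n, size=min(size, n), replace=False)}
        sub = make_subnetwork(net, block, produced)
        if len(sub.scope) > max_scope:
            continue
        produced += 1
        yield sub


def join_quadratic(left, right):
    """Reference join: plain double loop over all pairs (test oracle)."""
    out = []
    for a in left:
        for b in right:
            merged = compose_pair(a, b)
            if merged is not None:
                out.append(merged)
    return out


def bitstates(strings, order) -> list[PartialState]:
    return [PartialState.from_bits(order, map(int, s)) for s in strings]
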