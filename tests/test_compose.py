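"""Restriction, pairwise composition, set joins and the composition order."""

from itertools import permutations

import pytest

from bnfix import (
    IntermediateCapExceeded,
    PartialState,
    attractor_composition,
    compose_pair,
    determine_order,
    frontier_order,
    join_sets,
    local_fixed_points_sat,
    meb_partition,
    restrict,
)
from conftest import bitstates, join_quadratic, random_network


@pytest.fixture()
def local_sets(three_block_subs):
    return [local_fixed_points_sat(s) for s in three_block_subs]


class TestRestrict:
    def test_subvector_extraction(self):
        a = PartialState.from_bits(("v1", "v2", "v3", "v4", "v5"), (0, 1, 0, 1, 1))
        assert restrict(a, ["v2", "v3", "v4"]).vector(("v2", "v3", "v4")) == (1, 0, 1)

    def test_identity_and_empty(self):
        a = PartialState.from_bits(("x", "y"), (1, 0))
        assert restrict(a, a.domain) == a
        assert len(restrict(a, [])) == 0

    def test_target_outside_domain(self):
        a = PartialState.from_bits(("x",), (1,))
        with pytest.raises(KeyError):
            restrict(a, ["z"])


class TestComposePair:
    def test_agreeing_states_concatenate(self):
        a1 = PartialState.from_bits(("v1", "v2", "v3", "v4"), (1, 1, 1, 0))
        a2 = PartialState.from_bits(("v3", "v5"), (1, 1))
        merged = compose_pair(a1, a2)
        assert merged.vector(("v1", "v2", "v3", "v4", "v5")) == (1, 1, 1, 0, 1)
        assert merged.order == ("v1", "v2", "v3", "v4", "v5")

    def test_disjoint_domains_always_compose(self):
        a = PartialState.from_bits(("x",), (1,))
        b = PartialState.from_bits(("y",), (0,))
        assert compose_pair(a, b) == {"x": 1, "y": 0}

    def test_conflicting_common_node_is_incompatible(self):
        a1 = PartialState.from_bits(("v1", "v2", "v3", "v4"), (0, 0, 0, 0))
        a2 = PartialState.from_bits(("v3", "v5"), (1, 1))
        assert compose_pair(a1, a2) is None


class TestJoinSets:
    def test_printed_a1_a2_join(self, local_sets):
        out = join_sets(local_sets[0], local_sets[1])
        got = sorted(s.bitstring(("v1", "v2", "v3", "v4", "v5")) for s in out)
        # the two commonly quoted states plus 11111, forced by the local
        # sets themselves (A1 contains 1111 and A2 contains 11, agreeing
        # on the shared node v3); 11111 dies at the next join
        assert got == ["00000", "11101", "11111"]

    def test_printed_a1_a3_join(self, local_sets):
        out = join_sets(local_sets[0], local_sets[2])
        got = sorted(s.bitstring(("v1", "v2", "v3", "v4", "v5", "v6")) for s in out)
        assert got == ["000001", "000010", "111001", "111010"]

    def test_empty_annihilates(self, local_sets):
        assert join_sets(local_sets[0], []) == []
        assert join_sets([], local_sets[0]) == []

    def test_hash_join_equals_quadratic_loop(self):
        for seed in range(6):
            net = random_network(seed, n=10, K=3)
            subs = meb_partition(net)
            sets = [local_fixed_points_sat(s) for s in subs]
            for i in range(len(sets) - 1):
                fast = join_sets(sets[i], sets[i + 1])
                slow = join_quadratic(sets[i], sets[i + 1])
                assert set(fast) == set(slow) and len(fast) == len(slow)
                assert len(fast) <= len(sets[i]) * len(sets[i + 1])

    def test_disjoint_common_set_gives_full_product(self):
        a = bitstates(["0", "1"], ("x",))
        b = bitstates(["0", "1"], ("y",))
        assert len(join_sets(a, b)) == 4


class TestDetermineOrder:
    def test_three_block_order(self, three_block_subs):
        # seed = largest scope (4 nodes); overlap ties between the other
        # two blocks resolve to the one adding fewer new nodes
        assert determine_order(three_block_subs) == (0, 1, 2)

    def test_single_subnetwork(self, worked_example):
        from bnfix import make_subnetwork

        sub = make_subnetwork(worked_example, set(worked_example.nodes))
        assert determine_order([sub]) == (0,)

    def test_meb_order_seeds_at_first_largest_scope(self, worked_example):
        subs = meb_partition(worked_example)
        order = determine_order(subs)
        assert order[0] == 0  # v1's subnetwork: first of the size-3 scopes
        assert sorted(order) == list(range(6))

    def test_frontier_order_is_a_permutation(self, worked_example):
        subs = meb_partition(worked_example)
        assert sorted(frontier_order(subs)) == list(range(6))


class TestAttractorComposition:
    def test_heuristic_order_reaches_printed_fixed_points(
        self, worked_example, three_block_subs, local_sets
    ):
        out = attractor_composition(three_block_subs, local_sets, (0, 1, 2))
        assert [s.bitstring(worked_example.nodes) for s in out] == [
            "000001", "111010",
        ]

    def test_alternative_order_same_final_set(
        self, worked_example, three_block_subs, local_sets
    ):
        tr = []
        out = attractor_composition(three_block_subs, local_sets, (0, 2, 1), trace=tr)
        assert [s.bitstring(worked_example.nodes) for s in out] == [
            "000001", "111010",
        ]
        # the detour builds 4 intermediates and discards 2 of them
        assert tr[0].out_size == 4
        assert tr[1].discarded_left == 2

    def test_intermediate_accounting_along_both_orders(
        self, three_block_subs, local_sets
    ):
        tr = []
        attractor_composition(three_block_subs, local_sets, (0, 1, 2), trace=tr)
        assert max(s.out_size for s in tr) == 3
        tr = []
        attractor_composition(three_block_subs, local_sets, (0, 2, 1), trace=tr)
        assert max(s.out_size for s in tr) == 4

    def test_empty_local_set_empties_result(self, three_block_subs, local_sets):
        out = attractor_composition(
            three_block_subs, [local_sets[0], [], local_sets[2]], (0, 1, 2)
        )
        assert out == []

    def test_invalid_order_rejected(self, three_block_subs, local_sets):
        with pytest.raises(ValueError):
            attractor_composition(three_block_subs, local_sets, (0, 1))

    def test_cap_raises(self, three_block_subs, local_sets):
        with pytest.raises(IntermediateCapExceeded):
            attractor_composition(three_block_subs, local_sets, (0, 2, 1), cap=3)

    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_final_set_is_order_independent(self, seed):
        """Any composition order yields the same global fixed points."""
        import random as pyrandom

        net = random_network(seed, n=10, K=3)
        subs = meb_partition(net)
        sets = [local_fixed_points_sat(s) for s in subs]
        reference = attractor_composition(subs, sets, determine_order(subs))
        rng = pyrandom.Random(seed)
        for _ in range(5):
            order = list(range(len(subs)))
            rng.shuffle(order)
            assert attractor_composition(subs, sets, tuple(order)) == reference
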