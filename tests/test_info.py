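import itertools

import numpy as np
import pytest

from relaytrace.discretize import DiscreteStateTable
from relaytrace.fixtures import PlantedRelaySpec, exact_joint_table
from relaytrace.info import (
    co_information,
    joint_entropy,
    mutual_information,
    particular_relay_information,
    relay_information,
)

from _bruteforce import brute_entropy, brute_relay_information


def _table(labels, preds, bits, n_classes=2, weights=None):
    return DiscreteStateTable(np.asarray(labels), np.asarray(preds),
                              np.asarray(bits, dtype=np.uint8), n_classes, weights)


def _perfect_10class(reps=10):
    """Balanced perfect classifier whose 4 hidden bits encode the class."""
    labels = np.repeat(np.arange(10), reps)
    bits = ((labels[:, None] >> np.arange(4)) & 1).astype(np.uint8)
    return DiscreteStateTable(labels, labels.copy(), bits, 10)


class TestEntropy:
    def test_fair_bit_is_one_bit(self):
        t = _table([0, 0, 1, 1], [0, 0, 0, 0], np.zeros((4, 1)))
        assert joint_entropy(t, ["input"]) == pytest.approx(1.0)

    def test_constant_column_is_zero(self):
        t = _table([1, 1, 1], [0, 1, 0], np.zeros((3, 1)))
        assert joint_entropy(t, ["input"]) == 0.0

    def test_two_independent_fair_bits_are_two_bits(self):
        bits = np.array(list(itertools.product([0, 1], repeat=2)))
        t = _table([0] * 4, [0] * 4, bits)
        assert joint_entropy(t, [0, 1]) == pytest.approx(2.0)

    def test_entropy_bounded_by_log_distinct_tuples(self):
        rng = np.random.default_rng(0)
        t = _table(rng.integers(0, 3, 40), rng.integers(0, 3, 40),
                   rng.integers(0, 2, (40, 3)), n_classes=3)
        h = joint_entropy(t, ["input", "output", 0, 1, 2])
        distinct = len({tuple(r) for r in np.column_stack(
            [t.input_label, t.predicted_label, t.hidden_bits])})
        assert 0.0 <= h <= np.log2(distinct) + 1e-12

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            joint_entropy(_table([0], [0], [[0]]), [])


class TestMutualInformation:
    def test_perfect_balanced_ten_class_channel(self):
        t = _perfect_10class()
        assert mutual_information(t, "input", "output") == pytest.approx(np.log2(10))

    def test_independent_product_distribution_is_zero(self):
        rows = np.array(list(itertools.product([0, 1], [0, 1])))
        t = _table(rows[:, 0], rows[:, 1], np.zeros((4, 1)))
        assert mutual_information(t, "input", "output") == pytest.approx(0.0, abs=1e-12)

    def test_copy_has_entropy_of_source(self):
        labels = np.array([0, 0, 1, 2])
        t = _table(labels, labels.copy(), np.zeros((4, 1)), n_classes=3)
        assert mutual_information(t, "input", "output") == pytest.approx(
            joint_entropy(t, ["input"]))

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        t = _table(rng.integers(0, 3, 30), rng.integers(0, 3, 30),
                   rng.integers(0, 2, (30, 2)), n_classes=3)
        assert mutual_information(t, "input", [0, 1]) == pytest.approx(
            mutual_information(t, [0, 1], "input"))


class TestCoInformation:
    def test_copy_chain_is_one_bit(self):
        x = np.array([0, 1, 0, 1])
        t = _table(x, x.copy(), x[:, None])
        assert co_information(t, "input", "output", 0) == pytest.approx(1.0)

    def test_xor_is_minus_one_bit(self):
        rows = np.array(list(itertools.product([0, 1], [0, 1])))
        z = rows[:, 0] ^ rows[:, 1]
        t = _table(rows[:, 0], rows[:, 1], z[:, None])
        assert co_information(t, "input", "output", 0) == pytest.approx(-1.0)

    def test_constant_group_gives_zero(self):
        rng = np.random.default_rng(2)
        t = _table(rng.integers(0, 2, 20), rng.integers(0, 2, 20), np.zeros((20, 1)))
        assert co_information(t, "input", "output", 0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("perm", list(itertools.permutations("abc")))
    def test_permutation_invariance(self, perm):
        rng = np.random.default_rng(3)
        t = _table(rng.integers(0, 3, 50), rng.integers(0, 3, 50),
                   rng.integers(0, 2, (50, 2)), n_classes=3)
        groups = {"a": "input", "b": "output", "c": [0, 1]}
        base = co_information(t, groups["a"], groups["b"], groups["c"])
        assert co_information(t, *(groups[p] for p in perm)) == pytest.approx(
            base, abs=1e-12)


class TestRelayInformation:
    def test_conditioning_on_constant_is_a_no_op(self):
        x = np.array([0, 1] * 8)
        bits = np.column_stack([x, np.zeros(16)])
        t = _table(x, x.copy(), bits)
        assert relay_information(t, [0], [1]) == pytest.approx(1.0)

    def test_copy_in_conditioning_set_shields_the_relay(self):
        # redundancy shielding: given an exact copy, the relay adds nothing
        x = np.array([0, 1] * 8)
        bits = np.column_stack([x, x])
        t = _table(x, x.copy(), bits)
        assert relay_information(t, [0], [1]) == pytest.approx(0.0, abs=1e-12)

    def test_empty_conditioning_reduces_to_co_information(self):
        rng = np.random.default_rng(4)
        t = _table(rng.integers(0, 3, 60), rng.integers(0, 3, 60),
                   rng.integers(0, 2, (60, 4)), n_classes=3)
        assert relay_information(t, [0, 1, 2, 3], []) == pytest.approx(
            co_information(t, "input", "output", [0, 1, 2, 3]), abs=1e-12)

    def test_empty_relay_set_is_zero_by_convention(self):
        t = _table([0, 1], [0, 1], [[0], [1]])
        assert relay_information(t, [], [0]) == 0.0

    def test_overlapping_sets_rejected(self):
        t = _table([0, 1], [0, 1], [[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            relay_information(t, [0], [0])


class TestParticularRelayInformation:
    def test_perfect_classifier_full_set_gives_binary_entropy(self):
        t = _perfect_10class()
        h01 = -0.1 * np.log2(0.1) - 0.9 * np.log2(0.9)
        for i in (0, 7):
            assert particular_relay_information(t, i, [0, 1, 2, 3]) == pytest.approx(h01)

    def test_absent_class_gives_zero(self):
        t = _table([0, 0, 1, 1], [0, 0, 1, 1], [[0], [1], [0], [1]], n_classes=3)
        assert particular_relay_information(t, 2, [0]) == pytest.approx(0.0, abs=1e-12)

    def test_class_out_of_range_rejected(self):
        t = _table([0, 1], [0, 1], [[0], [1]])
        with pytest.raises(ValueError):
            particular_relay_information(t, 5, [0])


class TestOracleEquivalence:
    """The packed-array estimators must match a dictionary-based brute force
    that computes conditional co-information from its defining decomposition."""

    @pytest.mark.parametrize("seed", range(8))
    def test_sampled_tables_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n_hidden = int(rng.integers(2, 7))
        n = int(rng.integers(20, 80))
        t = _table(rng.integers(0, 3, n), rng.integers(0, 3, n),
                   rng.integers(0, 2, (n, n_hidden)), n_classes=3)
        cols = np.column_stack([t.input_label, t.hidden_bits])
        assert joint_entropy(t, ["input"] + list(range(n_hidden))) == pytest.approx(
            brute_entropy(cols), abs=1e-12)
        nodes = list(range(n_hidden))
        rng.shuffle(nodes)
        k = int(rng.integers(1, n_hidden))
        relay, cond = nodes[:k], nodes[k:]
        for target in (None, 1):
            assert relay_information(t, relay, cond, target) == pytest.approx(
                brute_relay_information(t.input_label, t.predicted_label,
                                        t.hidden_bits, relay, cond, target),
                abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_exact_weighted_tables_match_bruteforce(self, seed):
        t = exact_joint_table(PlantedRelaySpec(n_classes=3, proto_features=4, seed=seed))
        for relay, cond in ([(0, 1), (2, 3)], [(0, 2), (1, 3)], [(3,), (0, 1, 2)]):
            for target in (None, 1, 2):
                assert relay_information(t, relay, cond, target) == pytest.approx(
                    brute_relay_information(t.input_label, t.predicted_label,
                                            t.hidden_bits, relay, cond, target,
                                            weights=t.weights),
                    abs=1e-12)


class TestDistributionLevelProperties:
    def test_full_set_identity_on_deterministic_network(self, planted_table):
        # all input-output information passes through the hidden layer
        t = planted_table
        full = list(range(t.n_hidden))
        assert co_information(t, "input", "output", full) == pytest.approx(
            mutual_information(t, "input", "output"), abs=1e-12)

    def test_relay_information_monotone_over_nested_sets(self, planted_table):
        # on an exact distribution a subset cannot out-inform its superset
        t = planted_table
        rng = np.random.default_rng(0)
        all_nodes = list(range(t.n_hidden))
        for _ in range(20):
            size = int(rng.integers(2, t.n_hidden + 1))
            superset = sorted(rng.choice(all_nodes, size=size, replace=False))
            subset = sorted(rng.choice(superset, size=size - 1, replace=False))
            for target in (None, 1):
                big = relay_information(t, superset,
                                        [x for x in all_nodes if x not in superset], target)
                small = relay_information(t, subset,
                                          [x for x in all_nodes if x not in subset], target)
                assert small <= big + 1e-12

    def test_miller_madow_correction_only_shifts_sampled_estimates(self):
        rng = np.random.default_rng(5)
        t = _table(rng.integers(0, 3, 40), rng.integers(0, 3, 40),
                   rng.integers(0, 2, (40, 2)), n_classes=3)
        plain = joint_entropy(t, ["input", 0, 1])
        corrected = joint_entropy(t, ["input", 0, 1], bias_correction=True)
        assert corrected > plain  # plug-in underestimates; correction adds (K-1)/2n ln2
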