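import numpy as np
import pytest

from relaytrace.datasets import LabeledDataset
from relaytrace.fixtures import generate_pattern_dataset
from relaytrace.network import (
    Network,
    TanhNetClassifier,
    TrainConfig,
    compose,
    evaluate_accuracy,
    forward_clamped,
    knockout,
    record_states,
    train,
)


def _random_net(seed=0, n_in=6, n_hidden=5, n_out=3) -> Network:
    rng = np.random.default_rng(seed)
    return Network(
        [rng.normal(size=(n_hidden, n_in)), rng.normal(size=(n_out, n_hidden))],
        [rng.normal(size=n_hidden), rng.normal(size=n_out)],
    )


class TestTraining:
    def test_vacuous_target_stops_after_first_epoch(self):
        ds = generate_pattern_dataset(3, 4, 60, seed=0)
        _, history = train(ds, (4, 3, 3), TrainConfig(target_accuracy=0.0, max_epochs=50))
        assert len(history) == 1

    def test_separable_two_class_task_reaches_98_percent(self):
        # linearly separable by construction, so the bound must hold
        ds = generate_pattern_dataset(2, 16, 2000, noise=0.0, seed=1)
        cfg = TrainConfig(target_accuracy=0.98, max_epochs=200, seed=1)
        net, history = train(ds, (16, 4, 2), cfg)
        assert history["accuracy"].iloc[-1] >= 0.98
        assert len(history) <= 200

    def test_fixed_seed_training_is_reproducible(self):
        ds = generate_pattern_dataset(3, 8, 200, seed=2)
        cfg = TrainConfig(target_accuracy=1.0, max_epochs=3, seed=5)
        net_a, _ = train(ds, (8, 4, 3), cfg)
        net_b, _ = train(ds, (8, 4, 3), cfg)
        for wa, wb in zip(net_a.weights, net_b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_history_records_per_class_recall(self):
        ds = generate_pattern_dataset(3, 4, 90, seed=0)
        _, history = train(ds, (4, 3, 3), TrainConfig(target_accuracy=0.0))
        assert {"recall_0", "recall_1", "recall_2"} <= set(history.columns)

    def test_shape_mismatch_rejected(self):
        ds = generate_pattern_dataset(3, 4, 30, seed=0)
        with pytest.raises(ValueError):
            train(ds, (5, 3, 3), TrainConfig())
        with pytest.raises(ValueError):
            train(ds, (4, 3, 7), TrainConfig())

    def test_sklearn_estimator_api(self):
        ds = generate_pattern_dataset(3, 8, 300, seed=3, feature_noise=0.4)
        clf = TanhNetClassifier(hidden_units=4, max_epochs=100, target_accuracy=0.95,
                                random_state=0)
        assert clf.get_params()["hidden_units"] == 4
        clf.fit(ds.features, ds.labels)
        pred = clf.predict(ds.features)
        assert pred.shape == (300,)
        assert np.mean(pred == ds.labels) >= 0.9


class TestCompose:
    def test_composite_structure_is_block_sparse(self, trained_composite):
        comp, _ = trained_composite
        W2 = comp.weights[1]
        assert W2.shape == (10, 20)
        # exactly two nonzero second-layer weights per output, on the diagonal blocks
        assert np.count_nonzero(W2) == 20
        for i in range(10):
            block = np.zeros_like(W2[i])
            block[2 * i : 2 * i + 2] = W2[i, 2 * i : 2 * i + 2]
            np.testing.assert_array_equal(W2[i], block)

    def test_identical_subnets_give_symmetric_outputs(self):
        sub = _random_net(seed=1, n_in=4, n_hidden=2, n_out=1)
        comp = compose([sub] * 5)
        _, out = comp.forward(np.random.default_rng(0).uniform(-1, 1, (7, 4)))
        assert np.allclose(out, out[:, [0]])

    def test_composition_locality(self):
        # output i must ignore every hidden slot outside (2i, 2i+1)
        subs = [_random_net(seed=s, n_in=4, n_hidden=2, n_out=1) for s in range(3)]
        comp = compose(subs)
        X = np.random.default_rng(1).uniform(-1, 1, (20, 4))
        _, base = comp.forward(X)
        perturbed = comp.copy()
        perturbed.weights[0][2] *= -1.0  # hidden slot of sub-net 1
        perturbed.biases[0][2] += 0.5
        _, out = perturbed.forward(X)
        np.testing.assert_array_equal(out[:, 0], base[:, 0])
        np.testing.assert_array_equal(out[:, 2], base[:, 2])
        assert not np.allclose(out[:, 1], base[:, 1])

    def test_wrong_subnet_shape_rejected(self):
        with pytest.raises(ValueError):
            compose([_random_net(n_hidden=3, n_out=1)])
        with pytest.raises(ValueError):
            compose([_random_net(n_hidden=2, n_out=2)])


class TestKnockout:
    def test_empty_lesion_is_identity(self):
        net = _random_net()
        X = np.random.default_rng(2).uniform(-1, 1, (10, 6))
        np.testing.assert_array_equal(knockout(net, []).forward(X)[1], net.forward(X)[1])

    def test_full_lesion_gives_constant_prediction(self):
        net = _random_net()
        X = np.random.default_rng(3).uniform(-1, 1, (30, 6))
        lesioned = knockout(net, range(5))
        _, out = lesioned.forward(X)
        expected = np.broadcast_to(np.tanh(net.biases[1]), out.shape)
        np.testing.assert_allclose(out, expected, atol=1e-15)
        assert len(set(lesioned.predict(X))) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_clamp_equivalence_is_bit_exact(self, seed):
        # zeroing incident weights == clamping the activation to 0 (tanh(0)=0)
        rng = np.random.default_rng(seed)
        net = _random_net(seed=seed)
        nodes = rng.choice(5, size=rng.integers(1, 5), replace=False)
        X = rng.uniform(-1, 1, (25, 6))
        h_ko, out_ko = knockout(net, nodes).forward(X)
        h_cl, out_cl = forward_clamped(net, nodes, X)
        np.testing.assert_array_equal(out_ko, out_cl)
        np.testing.assert_array_equal(h_ko[:, sorted(set(nodes))], h_cl[:, sorted(set(nodes))])

    def test_composite_block_knockout_silences_one_output(self, trained_composite):
        comp, ds = trained_composite
        X = ds.features[:100]
        _, base = comp.forward(X)
        for i in (0, 7):
            _, out = knockout(comp, [2 * i, 2 * i + 1]).forward(X)
            assert np.ptp(out[:, i]) == 0.0  # constant across inputs
            others = [j for j in range(10) if j != i]
            np.testing.assert_array_equal(out[:, others], base[:, others])

    def test_out_of_range_index_rejected(self):
        with pytest.raises(IndexError):
            knockout(_random_net(), [99])


class TestStatesAndAccuracy:
    def test_record_states_aligns_predictions(self):
        net = _random_net()
        ds = LabeledDataset(np.random.default_rng(4).uniform(-1, 1, (40, 6)),
                            np.random.default_rng(4).integers(0, 3, 40), 3)
        st = record_states(net, ds)
        assert st.n_samples == 40 and st.n_hidden == 5
        np.testing.assert_array_equal(st.predicted_label, net.predict(ds.features))
        assert np.all(np.abs(st.hidden_activations) <= 1.0)

    def test_zero_weight_net_has_identical_rows(self):
        net = Network([np.zeros((4, 3)), np.zeros((2, 4))],
                      [np.full(4, 0.3), np.zeros(2)])
        ds = LabeledDataset(np.random.default_rng(0).uniform(-1, 1, (10, 3)),
                            np.zeros(10, dtype=int), 2)
        st = record_states(net, ds)
        np.testing.assert_allclose(st.hidden_activations, np.tanh(0.3), atol=1e-15)

    def test_constant_predictor_accuracy_and_recalls(self):
        # a net whose output biases force class 3 regardless of input
        b2 = np.zeros(10)
        b2[3] = 2.0
        net = Network([np.zeros((4, 5)), np.zeros((10, 4))], [np.zeros(4), b2])
        labels = np.repeat(np.arange(10), 5)
        ds = LabeledDataset(np.zeros((50, 5)), labels, 10)
        acc, recalls = evaluate_accuracy(net, ds)
        assert acc == pytest.approx(0.1)
        assert recalls[3] == 1.0
        assert all(recalls[i] == 0.0 for i in range(10) if i != 3)

    def test_absent_class_recall_is_nan(self):
        net = _random_net(n_out=3)
        ds = LabeledDataset(np.random.default_rng(1).uniform(-1, 1, (10, 6)),
                            np.zeros(10, dtype=int), 3)
        _, recalls = evaluate_accuracy(net, ds)
        assert np.isnan(recalls[1]) and np.isnan(recalls[2])


def test_network_json_round_trip_is_exact(tmp_path):
    net = _random_net(seed=9)
    path = tmp_path / "net.json"
    net.to_json(path)
    back = Network.from_json(path)
    for a, b in zip(net.weights + net.biases, back.weights + back.biases):
        np.testing.assert_array_equal(a, b)
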