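import numpy as np
import pytest

from relaytrace.datasets import LabeledDataset
from relaytrace.discretize import DiscreteStateTable, binarize, fit_binarizer
from relaytrace.fixtures import PlantedRelaySpec, exact_joint_table, generate_pattern_dataset
from relaytrace.network import TrainConfig, compose, record_states, train


def random_table(n_samples=60, n_hidden=5, n_classes=3, seed=0) -> DiscreteStateTable:
    """A random sampled discrete state table (no structure)."""
    rng = np.random.default_rng(seed)
    return DiscreteStateTable(
        rng.integers(0, n_classes, n_samples),
        rng.integers(0, n_classes, n_samples),
        rng.integers(0, 2, (n_samples, n_hidden)).astype(np.uint8),
        n_classes,
    )


@pytest.fixture
def planted_table() -> DiscreteStateTable:
    """Exact table of a 3-real-class planted network (6 hidden nodes)."""
    return exact_joint_table(PlantedRelaySpec(n_classes=4, proto_features=4, seed=1))


@pytest.fixture(scope="session")
def trained_composite():
    """A small composite control: ten one-vs-rest sub-nets trained on a
    10-class pattern task, assembled into a 16-20-10 network."""
    ds = generate_pattern_dataset(10, 16, 2500, noise=0.005, seed=1)
    subnets = []
    for i in range(10):
        binary = LabeledDataset(ds.features, (ds.labels == i).astype(int), 2)
        net, _ = train(
            binary, (16, 2, 1),
            TrainConfig(target_accuracy=0.98, max_epochs=300, seed=100 + i),
        )
        subnets.append(net)
    return compose(subnets), ds


@pytest.fixture(scope="session")
def composite_table(trained_composite) -> DiscreteStateTable:
    net, ds = trained_composite
    states = record_states(net, ds)
    return binarize(states, fit_binarizer(states, "kmeans"))
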