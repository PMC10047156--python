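"""Synthetic fixtures with known ground-truth relays.

Everything downstream of training — discretization, relay information, subset
search, attribution, knockout — is testable without any external data by
generating (a) separable pattern datasets and (b) *planted-relay* networks in
which the hidden nodes carrying each class's information are known by
construction, mirroring the composite-network control: class-i outputs are
wired exclusively to a designated pair of hidden relay nodes.

Design of the planted network
-----------------------------
A naive "perfect" composite (each relay pair a clean indicator of its class)
is useless as a fixture for *conditional* relay information: with C classes
partitioning the input space, the complement set Y0 then determines every
class indicator exactly, and all conditional relay informations collapse to
zero (the redundancy-shielding property doing its job too well).  Real
trained networks escape this because hidden states respond noisily.

The planted construction therefore gates each relay pair on private noise
inputs: relay r1 of class i fires when the class-i prototype is present *and*
noise bit a_i is up; relay r2 fires when a_i is down and b_i is up.  The two
relays are thus complementary rather than copies, jointly (but not
individually) covering most class-i inputs, and no class's relay pair — nor
the complement of any pair — determines Z_i exactly.  Class 0 is a
featureless *background* class that wins the argmax whenever no relay pair
fires, so the predicted label is an exact function of the *binarized*
hidden state — keeping the full-set identity I(Xin;Xout;Y) = I(Xin;Xout)
exact rather than polluted by sub-threshold analog residues — and no real
class is the default prediction.  Inert nodes (zero weights) and redundant
copies (duplicated incoming weights, zero outgoing) can be appended to
probe ΔI = 0 and essentiality-0 behaviour.

One caveat is inherent to mutually exclusive classes: other classes' relay
pairs carry *exclusion* information about class i (seeing class j fire
rules class i out), so conditioning them away always costs a little
information and the greedy trajectory for class i is not exactly flat until
the planted pair.  The single-real-class fixture (``n_classes=2`` plus
inert nodes) removes even that, making the planted pair the carrier of
strictly all class information.

Because every hidden activation is a function of the discrete state
(class, noise bits), the exact joint distribution over (Xin, Xout, Y) can be
enumerated in closed form — removing all sampling noise, so the
distribution-level guarantees (monotonicity of I_R over nested sets, greedy =
exhaustive per-size optimality) hold without tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import hadamard

from .datasets import LabeledDataset
from .discretize import DiscreteStateTable
from .network import Network

__all__ = [
    "PlantedRelaySpec",
    "generate_pattern_dataset",
    "orthogonal_prototypes",
    "make_planted_relay_network",
    "sample_planted_dataset",
    "exact_joint_table",
]


def orthogonal_prototypes(n_classes: int, n_features: int) -> np.ndarray:
    """C mutually orthogonal ±1 prototype vectors in F dimensions.

    Rows of a Hadamard matrix of order m (the smallest power of two >= C),
    tiled across full m-column blocks of F; any remainder columns are zero,
    preserving exact orthogonality.  Requires F >= m.
    """
    if n_classes < 1:
        raise ValueError("need at least 1 prototype")
    m = 1
    while m < n_classes:
        m *= 2
    if n_features < m:
        raise ValueError(f"need at least {m} features for {n_classes} orthogonal prototypes")
    H = hadamard(m)[:n_classes]
    tiles = n_features // m
    protos = np.zeros((n_classes, n_features))
    protos[:, : tiles * m] = np.tile(H, (1, tiles))
    return protos.astype(float)


def generate_pattern_dataset(
    n_classes: int,
    n_features: int,
    n_samples: int,
    noise: float = 0.0,
    seed: int = 0,
    feature_noise: float = 0.65,
) -> LabeledDataset:
    """Separable prototype patterns plus bounded feature noise.

    Each sample is its class prototype shrunk to ±(1 - feature_noise) plus
    uniform noise in [-feature_noise, feature_noise]; the recorded label is
    flipped to a different random class with probability ``noise``.  Classes
    are drawn uniformly, so the dataset is balanced up to binomial
    fluctuation, and with noise = 0 it is linearly separable by construction.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if not 0.0 <= noise < 0.5:
        raise ValueError("label-flip probability must lie in [0, 0.5)")
    if not 0.0 <= feature_noise < 1.0:
        raise ValueError("feature_noise must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    protos = orthogonal_prototypes(n_classes, n_features)
    true = rng.integers(0, n_classes, size=n_samples)
    X = protos[true] * (1.0 - feature_noise)
    X += rng.uniform(-feature_noise, feature_noise, size=X.shape)
    labels = true.copy()
    flip = rng.random(n_samples) < noise
    shift = rng.integers(1, n_classes, size=n_samples)
    labels[flip] = (labels[flip] + shift[flip]) % n_classes
    return LabeledDataset(X, labels, n_classes)


@dataclass
class PlantedRelaySpec:
    """Blueprint of a planted-relay network.

    Class 0 is a featureless *background* class: it has no prototype and no
    relay nodes, and it wins the argmax whenever no relay pair fires.  Each
    real class i in {1, ..., n_classes-1} owns the relay pair
    (2(i-1), 2(i-1)+1).  After the relay pairs come ``n_inert`` dead nodes
    (zero weights: activation exactly 0), then one copy node per entry of
    ``redundant_copies`` (the index of an existing relay whose incoming
    weights are duplicated; copies have zero outgoing weights).

    Inputs: ``proto_features`` prototype dimensions followed by two private
    noise dimensions (a_i, b_i) per real class, each taking values ±1.
    """

    n_classes: int = 4
    proto_features: int = 4
    n_inert: int = 0
    redundant_copies: tuple[int, ...] = ()
    gain: float = 16.0
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need a background class plus at least one real class")
        self.redundant_copies = tuple(int(r) for r in self.redundant_copies)
        for r in self.redundant_copies:
            if not 0 <= r < 2 * (self.n_classes - 1):
                raise ValueError(f"redundant copy {r} does not reference a relay node")
        if self.n_inert < 0:
            raise ValueError("n_inert must be >= 0")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        # validate the prototype geometry early
        orthogonal_prototypes(self.n_real_classes, self.proto_features)

    @property
    def n_real_classes(self) -> int:
        return self.n_classes - 1

    @property
    def n_noise_inputs(self) -> int:
        return 2 * self.n_real_classes

    @property
    def n_inputs(self) -> int:
        return self.proto_features + self.n_noise_inputs

    @property
    def n_hidden(self) -> int:
        return 2 * self.n_real_classes + self.n_inert + len(self.redundant_copies)

    @property
    def relay_map(self) -> dict[int, tuple[int, int]]:
        """Ground truth: real class -> the pair of hidden nodes carrying it."""
        return {i: (2 * (i - 1), 2 * (i - 1) + 1) for i in range(1, self.n_classes)}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedRelaySpec":
        doc = json.loads(Path(path).read_text())
        doc["redundant_copies"] = tuple(doc.get("redundant_copies", ()))
        return cls(**doc)


def make_planted_relay_network(spec: PlantedRelaySpec) -> tuple[Network, dict[int, tuple[int, int]]]:
    """Wire a network whose class-i output depends only on its planted pair.

    Relay r1 of real class i fires (activation > 0) iff the input matches
    prototype i and noise input a_i = +1; relay r2 fires iff the prototype
    matches, a_i = -1 and b_i = +1 (joint coverage 3/4).  The background
    output (class 0) reads nothing and sits at activation 0: above every
    "missed" real output, below every firing one, so the argmax is an exact
    function of the binarized hidden state.  Per-node gains carry a seeded
    ±5% jitter so distinct fixtures break ties differently while every
    decision margin keeps its sign (margins are at least ±gain/4).

    Returns the network and the ground-truth relay map.
    """
    rng = np.random.default_rng(spec.seed)
    R, Fp = spec.n_real_classes, spec.proto_features
    protos = orthogonal_prototypes(R, Fp)
    # prototype-match score s_i = <x_proto, p_i> / |p_i|^2 is 1 for real
    # class i, 0 for any other class or background, on noise-free states.
    norms = (protos**2).sum(axis=1)
    H, F = spec.n_hidden, spec.n_inputs
    W1 = np.zeros((H, F))
    b1 = np.zeros(H)
    for k in range(R):
        g1 = 0.25 * spec.gain * (1.0 + 0.05 * rng.uniform(-1, 1))
        g2 = 0.25 * spec.gain * (1.0 + 0.05 * rng.uniform(-1, 1))
        a_dim = Fp + 2 * k
        b_dim = Fp + 2 * k + 1
        r1, r2 = 2 * k, 2 * k + 1
        # r1: 2 s_i + u_a - 2 is +1 for (class i, u_a=+1), else <= -1
        W1[r1, :Fp] = protos[k] * (2.0 * g1 / norms[k])
        W1[r1, a_dim] = g1
        b1[r1] = -2.0 * g1
        # r2: 4 s_i - 2 u_a + u_b - 6 is +1 for (class i, u_a=-1, u_b=+1),
        # else <= -1
        W1[r2, :Fp] = protos[k] * (4.0 * g2 / norms[k])
        W1[r2, a_dim] = -2.0 * g2
        W1[r2, b_dim] = g2
        b1[r2] = -6.0 * g2
    # inert nodes keep all-zero rows and bias -> activation exactly 0
    base = 2 * R + spec.n_inert
    for k, src_node in enumerate(spec.redundant_copies):
        W1[base + k] = W1[src_node]
        b1[base + k] = b1[src_node]
    C = spec.n_classes
    W2 = np.zeros((C, H))
    b2 = np.zeros(C)
    for i in range(1, C):
        # pre-activation of real output i: h_r1 + h_r2 + 1, i.e. ~ +1 when a
        # relay fires and ~ -0.9 when both are silent; the background output
        # stays at exactly 0 and wins iff nothing fires.
        W2[i, 2 * (i - 1)] = 1.0
        W2[i, 2 * (i - 1) + 1] = 1.0
        b2[i] = 1.0
    return Network([W1, W2], [b1, b2]), spec.relay_map


def _proto_inputs(spec: PlantedRelaySpec, labels: np.ndarray, coins: np.ndarray) -> np.ndarray:
    """Assemble input vectors from class labels and ±1 coin states."""
    protos = orthogonal_prototypes(spec.n_real_classes, spec.proto_features)
    X = np.zeros((labels.size, spec.n_inputs))
    real = labels > 0
    X[real, : spec.proto_features] = protos[labels[real] - 1]
    X[:, spec.proto_features :] = coins
    return X


def _enumerate_states(spec: PlantedRelaySpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (class, coins) input states with their probabilities."""
    C, m = spec.n_classes, spec.n_noise_inputs
    if C * 2**m > 2**16:
        raise ValueError(
            f"exact enumeration needs {C}*2^{m} states; reduce n_classes "
            "(state space capped at 2^16)"
        )
    coin_states = np.array(
        [[1.0 if (s >> d) & 1 else -1.0 for d in range(m)] for s in range(2**m)]
    )
    n_coins = coin_states.shape[0]
    labels = np.repeat(np.arange(C), n_coins)
    X = _proto_inputs(spec, labels, np.tile(coin_states, (C, 1)))
    probs = np.full(C * n_coins, 1.0 / (C * n_coins))
    return X, labels, probs


def exact_joint_table(spec: PlantedRelaySpec) -> DiscreteStateTable:
    """The analytically exact discrete state table of a planted network.

    Enumerates the uniform distribution over (class, noise-bit) input states,
    runs the forward pass, binarizes hidden activations at sign (the tanh
    sign equals the pre-activation sign), and stores per-row probabilities —
    no sampling noise, so information identities hold exactly.
    """
    net, _ = make_planted_relay_network(spec)
    X, labels, probs = _enumerate_states(spec)
    hidden, out = net.forward(X)
    pred = np.argmax(out, axis=1)
    bits = (hidden > 0.0).astype(np.uint8)
    return DiscreteStateTable(labels, pred, bits, spec.n_classes, weights=probs)


def sample_planted_dataset(spec: PlantedRelaySpec, n_samples: int, seed: int = 0) -> LabeledDataset:
    """Sample (class, coins) states i.i.d. as a labeled dataset for the
    planted network, with optional label flips at rate ``spec.label_noise``."""
    rng = np.random.default_rng(seed)
    C, m = spec.n_classes, spec.n_noise_inputs
    true = rng.integers(0, C, size=n_samples)
    coins = rng.choice([-1.0, 1.0], size=(n_samples, m))
    X = _proto_inputs(spec, true, coins)
    labels = true.copy()
    if spec.label_noise > 0:
        flip = rng.random(n_samples) < spec.label_noise
        shift = rng.integers(1, C, size=n_samples)
        labels[flip] = (labels[flip] + shift[flip]) % C
    return LabeledDataset(X, labels, C)
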