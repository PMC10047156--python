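"""Feed-forward tanh networks: training, composition, lesioning, evaluation.

The networks in scope have a single hidden layer, hyperbolic-tangent units in
both the hidden and output layer, and an argmax readout over the output
activations.  They are trained with Adam on a mean-squared-error loss against
one-hot targets coded in {-1, +1} (the tanh range), stopping at the first
epoch whose training accuracy reaches a target, or at a fixed epoch cap.

Two structural operations matter downstream:

* :func:`compose` assembles a wide network from independently trained
  one-vs-rest sub-networks, so that the two hidden nodes of sub-network *i*
  are, by construction, the only carriers of class-*i* information — a
  positive control with known ground-truth relays.
* :func:`knockout` lesions hidden nodes by zeroing their incoming weights,
  bias and outgoing weights.  Because tanh(0) = 0 this is exactly equivalent
  to clamping the node's activation to zero during the forward pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import LabeledDataset

__all__ = [
    "Network",
    "TrainConfig",
    "StateTable",
    "TrainingDivergenceError",
    "train",
    "compose",
    "knockout",
    "forward_clamped",
    "record_states",
    "evaluate_accuracy",
    "TanhNetClassifier",
]


class TrainingDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class Network:
    """A single-hidden-layer tanh network with argmax readout.

    ``weights[k]`` has shape (units_out, units_in); activations propagate as
    ``a_out = tanh(W @ a_in + b)``.  Ties in the argmax readout resolve to the
    lowest output index.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        self.weights = [np.asarray(w, dtype=float) for w in self.weights]
        self.biases = [np.asarray(b, dtype=float) for b in self.biases]
        if len(self.weights) != 2 or len(self.biases) != 2:
            raise ValueError("exactly one hidden layer is supported (two weight matrices)")
        for w, b in zip(self.weights, self.biases):
            if w.ndim != 2 or b.ndim != 1 or w.shape[0] != b.shape[0]:
                raise ValueError("weight/bias shapes are not conformant")
        if self.weights[1].shape[1] != self.weights[0].shape[0]:
            raise ValueError("hidden layer size disagrees between the two weight matrices")

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[1]

    @property
    def n_hidden(self) -> int:
        return self.weights[0].shape[0]

    @property
    def n_outputs(self) -> int:
        return self.weights[1].shape[0]

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (hidden, output) activation matrices for a batch of inputs."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} input features, got {X.shape[1]}")
        hidden = np.tanh(X @ self.weights[0].T + self.biases[0])
        output = np.tanh(hidden @ self.weights[1].T + self.biases[1])
        return hidden, output

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class per sample: argmax over outputs (lowest index wins
        ties); for a single-output net, 1 if the activation is positive."""
        _, out = self.forward(X)
        if self.n_outputs == 1:
            return (out[:, 0] > 0.0).astype(int)
        return np.argmax(out, axis=1)

    def copy(self) -> "Network":
        return Network([w.copy() for w in self.weights], [b.copy() for b in self.biases])

    # ------------------------------------------------------------------ I/O
    def to_json(self, path: str | Path) -> None:
        """Write the network as a JSON document (row-major weight arrays).

        Round-trips exactly: JSON serialises doubles via ``repr`` so every
        weight is restored bit-for-bit.
        """
        doc = {
            "format": "relaytrace-network",
            "version": 1,
            "layer_sizes": [self.n_inputs, self.n_hidden, self.n_outputs],
            "activation": "tanh",
            "readout": "argmax",
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "Network":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "relaytrace-network":
            raise ValueError("not a relaytrace network file")
        return cls([np.array(w) for w in doc["weights"]], [np.array(b) for b in doc["biases"]])


@dataclass
class TrainConfig:
    """Optimisation settings for :func:`train`.

    ``target_accuracy`` is the early-stopping criterion: training halts at
    the first epoch whose overall training-set accuracy reaches it.
    """

    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    target_accuracy: float = 0.96
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_accuracy <= 1.0:
            raise ValueError("target_accuracy must lie in [0, 1]")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class StateTable:
    """Per-sample record of the channel: true label, predicted label, and the
    continuous hidden activations (the precursor of the discrete variable Y)."""

    input_label: np.ndarray
    predicted_label: np.ndarray
    hidden_activations: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        n = len(self.input_label)
        if len(self.predicted_label) != n or self.hidden_activations.shape[0] != n:
            raise ValueError("state-table columns are not aligned by sample")

    @property
    def n_samples(self) -> int:
        return len(self.input_label)

    @property
    def n_hidden(self) -> int:
        return self.hidden_activations.shape[1]


def _one_hot_targets(labels: np.ndarray, n_outputs: int) -> np.ndarray:
    # Targets in the tanh range: +1 for the true class, -1 elsewhere.
    if n_outputs == 1:
        return np.where(labels[:, None] == 1, 1.0, -1.0)
    t = -np.ones((labels.size, n_outputs))
    t[np.arange(labels.size), labels] = 1.0
    return t


def evaluate_accuracy(net: Network, dataset: LabeledDataset) -> tuple[float, np.ndarray]:
    """Overall accuracy and the per-class recall vector.

    Recall of class i is the fraction of class-i samples predicted as i;
    classes absent from the dataset get NaN.
    """
    pred = net.predict(dataset.features)
    overall = float(np.mean(pred == dataset.labels))
    n_classes = 2 if net.n_outputs == 1 else net.n_outputs
    recalls = np.full(n_classes, np.nan)
    for c in range(n_classes):
        mask = dataset.labels == c
        if mask.any():
            recalls[c] = float(np.mean(pred[mask] == c))
    return overall, recalls


def train(
    dataset: LabeledDataset,
    arch: Sequence[int],
    cfg: TrainConfig | None = None,
) -> tuple[Network, pd.DataFrame]:
    """Train a tanh network with Adam on MSE against ±1 one-hot targets.

    Parameters
    ----------
    dataset : LabeledDataset
        Training data; for a one-output net the labels must be binary
        (1 = positive class), coded as targets +1 / -1.
    arch : (n_inputs, n_hidden, n_outputs)
        Layer sizes.  ``n_outputs`` is C for a full classifier or 1 for a
        one-vs-rest sub-network.
    cfg : TrainConfig

    Returns
    -------
    (Network, history) where history is a DataFrame with one row per epoch:
    loss, overall accuracy and per-class recall.  Training stops at the first
    epoch whose accuracy reaches ``cfg.target_accuracy``, else at
    ``cfg.max_epochs``.
    """
    cfg = cfg or TrainConfig()
    arch = tuple(int(a) for a in arch)
    if len(arch) != 3:
        raise ValueError("arch must be (n_inputs, n_hidden, n_outputs)")
    if arch[0] != dataset.n_features:
        raise ValueError(f"arch input size {arch[0]} != feature count {dataset.n_features}")
    if arch[2] not in (1, dataset.n_classes):
        raise ValueError(
            f"arch output size {arch[2]} must be 1 (sub-net) or n_classes={dataset.n_classes}"
        )

    rng = np.random.default_rng(cfg.seed)
    params = []
    for fan_in, fan_out in zip(arch[:-1], arch[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        params.append(rng.uniform(-bound, bound, size=(fan_out, fan_in)))
        params.append(np.zeros(fan_out))
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    t = 0

    X = dataset.features
    targets = _one_hot_targets(dataset.labels, arch[2])
    n = X.shape[0]
    history: list[dict] = []

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, tb = X[idx], targets[idx]
            W1, b1, W2, b2 = params
            h = np.tanh(xb @ W1.T + b1)
            o = np.tanh(h @ W2.T + b2)
            err = o - tb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise TrainingDivergenceError(f"non-finite loss at epoch {epoch}")
            epoch_loss += loss * len(idx)
            # Backprop through the two tanh layers.
            d_o = (2.0 / err.size) * err * (1.0 - o**2)
            d_h = (d_o @ W2) * (1.0 - h**2)
            grads = [d_h.T @ xb, d_h.sum(axis=0), d_o.T @ h, d_o.sum(axis=0)]
            t += 1
            for k, g in enumerate(grads):
                m[k] = cfg.beta1 * m[k] + (1 - cfg.beta1) * g
                v[k] = cfg.beta2 * v[k] + (1 - cfg.beta2) * g**2
                m_hat = m[k] / (1 - cfg.beta1**t)
                v_hat = v[k] / (1 - cfg.beta2**t)
                params[k] = params[k] - cfg.learning_rate * m_hat / (np.sqrt(v_hat) + cfg.eps)

        net = Network([params[0], params[2]], [params[1], params[3]])
        acc, recalls = evaluate_accuracy(net, dataset)
        history.append(
            {
                "epoch": epoch,
                "loss": epoch_loss / n,
                "accuracy": acc,
                **{f"recall_{c}": r for c, r in enumerate(recalls)},
            }
        )
        if acc >= cfg.target_accuracy:
            break

    return Network([params[0], params[2]], [params[1], params[3]]), pd.DataFrame(history)


def compose(subnets: Sequence[Network]) -> Network:
    """Assemble one-vs-rest sub-networks into a composite classifier.

    Each sub-network must have two hidden nodes and one output.  Sub-network
    *i* occupies hidden slots (2i, 2i+1) and output *i*; all cross-block
    entries of the hidden-to-output matrix are exactly 0.0, so the composite's
    second-layer matrix is de facto sparse and output *i* depends on hidden
    slots (2i, 2i+1) only.  No further training is applied.
    """
    subnets = list(subnets)
    if not subnets:
        raise ValueError("need at least one sub-network")
    n_in = subnets[0].n_inputs
    for k, sn in enumerate(subnets):
        if sn.n_inputs != n_in:
            raise ValueError(f"sub-net {k} input size {sn.n_inputs} != {n_in}")
        if sn.n_hidden != 2 or sn.n_outputs != 1:
            raise ValueError(f"sub-net {k} must be (input)-2-1, got {sn.n_hidden}-{sn.n_outputs}")
    k = len(subnets)
    W1 = np.vstack([sn.weights[0] for sn in subnets])
    b1 = np.concatenate([sn.biases[0] for sn in subnets])
    W2 = np.zeros((k, 2 * k))
    b2 = np.zeros(k)
    for i, sn in enumerate(subnets):
        W2[i, 2 * i : 2 * i + 2] = sn.weights[1][0]
        b2[i] = sn.biases[1][0]
    return Network([W1, W2], [b1, b2])


def _check_hidden_indices(net: Network, nodes: Iterable[int]) -> np.ndarray:
    idx = np.asarray(sorted(set(int(i) for i in nodes)), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= net.n_hidden):
        raise IndexError(f"hidden indices out of range [0, {net.n_hidden})")
    return idx


def knockout(net: Network, nodes: Iterable[int]) -> Network:
    """Lesion hidden nodes: zero their incoming weights, bias and outgoing
    weights.  Equivalent to clamping their activations to 0 (tanh(0) = 0)."""
    idx = _check_hidden_indices(net, nodes)
    out = net.copy()
    if idx.size:
        out.weights[0][idx, :] = 0.0
        out.biases[0][idx] = 0.0
        out.weights[1][:, idx] = 0.0
    return out


def forward_clamped(
    net: Network, nodes: Iterable[int], X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass with the listed hidden activations clamped to 0.0 — the
    alternative knockout construction; bit-identical to :func:`knockout`."""
    idx = _check_hidden_indices(net, nodes)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    hidden = np.tanh(X @ net.weights[0].T + net.biases[0])
    if idx.size:
        hidden[:, idx] = 0.0
    output = np.tanh(hidden @ net.weights[1].T + net.biases[1])
    return hidden, output


def record_states(net: Network, dataset: LabeledDataset) -> StateTable:
    """Run the network over a dataset and record labels, predictions and
    hidden activations, aligned by sample."""
    hidden, out = net.forward(dataset.features)
    if net.n_outputs == 1:
        pred = (out[:, 0] > 0.0).astype(int)
    else:
        pred = np.argmax(out, axis=1)
    n_classes = max(dataset.n_classes, 2 if net.n_outputs == 1 else net.n_outputs)
    return StateTable(dataset.labels.copy(), pred, hidden, n_classes)


class TanhNetClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator facade over :func:`train`.

    Parameters mirror :class:`TrainConfig`; ``output_units`` may be set to 1
    to train a one-vs-rest sub-network on binary labels (decision threshold
    at activation 0).

    Attributes
    ----------
    network_ : Network
        The trained tanh network.
    history_ : pandas.DataFrame
        Per-epoch loss/accuracy/recall trace.
    classes_ : ndarray
        Sorted class labels seen in ``fit``.
    """

    def __init__(
        self,
        hidden_units: int = 20,
        output_units: int | None = None,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        max_epochs: int = 200,
        target_accuracy: float = 0.96,
        random_state: int = 0,
    ):
        self.hidden_units = hidden_units
        self.output_units = output_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.target_accuracy = target_accuracy
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        n_out = self.output_units or len(self.classes_)
        ds = LabeledDataset(X, y, n_classes=max(len(self.classes_), int(y.max()) + 1))
        cfg = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            target_accuracy=self.target_accuracy,
            seed=self.random_state,
        )
        self.network_, self.history_ = train(ds, (X.shape[1], self.hidden_units, n_out), cfg)
        return self

    def predict(self, X):
        check_is_fitted(self, "network_")
        return self.network_.predict(np.asarray(X, dtype=float))
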