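"""Coarse-graining of continuous hidden activations into binary symbols.

Discrete entropy estimation needs discrete states, so each hidden neuron's
activation (confined to [-1, 1] by tanh) is mapped to {0, 1} independently of
the other neurons.  Two rules are available:

* ``kmeans`` (default): a one-dimensional two-cluster k-means per neuron.
  Cluster 0 is the lower-centroid cluster; a value equidistant from both
  centroids goes to cluster 0.  This adapts the split to the neuron's actual
  activation distribution instead of forcing each bin to hold half the mass.
* ``median``: threshold at the neuron's median, the maximum-entropy split
  (each bin receives half of the values on even sample counts).

A neuron whose activations are (near-)constant carries no entropy either way
and is mapped entirely to bit 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .network import StateTable

__all__ = ["HiddenBinarizer", "DiscreteStateTable", "fit_binarizer", "binarize"]


@dataclass
class DiscreteStateTable:
    """Per-sample discrete symbols: the substrate of all entropy estimation.

    Columns: the input class variable Xin (``input_label``), the predicted
    class Xout (``predicted_label``), and one binary column per hidden neuron
    (the variable Y).  Class indicators Z_i = [label == i] and
    Xout^(i) = [predicted == i] are derived on demand.

    ``weights`` holds per-row probabilities for analytically exact tables
    (rows enumerate the joint distribution rather than sample it); ``None``
    means equal weight per sample.
    """

    input_label: np.ndarray
    predicted_label: np.ndarray
    hidden_bits: np.ndarray
    n_classes: int
    weights: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.input_label = np.asarray(self.input_label, dtype=int)
        self.predicted_label = np.asarray(self.predicted_label, dtype=int)
        self.hidden_bits = np.asarray(self.hidden_bits, dtype=np.uint8)
        n = self.input_label.size
        if self.predicted_label.size != n or self.hidden_bits.shape[0] != n:
            raise ValueError("table columns are not aligned by sample")
        if self.hidden_bits.size and self.hidden_bits.max() > 1:
            raise ValueError("hidden_bits must be binary")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.size != n:
                raise ValueError("weights are not aligned by sample")
            total = self.weights.sum()
            if not np.isclose(total, 1.0):
                self.weights = self.weights / total

    @property
    def n_samples(self) -> int:
        return self.input_label.size

    @property
    def n_hidden(self) -> int:
        return self.hidden_bits.shape[1]

    def input_indicator(self, i: int) -> np.ndarray:
        """Z_i: 1 where the true label is class i."""
        self._check_class(i)
        return (self.input_label == i).astype(np.uint8)

    def output_indicator(self, i: int) -> np.ndarray:
        """Xout^(i): 1 where the predicted label is class i."""
        self._check_class(i)
        return (self.predicted_label == i).astype(np.uint8)

    def _check_class(self, i: int) -> None:
        if not 0 <= i < self.n_classes:
            raise ValueError(f"class {i} outside {{0..{self.n_classes - 1}}}")

    def to_frame(self) -> pd.DataFrame:
        cols = {"label": self.input_label, "prediction": self.predicted_label}
        for j in range(self.n_hidden):
            cols[f"bit_{j}"] = self.hidden_bits[:, j]
        if self.weights is not None:
            cols["weight"] = self.weights
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_classes: int | None = None) -> "DiscreteStateTable":
        frame = pd.read_csv(path)
        bit_cols = [c for c in frame.columns if c.startswith("bit_")]
        weights = frame["weight"].to_numpy() if "weight" in frame.columns else None
        labels = frame["label"].to_numpy(dtype=int)
        preds = frame["prediction"].to_numpy(dtype=int)
        if n_classes is None:
            n_classes = int(max(labels.max(), preds.max())) + 1
        return cls(labels, preds, frame[bit_cols].to_numpy(dtype=np.uint8), n_classes, weights)


def _kmeans_1d(values: np.ndarray, tol: float, max_iter: int = 300) -> tuple[float, float]:
    """Two-cluster Lloyd iteration on a 1-D array, initialised at (min, max).

    Deterministic: for two ordered centroids the assignment is a threshold at
    their midpoint, so iterating the midpoint until the partition is stable
    solves the problem exactly.  Returns ordered centroids (c0 <= c1).
    """
    lo, hi = float(values.min()), float(values.max())
    if hi - lo <= tol:
        return lo, hi  # degenerate: caller maps everything to bit 0
    c0, c1 = lo, hi
    prev_split = None
    for _ in range(max_iter):
        mid = 0.5 * (c0 + c1)
        upper = values > mid
        n_up = int(upper.sum())
        if n_up == 0 or n_up == values.size:
            break
        if prev_split == n_up:
            break
        prev_split = n_up
        c0 = float(values[~upper].mean())
        c1 = float(values[upper].mean())
    return c0, c1


class HiddenBinarizer(TransformerMixin, BaseEstimator):
    """Per-neuron binarizer for hidden activations (scikit-learn transformer).

    Parameters
    ----------
    method : {"kmeans", "median"}
        Coarse-graining rule (see module docstring).
    degenerate_tol : float
        Activation ranges at or below this are treated as constant neurons.
    random_state : int
        Recorded for provenance; the fit itself is deterministic (k-means is
        initialised at each neuron's min/max).

    Attributes
    ----------
    centroids_ : ndarray of shape (n_neurons, 2)
        Ordered k-means centroids per neuron (kmeans method).
    thresholds_ : ndarray of shape (n_neurons,)
        Decision threshold per neuron: the centroid midpoint for kmeans, the
        median for the median method.
    degenerate_ : ndarray of bool
        Neurons flagged as constant; all their samples map to bit 0.
    """

    def __init__(self, method: str = "kmeans", degenerate_tol: float = 1e-9, random_state: int = 0):
        self.method = method
        self.degenerate_tol = degenerate_tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples to fit a binarizer")
        if self.method not in ("kmeans", "median"):
            raise ValueError("method must be 'kmeans' or 'median'")
        n_neurons = X.shape[1]
        self.degenerate_ = np.ptp(X, axis=0) <= self.degenerate_tol
        if self.method == "kmeans":
            self.centroids_ = np.empty((n_neurons, 2))
            for j in range(n_neurons):
                self.centroids_[j] = _kmeans_1d(X[:, j], self.degenerate_tol)
            self.thresholds_ = self.centroids_.mean(axis=1)
        else:
            self.thresholds_ = np.median(X, axis=0)
        self.n_features_in_ = n_neurons
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "thresholds_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"binarizer fitted on {self.n_features_in_} neurons, got {X.shape[1]}"
            )
        # Strict inequality: a value at the threshold (equidistant from both
        # k-means centroids, or equal to the median) goes to bit 0.
        bits = (X > self.thresholds_).astype(np.uint8)
        bits[:, self.degenerate_] = 0
        return bits

    def to_dict(self) -> dict:
        check_is_fitted(self, "thresholds_")
        doc = {
            "method": self.method,
            "thresholds": self.thresholds_.tolist(),
            "degenerate": self.degenerate_.astype(bool).tolist(),
        }
        if self.method == "kmeans":
            doc["centroids"] = self.centroids_.tolist()
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "HiddenBinarizer":
        b = cls(method=doc["method"])
        b.thresholds_ = np.asarray(doc["thresholds"], dtype=float)
        b.degenerate_ = np.asarray(doc["degenerate"], dtype=bool)
        if "centroids" in doc:
            b.centroids_ = np.asarray(doc["centroids"], dtype=float)
        b.n_features_in_ = b.thresholds_.size
        return b


def fit_binarizer(states: StateTable, method: str = "kmeans", seed: int = 0) -> HiddenBinarizer:
    """Fit a per-neuron binarizer on the hidden activations of a state table."""
    return HiddenBinarizer(method=method, random_state=seed).fit(states.hidden_activations)


def binarize(states: StateTable, binarizer: HiddenBinarizer) -> DiscreteStateTable:
    """Map a continuous state table to discrete symbols using a fitted binarizer."""
    bits = binarizer.transform(states.hidden_activations)
    return DiscreteStateTable(
        states.input_label, states.predicted_label, bits, states.n_classes
    )
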