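"""Plug-in discrete entropy, co-information, and relay information.

The network is treated as a channel from the input class variable Xin to the
predicted class Xout via the binarized hidden layer Y.  For a disjoint split
Y = YR ⊗ Y0 of the hidden nodes, the *relay information*

    I_R = I(Xin; Xout; YR | Y0)

is the three-way co-information between input, output and the candidate relay
set, with every entropy term conditioned on the complementary set Y0.
Conditioning on Y0 shields the measure from inert nodes that merely copy a
relay's state: a copy in Y0 makes the relay's conditional contribution vanish
instead of being double-counted.

The *particular* relay information restricts the channel to one class i by
replacing Xin with the indicator Z_i = [label = i] and Xout with
Xout^(i) = [prediction = i].

All entropies are plug-in (maximum-likelihood) estimates in base 2, computed
from the empirical frequencies of observed tuples only; tables may carry
per-row probability weights, in which case the estimate is exact for the
distribution the rows enumerate.  An optional Miller–Madow bias correction is
available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .discretize import DiscreteStateTable

__all__ = [
    "VariableSelection",
    "InfoResult",
    "joint_entropy",
    "mutual_information",
    "co_information",
    "relay_information",
    "particular_relay_information",
]

# Column identifiers understood by the table-level operations: the strings
# "input" / "output" (class variables), ("input", i) / ("output", i)
# (class-i indicators), an integer hidden-node index, or a raw array.
ColumnSpec = object


@dataclass(frozen=True)
class VariableSelection:
    """A disjoint split of the hidden nodes into relay set YR and
    conditioning set Y0, optionally restricted to one class."""

    relay: tuple[int, ...]
    condition: tuple[int, ...] = ()
    target: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "relay", tuple(int(i) for i in self.relay))
        object.__setattr__(self, "condition", tuple(int(i) for i in self.condition))
        if set(self.relay) & set(self.condition):
            raise ValueError("relay set YR and conditioning set Y0 must be disjoint")


@dataclass(frozen=True)
class InfoResult:
    """An information estimate in bits with its provenance."""

    value: float
    n_samples: int
    selection: VariableSelection


def _resolve(table: DiscreteStateTable, var: ColumnSpec) -> np.ndarray:
    if isinstance(var, str):
        if var == "input":
            return table.input_label
        if var == "output":
            return table.predicted_label
        raise ValueError(f"unknown column identifier {var!r}")
    if isinstance(var, tuple) and len(var) == 2 and isinstance(var[0], str):
        side, i = var
        if side == "input":
            return table.input_indicator(int(i))
        if side == "output":
            return table.output_indicator(int(i))
        raise ValueError(f"unknown column identifier {var!r}")
    if isinstance(var, (int, np.integer)):
        if not 0 <= int(var) < table.n_hidden:
            raise IndexError(f"hidden index {var} out of range")
        return table.hidden_bits[:, int(var)]
    arr = np.asarray(var)
    if arr.ndim == 1:
        return arr
    raise ValueError("column spec must resolve to a 1-D array")


def _stack(table: DiscreteStateTable, columns: Sequence[ColumnSpec]) -> np.ndarray:
    cols = [_resolve(table, c) for c in columns]
    return np.column_stack(cols).astype(np.int64)


def _entropy_bits(matrix: np.ndarray, weights: np.ndarray | None, bias_correction: bool) -> float:
    """Plug-in joint entropy of the rows of an integer matrix, in bits."""
    n = matrix.shape[0]
    # Pack each row into a single integer key (mixed-radix over columns).
    key = np.zeros(n, dtype=np.int64)
    radix = 1
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        lo, hi = int(col.min()), int(col.max())
        card = hi - lo + 1
        if radix > (2**62) // max(card, 1):
            return _entropy_bits_rows(matrix, weights, bias_correction)
        key += (col - lo) * radix
        radix *= card
    _, inverse = np.unique(key, return_inverse=True)
    if weights is None:
        counts = np.bincount(inverse).astype(float)
        p = counts / n
    else:
        p = np.bincount(inverse, weights=weights)
        p = p[p > 0]
    h = float(-np.sum(p * np.log2(p, where=p > 0, out=np.zeros_like(p))))
    if bias_correction and weights is None:
        h += (p.size - 1) / (2.0 * n * np.log(2.0))
    return h


def _entropy_bits_rows(matrix, weights, bias_correction):
    # Fallback for very wide tables: group full rows.
    _, inverse = np.unique(matrix, axis=0, return_inverse=True)
    n = matrix.shape[0]
    if weights is None:
        p = np.bincount(inverse).astype(float) / n
    else:
        p = np.bincount(inverse, weights=weights)
        p = p[p > 0]
    h = float(-np.sum(p * np.log2(p, where=p > 0, out=np.zeros_like(p))))
    if bias_correction and weights is None:
        h += (p.size - 1) / (2.0 * n * np.log(2.0))
    return h


def joint_entropy(
    table: DiscreteStateTable,
    columns: Sequence[ColumnSpec],
    bias_correction: bool = False,
) -> float:
    """Joint entropy H of the selected columns, in bits.

    Empirical (plug-in) estimate over observed tuples; exact when the table
    carries enumeration weights.
    """
    columns = list(columns)
    if not columns:
        raise ValueError("joint_entropy needs at least one column")
    if table.n_samples == 0:
        raise ValueError("empty table")
    return _entropy_bits(_stack(table, columns), table.weights, bias_correction)


def mutual_information(
    table: DiscreteStateTable,
    x: Sequence[ColumnSpec] | ColumnSpec,
    y: Sequence[ColumnSpec] | ColumnSpec,
    bias_correction: bool = False,
) -> float:
    """I(X;Y) = H(X) + H(Y) - H(X,Y), in bits.  Symmetric in its arguments."""
    gx, gy = _as_group(x), _as_group(y)
    h = lambda cols: joint_entropy(table, cols, bias_correction)
    return h(gx) + h(gy) - h(gx + gy)


def co_information(
    table: DiscreteStateTable,
    x: Sequence[ColumnSpec] | ColumnSpec,
    y: Sequence[ColumnSpec] | ColumnSpec,
    z: Sequence[ColumnSpec] | ColumnSpec,
    bias_correction: bool = False,
) -> float:
    """Three-way co-information I(X;Y;Z) by inclusion–exclusion:

        H(X)+H(Y)+H(Z) - H(X,Y) - H(X,Z) - H(Y,Z) + H(X,Y,Z)

    Invariant under permutation of the three groups; can be negative (the
    XOR of two fair bits has co-information -1 with its inputs).
    """
    gx, gy, gz = _as_group(x), _as_group(y), _as_group(z)
    h = lambda cols: joint_entropy(table, cols, bias_correction)
    return (
        h(gx) + h(gy) + h(gz)
        - h(gx + gy) - h(gx + gz) - h(gy + gz)
        + h(gx + gy + gz)
    )


def _as_group(x) -> list:
    if isinstance(x, (list, tuple)) and not (
        len(x) == 2 and isinstance(x[0], str)
    ):
        return list(x)
    return [x]


def relay_information(
    table: DiscreteStateTable,
    relay: Sequence[int],
    condition: Sequence[int] = (),
    target: int | None = None,
    bias_correction: bool = False,
) -> float:
    """Relay information I_R = I(Xin; Xout; YR | Y0), in bits.

    The co-information of (input, output, YR) with every entropy term
    conditioned on Y0 via H(·|Y0) = H(·, Y0) - H(Y0).  With Y0 = ∅ this
    reduces exactly to :func:`co_information`; with YR = ∅ it is 0 by
    convention (no relay).

    ``target`` selects the particular relay information for one class:
    input/output are replaced by the indicators Z_i and Xout^(i).
    """
    sel = VariableSelection(tuple(relay), tuple(condition), target)
    if not sel.relay:
        return 0.0
    for i in sel.relay + sel.condition:
        if not 0 <= i < table.n_hidden:
            raise IndexError(f"hidden index {i} out of range")
    if target is None:
        a: ColumnSpec = "input"
        b: ColumnSpec = "output"
    else:
        a = ("input", target)
        b = ("output", target)
    r = list(sel.relay)
    c = list(sel.condition)
    h = lambda cols: joint_entropy(table, cols, bias_correction)
    signed = (
        h([a] + c) + h([b] + c) + h(r + c)
        - h([a, b] + c) - h([a] + r + c) - h([b] + r + c)
        + h([a, b] + r + c)
    )
    # Net -1 copy of H(Y0) from the seven conditionings (+3 -3 +1).
    h_c = h(c) if c else 0.0
    return signed - h_c


def particular_relay_information(
    table: DiscreteStateTable,
    target: int,
    relay: Sequence[int],
    condition: Sequence[int] = (),
    bias_correction: bool = False,
) -> float:
    """I_R(i) = I(Z_i; Xout^(i); YR | Y0): relay information about class i."""
    table._check_class(int(target))
    return relay_information(table, relay, condition, int(target), bias_correction)
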