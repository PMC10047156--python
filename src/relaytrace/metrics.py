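"""Node-level attribution derived from a greedy removal trajectory.

Three quantities describe each hidden node's role in relaying class
information:

* **ΔI(n)** — the relay information lost at the step where node n was
  removed: I_R(YR ∪ n | Y0) - I_R(YR | Y0 + n).  Summed over a complete
  trajectory these differences telescope to the full hidden layer's relay
  information.
* **Aggregated relay information I_A(n)** — the cumulative loss up to and
  including node n's removal step.  This exposes "encrypted" essential sets:
  when no member of a synergistic set can be removed without destroying all
  the information, the last members show ΔI ≈ 0 individually yet inherit the
  full loss through I_A.
* **Essentiality** — the loss when node n alone is dropped from the *full*
  hidden set: I_R(Y) - I_R(Y \\ n), both with empty conditioning set.  Zero
  for inert nodes and for nodes whose content is duplicated elsewhere (the
  co-information of the remainder is unchanged when a duplicate is dropped),
  so a node can rank high on I_A yet be non-essential.  Dropping the node
  without conditioning on it is what makes redundancy visible: moving it
  into the conditioning set instead would charge the node its individual
  co-information even when an exact copy remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discretize import DiscreteStateTable
from .info import relay_information
from .search import RemovalTrace, greedy_shrink, _full_set_info

__all__ = [
    "delta_information",
    "aggregated_relay_information",
    "essentiality",
    "AttributionReport",
    "attribution_report",
]


def _check_complete(trace: RemovalTrace) -> None:
    if not trace.steps:
        raise ValueError("empty trace")
    removed = trace.removal_order
    first = trace.steps[0].relay_before
    if sorted(removed) != sorted(first) or len(trace.steps[-1].relay_before) != 1:
        raise ValueError("trace is incomplete: every node must be removed exactly once")


def delta_information(trace: RemovalTrace) -> dict[int, float]:
    """ΔI per node from a complete greedy trace.

    ΔI of the node removed at a step is the step's information before
    removal minus the information after.  Negative values can occur from
    sampling noise in the entropy estimates and are kept (not clipped).
    """
    _check_complete(trace)
    return {s.removed: s.info_before - s.info_after for s in trace.steps}


def aggregated_relay_information(trace: RemovalTrace) -> dict[int, float]:
    """I_A per node: the running sum of ΔI over removal order, so the node
    removed last carries the full hidden layer's relay information."""
    delta = delta_information(trace)
    out: dict[int, float] = {}
    running = 0.0
    for node in trace.removal_order:
        running += delta[node]
        out[node] = running
    return out


def essentiality(
    table: DiscreteStateTable,
    node: int,
    target: int | None = None,
    bias_correction: bool = False,
) -> float:
    """Information lost when ``node`` alone is dropped from the full hidden
    set: I_R(Y) - I_R(Y - n), both unconditioned.  Vanishes for inert nodes
    and for nodes with an exact duplicate in the remainder."""
    if not 0 <= node < table.n_hidden:
        raise IndexError(f"hidden index {node} out of range")
    full = _full_set_info(table, target)
    rest = [i for i in range(table.n_hidden) if i != node]
    return full - relay_information(table, rest, [], target, bias_correction)


@dataclass
class AttributionReport:
    """Per-node, per-class attribution matrices (rows = hidden nodes,
    columns = classes), plus the greedy traces they derive from."""

    delta_info: pd.DataFrame
    aggregated_info: pd.DataFrame
    essentiality: pd.DataFrame
    removal_rank: pd.DataFrame
    traces: dict[int, RemovalTrace]

    def to_csv(self, directory, prefix: str = "attribution") -> list[str]:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in [
            ("delta_info", self.delta_info),
            ("aggregated_info", self.aggregated_info),
            ("essentiality", self.essentiality),
            ("removal_rank", self.removal_rank),
        ]:
            path = directory / f"{prefix}_{name}.csv"
            frame.to_csv(path)
            written.append(str(path))
        return written


def attribution_report(
    table: DiscreteStateTable,
    classes: list[int] | None = None,
    bias_correction: bool = False,
) -> AttributionReport:
    """Run the greedy search per class and assemble ΔI, I_A, essentiality and
    removal-rank matrices (hidden nodes × classes)."""
    classes = list(range(table.n_classes)) if classes is None else list(classes)
    nodes = list(range(table.n_hidden))
    mats = {name: np.zeros((len(nodes), len(classes))) for name in ("d", "a", "e", "r")}
    traces: dict[int, RemovalTrace] = {}
    for ci, c in enumerate(classes):
        trace = greedy_shrink(table, target=c, bias_correction=bias_correction)
        traces[c] = trace
        delta = delta_information(trace)
        agg = aggregated_relay_information(trace)
        for rank, node in enumerate(trace.removal_order, start=1):
            mats["d"][node, ci] = delta[node]
            mats["a"][node, ci] = agg[node]
            mats["r"][node, ci] = rank
        for node in nodes:
            mats["e"][node, ci] = essentiality(table, node, target=c,
                                               bias_correction=bias_correction)
    idx = pd.Index(nodes, name="node")
    cols = pd.Index(classes, name="class")
    return AttributionReport(
        delta_info=pd.DataFrame(mats["d"], index=idx, columns=cols),
        aggregated_info=pd.DataFrame(mats["a"], index=idx, columns=cols),
        essentiality=pd.DataFrame(mats["e"], index=idx, columns=cols),
        removal_rank=pd.DataFrame(mats["r"], index=idx, columns=cols, dtype=int),
        traces=traces,
    )
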