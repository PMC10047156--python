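"""Causal validation of informational findings via node knockouts.

If a hidden-node set truly relays the information used to recognise class i,
lesioning it should abrogate class-i performance.  The knockout effect K of a
set is the drop in class-i recall between the intact and the lesioned
network.  Because larger sets trivially tend to cause larger drops, set size
confounds the relation between relay information and knockout effect; a
multiple linear regression of K on (standardised) set size and particular
relay information separates the two, and single-predictor fits give each
predictor's own explained variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datasets import LabeledDataset
from .network import Network, evaluate_accuracy, knockout
from .search import RemovalTrace

__all__ = [
    "KnockoutRecord",
    "RegressionSummary",
    "knockout_effect",
    "build_knockout_panel",
    "regression_analysis",
]


@dataclass(frozen=True)
class KnockoutRecord:
    """One lesion experiment: the node set, its size, the class analysed, the
    particular relay information I_R(i) the set carried, and the measured
    knockout effect K (drop in class-i recall, in [-1, 1])."""

    nodes: tuple[int, ...]
    class_index: int
    set_size: int
    relay_info: float
    effect: float


@dataclass
class RegressionSummary:
    """Multiple-regression comparison of set size vs relay information as
    predictors of the knockout effect.

    ``coef_size`` / ``coef_info`` are the standardised multiple-regression
    coefficients; ``r2_size`` / ``r2_info`` are the r² of the two
    single-predictor fits; ``f_statistic`` is the ratio of their residual
    sums of squares (size-only over information-only: > 1 means relay
    information explains the effect better).
    """

    coef_size: float
    coef_info: float
    r2_multiple: float
    r2_size: float
    r2_info: float
    f_statistic: float
    f_pvalue: float
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "coef_size": self.coef_size,
            "coef_info": self.coef_info,
            "r2_multiple": self.r2_multiple,
            "r2_size": self.r2_size,
            "r2_info": self.r2_info,
            "f_statistic": self.f_statistic,
            "f_pvalue": self.f_pvalue,
            "n_obs": self.n_obs,
        }


def _recall(net: Network, dataset: LabeledDataset, class_index: int) -> float:
    mask = dataset.labels == class_index
    if not mask.any():
        raise ValueError(f"class {class_index} absent from dataset")
    pred = net.predict(dataset.features[mask])
    return float(np.mean(pred == class_index))


def knockout_effect(
    net: Network,
    dataset: LabeledDataset,
    nodes: Iterable[int],
    class_index: int,
    metric: str = "recall",
) -> float:
    """K = class-i recall of the intact network minus that of the lesioned
    network (``metric="overall"`` uses overall accuracy instead)."""
    nodes = tuple(nodes)
    lesioned = knockout(net, nodes)
    if metric == "recall":
        return _recall(net, dataset, class_index) - _recall(lesioned, dataset, class_index)
    if metric == "overall":
        return evaluate_accuracy(net, dataset)[0] - evaluate_accuracy(lesioned, dataset)[0]
    raise ValueError("metric must be 'recall' or 'overall'")


def build_knockout_panel(
    net: Network,
    dataset: LabeledDataset,
    traces: dict[int, RemovalTrace],
    metric: str = "recall",
) -> list[KnockoutRecord]:
    """Knock out every set along each class's greedy trajectory and score it.

    One record per (class, trajectory set); the empty set (K = 0 by
    definition) is excluded.  For N hidden nodes and C classes this yields
    N·C records.
    """
    records: list[KnockoutRecord] = []
    for class_index, trace in sorted(traces.items()):
        intact = _recall(net, dataset, class_index)
        for step in trace.steps:
            nodes = tuple(sorted(step.relay_before))
            lesioned = knockout(net, nodes)
            if metric == "recall":
                effect = intact - _recall(lesioned, dataset, class_index)
            else:
                effect = (
                    evaluate_accuracy(net, dataset)[0]
                    - evaluate_accuracy(lesioned, dataset)[0]
                )
            records.append(
                KnockoutRecord(nodes, class_index, len(nodes), step.info_before, effect)
            )
    return records


def panel_frame(records: Sequence[KnockoutRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "class": [r.class_index for r in records],
            "set_size": [r.set_size for r in records],
            "relay_info": [r.relay_info for r in records],
            "effect": [r.effect for r in records],
            "nodes": [" ".join(map(str, r.nodes)) for r in records],
        }
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance predictor")
    return (x - x.mean()) / sd


def regression_analysis(records: Sequence[KnockoutRecord]) -> RegressionSummary:
    """OLS of the knockout effect on z-scored set size and z-scored particular
    relay information, plus single-predictor fits and the F comparison of
    their residual sums of squares."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    size = np.array([r.set_size for r in records], dtype=float)
    info = np.array([r.relay_info for r in records], dtype=float)
    effect = np.array([r.effect for r in records], dtype=float)
    z_size, z_info = _zscore(size), _zscore(info)

    X = sm.add_constant(np.column_stack([z_size, z_info]))
    multi = sm.OLS(effect, X).fit()
    fit_size = sm.OLS(effect, sm.add_constant(z_size)).fit()
    fit_info = sm.OLS(effect, sm.add_constant(z_info)).fit()

    n = len(records)
    rss_size, rss_info = float(fit_size.ssr), float(fit_info.ssr)
    if rss_info > 0:
        f_stat = rss_size / rss_info
        f_p = float(stats.f.sf(f_stat, n - 2, n - 2))
    else:
        f_stat, f_p = float("inf"), 0.0
    return RegressionSummary(
        coef_size=float(multi.params[1]),
        coef_info=float(multi.params[2]),
        r2_multiple=float(multi.rsquared),
        r2_size=float(fit_size.rsquared),
        r2_info=float(fit_info.rsquared),
        f_statistic=f_stat,
        f_pvalue=f_p,
        n_obs=n,
    )
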