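"""Finding minimal informative subsets of hidden nodes.

Exhaustively testing every bi-partition Y = YR ⊗ Y0 of N hidden nodes costs
2^N - 1 relay-information evaluations.  The *shrinking subset aggregation*
algorithm exploits the fact that (at the distribution level) a subset can
never carry more relay information than its superset: starting from
YR = all nodes, it repeatedly evaluates every single-node removal
I_R(YR - a | Y0 + a) and permanently discards the node whose removal retains
the most information — i.e. the node that individually contributes least.
This costs exactly N(N+1)/2 evaluations and, absent redundant sets and
estimation noise, visits the most informative set of every size.

When information is stored redundantly (two node groups carrying the same
content), several equally informative sets exist and the greedy trajectory
commits to one of them arbitrarily; the exhaustive search reports all ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import warnings

from .discretize import DiscreteStateTable
from .info import co_information, relay_information

__all__ = [
    "TraceStep",
    "RemovalTrace",
    "SearchResult",
    "greedy_shrink",
    "exhaustive_search",
    "minimal_set",
    "RelaySubsetSelector",
]

_TIE_TOL = 1e-12


@dataclass
class TraceStep:
    """One greedy removal: the set before removal, its relay information, the
    candidate evaluations I_R(YR - a | Y0 + a) for every a, and the node
    removed (argmax retained information, ties to the lowest index)."""

    removed: int
    relay_before: tuple[int, ...]
    info_before: float
    candidate_info: dict[int, float]

    @property
    def info_after(self) -> float:
        return self.candidate_info[self.removed]


@dataclass
class RemovalTrace:
    """Ordered record of a complete greedy run (all nodes removed once)."""

    steps: list[TraceStep]
    target: int | None
    n_evaluations: int

    @property
    def full_info(self) -> float:
        """Relay information of the complete hidden set (Y0 = ∅)."""
        return self.steps[0].info_before if self.steps else 0.0

    @property
    def removal_order(self) -> list[int]:
        return [s.removed for s in self.steps]

    def sets_with_info(self) -> list[tuple[tuple[int, ...], float]]:
        """The trajectory as (YR, I_R) pairs, largest set first, ending with
        the empty set at 0 bits."""
        out = [(s.relay_before, s.info_before) for s in self.steps]
        out.append(((), 0.0))
        return out


@dataclass
class SearchResult:
    """Per-size best sets from either search method.

    ``per_size_sets`` keeps *all* sets tied (within 1e-12) for the per-size
    maximum — redundant variants are reported, not collapsed.
    """

    method: str
    target: int | None
    per_size_best: dict[int, float]
    per_size_sets: dict[int, list[tuple[int, ...]]]
    full_info: float
    n_evaluations: int = 0


def _full_set_info(table: DiscreteStateTable, target: int | None) -> float:
    """I_R of the complete hidden layer (Y0 = ∅), i.e. the plain
    co-information of input, output and Y."""
    hidden = list(range(table.n_hidden))
    if target is None:
        return co_information(table, "input", "output", hidden)
    return co_information(table, ("input", target), ("output", target), hidden)


def greedy_shrink(
    table: DiscreteStateTable,
    target: int | None = None,
    bias_correction: bool = False,
) -> RemovalTrace:
    """Run the shrinking subset aggregation algorithm to completion.

    Starts with YR = all hidden nodes, Y0 = ∅.  Each step evaluates
    I_R(YR - a | Y0 + a) for every a in YR and permanently moves the node
    whose removal retains the most information into Y0 (ties break to the
    lowest node index).  Repeats until YR is empty: exactly N(N+1)/2
    relay-information evaluations for N nodes.

    ``target=None`` searches on the global relay information; an integer
    class searches on the particular relay information for that class.
    """
    n = table.n_hidden
    if n < 1:
        raise ValueError("table has no hidden nodes")
    relay = list(range(n))
    cond: list[int] = []
    info_before = _full_set_info(table, target)
    steps: list[TraceStep] = []
    n_evals = 0
    while relay:
        candidates: dict[int, float] = {}
        for a in relay:
            trial_relay = [x for x in relay if x != a]
            trial_cond = cond + [a]
            candidates[a] = relay_information(
                table, trial_relay, trial_cond, target, bias_correction
            )
            n_evals += 1
        best = relay[0]
        for a in relay[1:]:
            if candidates[a] > candidates[best] + _TIE_TOL:
                best = a
        steps.append(TraceStep(best, tuple(relay), info_before, candidates))
        info_before = candidates[best]
        relay.remove(best)
        cond.append(best)
    return RemovalTrace(steps, target, n_evals)


def exhaustive_search(
    table: DiscreteStateTable,
    target: int | None = None,
    bias_correction: bool = False,
    hard_cap: int = 20,
) -> SearchResult:
    """Evaluate I_R for every nonempty bi-partition (YR, Y0 = complement).

    2^N - 1 evaluations; refuses above ``hard_cap`` nodes and warns above 16
    (use :func:`greedy_shrink` instead at scale).
    """
    n = table.n_hidden
    if n > hard_cap:
        raise ValueError(
            f"exhaustive search over {n} nodes needs 2^{n}-1 evaluations; "
            "use greedy_shrink for layers this wide"
        )
    if n > 16:
        warnings.warn(f"exhaustive search over {n} nodes: 2^{n}-1 evaluations", stacklevel=2)
    all_nodes = list(range(n))
    per_size_best: dict[int, float] = {}
    per_size_sets: dict[int, list[tuple[int, ...]]] = {}
    n_evals = 0
    for size in range(1, n + 1):
        best_val = -float("inf")
        best_sets: list[tuple[int, ...]] = []
        for relay in combinations(all_nodes, size):
            cond = [x for x in all_nodes if x not in relay]
            val = relay_information(table, relay, cond, target, bias_correction)
            n_evals += 1
            if val > best_val + _TIE_TOL:
                best_val = val
                best_sets = [relay]
            elif abs(val - best_val) <= _TIE_TOL:
                best_sets.append(relay)
        per_size_best[size] = best_val
        per_size_sets[size] = best_sets
    return SearchResult(
        "exhaustive", target, per_size_best, per_size_sets,
        full_info=per_size_best[n], n_evaluations=n_evals,
    )


def trace_to_result(trace: RemovalTrace) -> SearchResult:
    """View a greedy trajectory as a per-size result (one set per size)."""
    per_size_best = {len(s.relay_before): s.info_before for s in trace.steps}
    per_size_sets = {len(s.relay_before): [s.relay_before] for s in trace.steps}
    return SearchResult(
        "greedy", trace.target, per_size_best, per_size_sets,
        full_info=trace.full_info, n_evaluations=trace.n_evaluations,
    )


def minimal_set(
    source: RemovalTrace | SearchResult, epsilon: float = 0.05
) -> tuple[int, ...]:
    """The smallest candidate set retaining at least (1 - epsilon) of the
    full hidden layer's relay information.

    From a greedy trace the candidates are the trajectory sets (including the
    empty set at 0 bits); from an exhaustive result, the per-size maxima.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if isinstance(source, RemovalTrace):
        candidates = source.sets_with_info()
        full = source.full_info
    else:
        candidates = [
            (sets[0], source.per_size_best[size])
            for size, sets in sorted(source.per_size_sets.items())
        ]
        candidates.append(((), 0.0))
        full = source.full_info
    threshold = (1.0 - epsilon) * full
    best: tuple[int, ...] | None = None
    for relay, info in candidates:
        if info >= threshold - _TIE_TOL:
            if best is None or len(relay) < len(best):
                best = tuple(sorted(relay))
    if best is None:  # full set always qualifies (epsilon >= 0)
        best = tuple(sorted(candidates[0][0]))
    return best


class RelaySubsetSelector:
    """Estimator-style wrapper: fit a subset search on a discrete state table.

    Parameters
    ----------
    target : int or None
        Class index for particular relay information; None for the global
        measure.
    method : {"greedy", "exhaustive"}
    epsilon : float
        Relative information tolerance defining the minimal set.
    bias_correction : bool
        Apply the Miller–Madow correction to every entropy estimate.

    Attributes (after ``fit``)
    --------------------------
    trace_ : RemovalTrace (greedy method only)
    result_ : SearchResult
    minimal_set_ : tuple of node indices
    full_info_ : float
    """

    def __init__(
        self,
        target: int | None = None,
        method: str = "greedy",
        epsilon: float = 0.05,
        bias_correction: bool = False,
    ):
        self.target = target
        self.method = method
        self.epsilon = epsilon
        self.bias_correction = bias_correction

    def get_params(self, deep: bool = True) -> dict:
        return {
            "target": self.target,
            "method": self.method,
            "epsilon": self.epsilon,
            "bias_correction": self.bias_correction,
        }

    def set_params(self, **params) -> "RelaySubsetSelector":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, table: DiscreteStateTable, y=None) -> "RelaySubsetSelector":
        if self.method == "greedy":
            self.trace_ = greedy_shrink(table, self.target, self.bias_correction)
            self.result_ = trace_to_result(self.trace_)
            self.minimal_set_ = minimal_set(self.trace_, self.epsilon)
        elif self.method == "exhaustive":
            self.result_ = exhaustive_search(table, self.target, self.bias_correction)
            self.minimal_set_ = minimal_set(self.result_, self.epsilon)
        else:
            raise ValueError("method must be 'greedy' or 'exhaustive'")
        self.full_info_ = self.result_.full_info
        return self
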