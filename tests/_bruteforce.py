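"""Independent brute-force information measures for oracle tests.

Everything here tabulates full joint distributions as Python dictionaries
and computes conditional co-information from its defining decomposition
(a probability-weighted average of per-conditioning-state co-informations),
deliberately avoiding the packed-array/inclusion-exclusion path used by the
package.  Only for tiny tables.
"""

from __future__ import annotations

import math
from collections import defaultdict
from itertools import combinations

import numpy as np


def dist_from_rows(rows: np.ndarray, weights=None) -> dict[tuple, float]:
    """Empirical joint distribution of the rows of a matrix."""
    n = rows.shape[0]
    dist: dict[tuple, float] = defaultdict(float)
    for i in range(n):
        w = 1.0 / n if weights is None else float(weights[i])
        dist[tuple(int(v) for v in rows[i])] += w
    return dict(dist)


def entropy(dist: dict[tuple, float]) -> float:
    return -sum(p * math.log2(p) for p in dist.values() if p > 0)


def marginal(dist: dict[tuple, float], idx: list[int]) -> dict[tuple, float]:
    out: dict[tuple, float] = defaultdict(float)
    for state, p in dist.items():
        out[tuple(state[i] for i in idx)] += p
    return dict(out)


def brute_entropy(rows: np.ndarray, weights=None) -> float:
    return entropy(dist_from_rows(np.atleast_2d(rows), weights))


def co_information_of_dist(dist: dict[tuple, float], a, b, c) -> float:
    """I(A;B;C) for index groups a, b, c of a joint distribution, via the
    identity I(A;B;C) = I(A;B) - I(A;B|C), each term from first principles."""
    iab = mutual_information_of_dist(dist, a, b)
    # I(A;B|C) = sum_c p(c) I(A;B | C=c)
    pc = marginal(dist, c)
    cond = 0.0
    for cstate, p in pc.items():
        sub: dict[tuple, float] = defaultdict(float)
        for state, q in dist.items():
            if tuple(state[i] for i in c) == cstate:
                sub[state] += q / p
        cond += p * mutual_information_of_dist(dict(sub), a, b)
    return iab - cond


def mutual_information_of_dist(dist, a, b) -> float:
    return (
        entropy(marginal(dist, a))
        + entropy(marginal(dist, b))
        - entropy(marginal(dist, list(a) + list(b)))
    )


def brute_relay_information(labels, preds, bits, relay, cond, target=None, weights=None):
    """Conditional co-information I(Xin; Xout; YR | Y0) as the average of
    per-Y0-state co-informations."""
    relay = list(relay)
    cond = list(cond)
    if not relay:
        return 0.0
    if target is None:
        a_col = np.asarray(labels)
        b_col = np.asarray(preds)
    else:
        a_col = (np.asarray(labels) == target).astype(int)
        b_col = (np.asarray(preds) == target).astype(int)
    mat = np.column_stack([a_col, b_col, bits[:, relay], bits[:, cond]])
    dist = dist_from_rows(mat, weights)
    a = [0]
    b = [1]
    r = list(range(2, 2 + len(relay)))
    c = list(range(2 + len(relay), 2 + len(relay) + len(cond)))
    if not c:
        return co_information_of_dist(dist, a, b, r)
    pc = marginal(dist, c)
    total = 0.0
    for cstate, p in pc.items():
        sub: dict[tuple, float] = defaultdict(float)
        for state, q in dist.items():
            if tuple(state[i] for i in c) == cstate:
                sub[state] += q / p
        total += p * co_information_of_dist(dict(sub), a, b, r)
    return total


def brute_exhaustive(labels, preds, bits, target=None, weights=None):
    """Best relay set of every size, by full enumeration."""
    n = bits.shape[1]
    nodes = list(range(n))
    best: dict[int, tuple[float, list[tuple[int, ...]]]] = {}
    for size in range(1, n + 1):
        vals = []
        for relay in combinations(nodes, size):
            cond = [x for x in nodes if x not in relay]
            vals.append(
                (brute_relay_information(labels, preds, bits, relay, cond, target, weights),
                 relay)
            )
        top = max(v for v, _ in vals)
        best[size] = (top, [r for v, r in vals if abs(v - top) <= 1e-12])
    return best
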