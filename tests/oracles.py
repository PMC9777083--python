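"""Independent brute-force oracles used to verify the package's statistics.

Everything here is written from the definitions, deliberately naive
(double loops, dense grids, exhaustive subset enumeration), and shares
no code with the implementation it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_concordance(score, time, event) -> float:
    """Harrell's C by an explicit double loop over ordered sample pairs."""
    score, time, event = (np.asarray(a, dtype=float) for a in (score, time, event))
    n = len(score)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if score[i] > score[j]:
                    num += 1
                elif score[i] == score[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def brute_bh(p) -> np.ndarray:
    """Step-up BH from the definition: adj_i = min_{k: p(k) >= p(i)} p(k)*m/k."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        running_min = min(running_min, p[order[rank - 1]] * m / rank)
        adj_sorted[rank - 1] = min(running_min, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def breslow_loglik(beta, x, time, event) -> float:
    """Breslow partial log-likelihood of a single covariate, from the definition."""
    x, time, event = (np.asarray(a, dtype=float) for a in (x, time, event))
    ll = 0.0
    for t in np.unique(time[event == 1]):
        at_t = (time == t) & (event == 1)
        risk = time >= t
        ll += beta * x[at_t].sum() - at_t.sum() * np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def grid_argmax_cox(x, time, event, lo=-5.0, hi=5.0, step=2.5e-4) -> float:
    """Dense grid-search maximizer of the Breslow partial likelihood."""
    grid = np.arange(lo, hi + step, step)
    x, time, event = (np.asarray(a, dtype=float) for a in (x, time, event))
    lls = np.zeros_like(grid)
    for t in np.unique(time[event == 1]):
        at_t = (time == t) & (event == 1)
        risk = time >= t
        lls += grid * x[at_t].sum()
        lls -= at_t.sum() * np.log(np.exp(np.outer(grid, x[risk])).sum(axis=1))
    return float(grid[np.argmax(lls)])


def brute_best_subset(indicators: np.ndarray, time, event):
    """Exhaustive best-subset search of the vote-fraction C-index.

    ``indicators`` is (candidates x samples) 0/1: candidate in its risky
    state. Returns (best_c, best_subset).
    """
    m = indicators.shape[0]
    best_c, best_subset = -np.inf, None
    for size in range(1, m + 1):
        for subset in combinations(range(m), size):
            score = indicators[list(subset)].mean(axis=0)
            c = brute_concordance(score, time, event)
            if c > best_c:
                best_c, best_subset = c, subset
    return best_c, best_subset
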