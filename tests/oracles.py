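"""Independent reference implementations used only to check survmod.

Each oracle deliberately takes the slow, transparent route (dense grids,
exact enumeration, rational arithmetic) so it shares no code path with
the implementation under test.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb, exp, log, sqrt

import numpy as np


def breslow_partial_loglik(beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Direct double-loop Breslow partial log-likelihood, one covariate."""
    ll = 0.0
    for i in range(len(x)):
        if event[i] != 1:
            continue
        risk = [j for j in range(len(x)) if time[j] >= time[i]]
        denom = sum(exp(beta * x[j]) for j in risk)
        ll += beta * x[i] - log(denom)
    return ll


def cox_grid_fit(x, time, event, span: float = 8.0, n_grid: int = 160_001):
    """Maximise the partial likelihood on a dense beta grid; Wald p via a
    numeric second derivative at the optimum."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    grid = np.linspace(-span, span, n_grid)
    lls = np.array([breslow_partial_loglik(b, x, time, event) for b in grid])
    beta = float(grid[np.argmax(lls)])
    h = 1e-4
    d2 = (
        breslow_partial_loglik(beta + h, x, time, event)
        - 2 * breslow_partial_loglik(beta, x, time, event)
        + breslow_partial_loglik(beta - h, x, time, event)
    ) / h**2
    se = 1.0 / sqrt(-d2)
    from scipy.stats import norm

    p = 2 * norm.sf(abs(beta / se))
    return beta, se, p


def hypergeom_tail_exact(x: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= x) by exact rational summation over the support."""
    total = Fraction(0)
    for i in range(x, min(n, K) + 1):
        if n - i > N - K:
            continue
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return total


def logrank_statistic(time, event, group) -> float:
    """Two-group log-rank chi-square statistic from first principles."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def logrank_exact_permutation_p(time, event, group) -> float:
    """Exact permutation p of the log-rank statistic over all label
    assignments with the observed group sizes."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    n = len(time)
    k = int(group.sum())
    observed = logrank_statistic(time, event, group)
    count = 0
    total = 0
    for idx in combinations(range(n), k):
        g = np.zeros(n, int)
        g[list(idx)] = 1
        total += 1
        if logrank_statistic(time, event, g) >= observed - 1e-12:
            count += 1
    return count / total


def km_survival_by_hand(time, event):
    """Product-limit estimate computed step by step."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    s = 1.0
    curve = []
    for t in np.unique(time[event == 1]):
        n = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1 - d / n
        curve.append((float(t), s))
    return curve
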