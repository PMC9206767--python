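"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — exhaustive enumeration and an
un-pruned quadratic optimal-partitioning DP — and shares no code with the
package's changepoint engines.
"""

from __future__ import annotations

import itertools

import numpy as np


def rss(values: np.ndarray) -> float:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return np.inf
    return float(((values - values.mean()) ** 2).sum())


def enumerate_optimum(values: np.ndarray, n: int):
    """Global optimum with exactly n changepoints by exhaustive enumeration."""
    values = np.asarray(values, dtype=float)
    T = values.size
    best_e, best_cps = np.inf, None
    for cps in itertools.combinations(range(1, T), n):
        bounds = (0,) + cps + (T,)
        e = sum(rss(values[a:b]) for a, b in zip(bounds[:-1], bounds[1:]))
        if e < best_e:
            best_e, best_cps = e, cps
    return best_e, best_cps


def op_penalized(values: np.ndarray, beta: float) -> float:
    """Un-pruned O(T^2) optimal partitioning: min total RSS + beta * n."""
    v = np.asarray(values, dtype=float)
    T = v.size
    s1 = np.concatenate(([0.0], np.cumsum(v)))
    s2 = np.concatenate(([0.0], np.cumsum(v * v)))

    def cost(i, j):
        if j - i == 1:
            return 0.0
        d = s1[j] - s1[i]
        return max(s2[j] - s2[i] - d * d / (j - i), 0.0)

    F = np.empty(T + 1)
    F[0] = -beta
    for t in range(1, T + 1):
        F[t] = min(F[i] + cost(i, t) + beta for i in range(t))
    return float(F[T])
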