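"""Low-level changepoint kernels (numba-jitted when available).

All kernels work on a *compressed* axis: masked bins are removed before the
prefix sums are built and changepoint indices are mapped back to the original
bin grid by the caller.  Values are centered on their global mean before the
prefix sums are formed; the within-segment residual sum of squares (RSS) is
invariant to that shift and centering keeps the prefix-sum cost formula well
conditioned.  Costs below a data-scaled floor are snapped to zero so that a
noise-free piecewise-constant trace yields exactly zero error.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


def prepare_prefix(values: np.ndarray):
    """Centered prefix sums ``(S1, S2, floor)`` for RSS segment costs.

    ``floor`` is the numeric zero threshold: cancellation error in the
    prefix-sum cost formula is bounded by a small multiple of eps * S2_total,
    so anything below it is numerically indistinguishable from zero.
    """
    v = np.asarray(values, dtype=np.float64)
    c = v - v.mean()
    s1 = np.concatenate(([0.0], np.cumsum(c)))
    s2 = np.concatenate(([0.0], np.cumsum(c * c)))
    # cumsum cancellation error grows roughly linearly in the trace length
    floor = 4.0 * max(256.0, v.size) * np.finfo(np.float64).eps * max(s2[-1], 1.0)
    return s1, s2, floor


@njit(cache=True)
def _cost(s1, s2, floor, i, j):
    if j - i == 1:
        return 0.0
    d = s1[j] - s1[i]
    q = s2[j] - s2[i] - d * d / (j - i)
    if q < floor:
        return 0.0
    return q


@njit(cache=True)
def segment_neighborhood(s1, s2, floor, n_max):
    """Exact DP over the number of changepoints.

    Returns ``(E, B)`` where ``E[n, t]`` is the minimum total RSS of the
    first ``t`` points using exactly ``n`` changepoints and ``B[n, t]`` is
    the position of the last changepoint of one optimizer.  Ties prefer the
    earlier changepoint index (deterministic).
    """
    T = s1.shape[0] - 1
    E = np.full((n_max + 1, T + 1), np.inf)
    B = np.zeros((n_max + 1, T + 1), dtype=np.int64)
    for t in range(1, T + 1):
        E[0, t] = _cost(s1, s2, floor, 0, t)
    for n in range(1, n_max + 1):
        for t in range(n + 1, T + 1):
            best = np.inf
            arg = n
            for i in range(n, t):
                v = E[n - 1, i] + _cost(s1, s2, floor, i, t)
                if v < best:
                    best = v
                    arg = i
            E[n, t] = best
            B[n, t] = arg
    return E, B


@njit(cache=True)
def backtrack_segneigh(B, n, T):
    """Changepoint indices of the ``n``-changepoint optimizer ending at T."""
    cps = np.empty(n, dtype=np.int64)
    t = T
    for k in range(n, 0, -1):
        t = B[k, t]
        cps[k - 1] = t
    return cps


@njit(cache=True)
def pelt(s1, s2, floor, beta):
    """Penalized exact changepoint search with PELT pruning.

    Minimizes total RSS + beta * (number of changepoints); identical to
    un-pruned optimal partitioning.  Returns the ``prev`` backtracking array.
    """
    T = s1.shape[0] - 1
    F = np.empty(T + 1)
    F[0] = -beta
    prev = np.zeros(T + 1, dtype=np.int64)
    cand = np.empty(T + 1, dtype=np.int64)
    cand[0] = 0
    ncand = 1
    for t in range(1, T + 1):
        best = np.inf
        arg = 0
        for k in range(ncand):
            i = cand[k]
            v = F[i] + _cost(s1, s2, floor, i, t) + beta
            if v < best:
                best = v
                arg = i
        F[t] = best
        prev[t] = arg
        # prune candidates that can never be optimal again
        m = 0
        for k in range(ncand):
            i = cand[k]
            if F[i] + _cost(s1, s2, floor, i, t) <= F[t]:
                cand[m] = i
                m += 1
        cand[m] = t
        ncand = m + 1
    return prev


def backtrack_pelt(prev: np.ndarray) -> np.ndarray:
    """Changepoint indices (ascending) from a PELT backtracking array."""
    T = prev.shape[0] - 1
    cps = []
    t = T
    while t > 0:
        i = int(prev[t])
        if i > 0:
            cps.append(i)
        t = i
    return np.array(cps[::-1], dtype=np.int64)


def total_rss(s1: np.ndarray, s2: np.ndarray, floor: float,
              cps: np.ndarray) -> float:
    """Total RSS of the segmentation defined by changepoints ``cps``."""
    T = s1.shape[0] - 1
    bounds = np.concatenate(([0], np.asarray(cps, dtype=np.int64), [T]))
    return float(sum(_cost(s1, s2, floor, int(a), int(b))
                     for a, b in zip(bounds[:-1], bounds[1:])))
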