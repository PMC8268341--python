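"""Exact minimum-hypergeometric (mHG) statistic for ranked-list enrichment.

The mHG test asks, for a ranked universe of N items containing K members of
a set, whether the members concentrate unusually near the top of the list —
without fixing a cutoff.  For every prefix length t the hypergeometric
upper-tail probability of seeing at least k_t members in the top t is
computed; the statistic is the minimum tail over all prefixes.  Because the
minimum is taken over many dependent tests, the statistic itself is not a
p-value; the exact null probability of reaching a statistic at least as
small is obtained by a dynamic program over monotone lattice paths from
(0, 0) to (N, K), where each path corresponds to one of the C(N, K) equally
likely member placements and paths entering the rejection region are
absorbed.

All heavy loops are jitted with numba; a pure-Python fallback keeps the
module importable (slowly) without it.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=True)
def _hg_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= max(0, n + K - N):
        return 1.0
    hi = min(n, K)
    if k > hi:
        return 0.0
    # first term P(X = k) via lgamma, then ratio recurrence upward
    logp = (
        math.lgamma(K + 1) - math.lgamma(k + 1) - math.lgamma(K - k + 1)
        + math.lgamma(N - K + 1) - math.lgamma(n - k + 1) - math.lgamma(N - K - n + k + 1)
        - (math.lgamma(N + 1) - math.lgamma(n + 1) - math.lgamma(N - n + 1))
    )
    term = math.exp(logp)
    total = term
    for i in range(k, hi):
        term *= (K - i) * (n - i) / ((i + 1.0) * (N - K - n + i + 1.0))
        total += term
    if total > 1.0:
        total = 1.0
    return total


@njit(cache=True)
def _mhg_statistic(positions: np.ndarray, N: int) -> float:
    """Minimum hypergeometric tail over all prefixes of the ranked list.

    ``positions`` are the 0-based ranks of the K set members, sorted
    ascending.  The minimum over all cutoffs t is attained at a prefix
    ending on a member, so only K tails are evaluated.
    """
    K = positions.shape[0]
    s = 1.0
    for j in range(K):
        t = positions[j] + 1  # prefix length including this member
        tail = _hg_upper_tail(N, K, t, j + 1)
        if tail < s:
            s = tail
    return s


@njit(cache=True)
def _mhg_pvalue(N: int, K: int, s: float) -> float:
    """Exact P(mHG statistic <= s) under uniform placement of K members.

    Dynamic program over lattice paths (n, k): a path step reveals the next
    ranked item, moving to k+1 with probability (K-k)/(N-n).  Mass entering
    the rejection region {(n, k): upper tail <= s} is absorbed; the exact
    p-value is one minus the surviving mass.
    """
    if K <= 0:
        return 1.0
    s_eff = s * (1.0 + 1e-12)
    if s_eff >= 1.0:
        return 1.0
    prob = np.zeros(K + 1)
    prob[0] = 1.0
    kmin = 1  # rejection boundary is non-decreasing in n
    for n in range(1, N + 1):
        lo = max(0, n + K - N)
        hi = min(n, K)
        # propagate from step n-1 to n, iterating k downwards (in place)
        for k in range(hi, lo - 1, -1):
            denom = N - (n - 1)
            stay = 0.0
            if k <= min(n - 1, K):
                stay = prob[k] * (denom - (K - k)) / denom
            enter = 0.0
            if k >= 1:
                enter = prob[k - 1] * (K - (k - 1)) / denom
            prob[k] = stay + enter
        if lo > 0:
            for k in range(0, lo):
                prob[k] = 0.0
        # advance rejection boundary for this n and absorb
        if kmin < lo:
            kmin = lo
        while kmin <= hi and _hg_upper_tail(N, K, n, kmin) > s_eff:
            kmin += 1
        for k in range(max(kmin, lo), hi + 1):
            prob[k] = 0.0
    surviving = prob[K]
    p = 1.0 - surviving
    if p < s:  # numerically the exact p can never undercut the statistic
        p = s
    if p > 1.0:
        p = 1.0
    return p


def mhg_test(positions: np.ndarray | list, N: int) -> tuple[float, float]:
    """Run the mHG test for set members at the given ranks.

    Parameters
    ----------
    positions
        0-based ranks of the set members within the ranked universe.
    N
        Size of the ranked universe.

    Returns
    -------
    (statistic, pvalue)
        The minimum hypergeometric tail and its exact null probability.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size == 0:
        raise ValueError("set has no members in the ranked universe")
    if pos.min() < 0 or pos.max() >= N:
        raise ValueError("member ranks must lie in [0, N)")
    pos = np.sort(pos)
    s = _mhg_statistic(pos, N)
    p = _mhg_pvalue(N, int(pos.size), s)
    return float(s), float(p)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Public wrapper for the hypergeometric upper tail P(X >= k)."""
    return float(_hg_upper_tail(N, K, n, k))
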