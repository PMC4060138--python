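"""Independent brute-force oracles used to pin expected values.

Everything here is computed from first principles (log-factorial sums and
explicit tail enumeration), deliberately avoiding the scipy distribution
machinery the implementation relies on.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln


def log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail_grid(dn: int, dt: int) -> np.ndarray:
    """P(alt_in_tumor >= j) for every table with margins (dn, dt).

    Returns an array T of shape (dn + dt + 1, dt + 1) where ``T[K, j]`` is
    the upper-tail probability of drawing at least ``j`` alt reads in the
    tumor when ``K`` alt reads in total are split between a normal of depth
    ``dn`` and a tumor of depth ``dt``.  Entries with an impossible
    configuration (K - j > dn or j > K) carry NaN-free placeholder mass of
    zero in the pmf and are handled by the caller's mask.
    """
    N = dn + dt
    K = np.arange(N + 1)[:, None]  # total alt
    j = np.arange(dt + 1)[None, :]  # alt in tumor
    valid = (j <= K) & (K - j <= dn)
    with np.errstate(invalid="ignore"):
        logpmf = log_comb(dt, j) + log_comb(dn, K - j) - log_comb(N, K)
    pmf = np.where(valid, np.exp(logpmf), 0.0)
    # reverse cumulative sum over j: tail P(X >= j)
    tail = np.cumsum(pmf[:, ::-1], axis=1)[:, ::-1]
    return tail


def fisher_one_sided_bruteforce(nr: int, na: int, tr: int, ta: int) -> float:
    """Exact one-sided (tumor alt enrichment) Fisher p by explicit tail sum."""
    dn, dt = nr + na, tr + ta
    K = na + ta
    total = 0.0
    for j in range(ta, min(K, dt) + 1):
        if K - j > dn:
            continue
        total += math.exp(
            float(log_comb(dt, j) + log_comb(dn, K - j) - log_comb(dn + dt, K))
        )
    return min(total, 1.0)


def kruskal_h_bruteforce(groups: list[list[float]]) -> float:
    """Kruskal-Wallis H from the explicit rank formula with tie correction."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    # average ranks over ties
    for v in np.unique(pooled):
        mask = pooled == v
        ranks[mask] = ranks[mask].mean()
    h = 0.0
    start = 0
    for g in groups:
        ng = len(g)
        rbar = ranks[start : start + ng].mean()
        h += ng * (rbar - (n + 1) / 2) ** 2
        start += ng
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction
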