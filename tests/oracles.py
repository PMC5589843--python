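"""Independent brute-force oracles used by the test suite.

Everything here recomputes statistics by direct enumeration or naive pair
counting, deliberately avoiding the code paths (convolution recurrences,
vectorized counting) used by the package itself.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_kendall(x, y):
    """Tau-b by explicit O(n^2) loops over all pairs (with tie handling).

    Returns (tau, S) where S = concordant - discordant; tau is NaN when all
    x or all y are tied.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    s = 0
    tx = 0
    ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a = (x[i] > x[j]) - (x[i] < x[j])
            b = (y[i] > y[j]) - (y[i] < y[j])
            s += a * b
            tx += a == 0
            ty += b == 0
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    if denom == 0:
        return float("nan"), s
    return s / denom, s


def kendall_null_s_distribution(n: int, chunk: int = 200_000):
    """Exact null distribution of S = concordant - discordant for tie-free
    samples of size n, by full enumeration of the n! rank permutations.

    Returns (s_values, probabilities).  Enumeration is chunked so n = 10
    (3.6M permutations) stays within memory.
    """
    n0 = n * (n - 1) // 2
    counts = np.zeros(n0 + 1, dtype=np.int64)  # counts of inversion numbers
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    it = itertools.permutations(range(n))
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            break
        arr = np.asarray(block, dtype=np.int8)
        inv = (arr[:, ii] > arr[:, jj]).sum(axis=1)
        counts += np.bincount(inv, minlength=n0 + 1)
    total = counts.sum()
    s_values = n0 - 2 * np.arange(n0 + 1)
    return s_values, counts / total


def kendall_exact_p_enum(n: int, s: int, dist_cache: dict) -> float:
    """Two-sided exact p = P(|S'| >= |s|) from the enumerated null."""
    if n not in dist_cache:
        dist_cache[n] = kendall_null_s_distribution(n)
    s_values, probs = dist_cache[n]
    return float(probs[np.abs(s_values) >= abs(s)].sum())


def wilcoxon_enum(values):
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors.

    Same conventions as the implementation under test is *required* to use:
    zeros dropped, average ranks for ties, symmetric tail mass
    P(|W - mu| >= |w_obs - mu|).
    """
    v = np.asarray(values, dtype=float)
    v = v[v != 0.0]
    n = v.size
    if n == 0:
        return 0.0, 1.0
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(v))
    w_obs = float(ranks[v > 0].sum())
    mu = float(ranks.sum()) / 2.0
    hits = 0
    total = 2**n
    for signs in itertools.product((0, 1), repeat=n):
        w = float(sum(r for r, s in zip(ranks, signs) if s))
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return w_obs, hits / total


def sma_slope_direct(x, y):
    """SMA slope/intercept by the textbook formula, recomputed from scratch."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.corrcoef(x, y)[0, 1]
    slope = (1.0 if r >= 0 else -1.0) * y.std(ddof=1) / x.std(ddof=1)
    return slope, y.mean() - slope * x.mean(), r * r
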