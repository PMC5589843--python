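"""Rank statistics used by the correlation and debiasing stages.

Sample sizes here are tiny (a stratum holds at most one observation per
year), so the tie-corrected Kendall statistic is computed by direct pair
counting and small-sample p-values come from the exact null distribution.
Both exact nulls (Kendall's S over permutations, the signed-rank sum over
sign assignments) are computed by integer convolution, which is feasible for
every sample size the pipeline produces.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy import stats as sstats

__all__ = ["kendall_tau", "wilcoxon_signed_rank", "KENDALL_EXACT_MAX_N"]

#: Largest tie-free sample for which the exact Kendall null is used.
KENDALL_EXACT_MAX_N = 10

#: Largest (zero-stripped) sample for which the exact signed-rank null is used.
WILCOXON_EXACT_MAX_N = 25


@lru_cache(maxsize=64)
def _kendall_null_counts(n: int) -> tuple[np.ndarray, float]:
    """Distribution of the number of discordant pairs under the tie-free null.

    Returns ``(counts, total)`` where ``counts[d]`` is the number of
    permutations of ``n`` items with exactly ``d`` inversions (Mahonian
    numbers), built by convolving the uniform polynomials
    ``1 + z + ... + z^k`` for ``k = 0..n-1``.
    """
    counts = np.ones(1)
    for k in range(1, n):
        counts = np.convolve(counts, np.ones(k + 1))
    return counts, float(math.factorial(n))


def _kendall_exact_p(n: int, s: int) -> float:
    """Two-sided exact p-value P(|S'| >= |S|) for tie-free data.

    ``S = concordant - discordant`` relates to the inversion count ``d`` by
    ``S = n(n-1)/2 - 2d``; the null is symmetric around 0.
    """
    counts, total = _kendall_null_counts(n)
    n0 = n * (n - 1) // 2
    s_values = n0 - 2 * np.arange(counts.size)
    return float(counts[np.abs(s_values) >= abs(s)].sum() / total)


def _tie_sizes(v: np.ndarray) -> np.ndarray:
    _, c = np.unique(v, return_counts=True)
    return c[c > 1]


def kendall_tau(x, y) -> tuple[float, float]:
    """Tie-corrected Kendall rank correlation (tau-b) with two-sided p-value.

    Parameters
    ----------
    x, y : array-like
        Paired observations (one value per year within a stratum).

    Returns
    -------
    (tau, p_value)
        ``tau`` is tau-b in [-1, 1].  The p-value uses the exact tie-free
        null for ``n <= 10`` without ties and the tie-corrected normal
        approximation otherwise.  When every ``x`` or every ``y`` is tied the
        statistic is undefined and ``(nan, nan)`` is returned.

    Raises
    ------
    ValueError
        If the inputs differ in length or hold fewer than two pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be 1-d of equal length, got {x.shape} vs {y.shape}")
    n = x.size
    if n < 2:
        raise ValueError("kendall_tau needs at least two pairs")

    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    prod = dx[iu] * dy[iu]
    s = int(prod.sum())

    n0 = n * (n - 1) // 2
    tx = _tie_sizes(x)
    ty = _tie_sizes(y)
    n1 = int((tx * (tx - 1) // 2).sum())
    n2 = int((ty * (ty - 1) // 2).sum())
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    if denom == 0.0:  # all x tied or all y tied: tau undefined
        return float("nan"), float("nan")
    tau = s / denom

    has_ties = n1 > 0 or n2 > 0
    if not has_ties and n <= KENDALL_EXACT_MAX_N:
        return tau, _kendall_exact_p(n, s)

    # Tie-corrected variance of S (normal approximation, no continuity corr.)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = float((tx * (tx - 1) * (2 * tx + 5)).sum())
    vu = float((ty * (ty - 1) * (2 * ty + 5)).sum())
    v1 = float((tx * (tx - 1)).sum()) * float((ty * (ty - 1)).sum()) / (2.0 * n * (n - 1))
    v2 = 0.0
    if n > 2:
        v2 = (
            float((tx * (tx - 1) * (tx - 2)).sum())
            * float((ty * (ty - 1) * (ty - 2)).sum())
            / (9.0 * n * (n - 1) * (n - 2))
        )
    var_s = (v0 - vt - vu) / 18.0 + v1 + v2
    if var_s <= 0:
        return tau, float("nan")
    z = s / math.sqrt(var_s)
    return tau, float(2.0 * sstats.norm.sf(abs(z)))


def _signed_rank_exact_p(dranks: np.ndarray, w2: float) -> float:
    """Exact two-sided p for the signed-rank sum with (possibly tied) ranks.

    ``dranks`` are doubled midranks (integers even with average-rank ties);
    ``w2`` is the doubled observed positive-rank sum.  The null assigns each
    rank a + sign independently with probability 1/2, so the distribution of
    the doubled sum is the convolution of ``(1 + z^d)`` terms; p is the
    symmetric tail mass P(|W' - mu| >= |W - mu|).
    """
    total = int(dranks.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for d in dranks:
        shifted = np.zeros_like(pmf)
        shifted[d:] = pmf[: pmf.size - d]
        pmf = 0.5 * (pmf + shifted)
    mu = total / 2.0
    dev = np.abs(np.arange(total + 1) - mu)
    return float(pmf[dev >= abs(w2 - mu) - 1e-9].sum())


def wilcoxon_signed_rank(values, exact_max_n: int = WILCOXON_EXACT_MAX_N) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of ``values`` against zero.

    Zeros are dropped; ties in |values| receive average ranks.  The exact
    null (all 2^n sign assignments) is used for samples of up to
    ``exact_max_n`` nonzero values; above that the normal approximation with
    continuity correction applies.

    Returns ``(w_plus, p_value)``; an all-zero sample returns ``(0.0, 1.0)``.
    """
    v = np.asarray(values, dtype=float)
    v = v[v != 0.0]
    n = v.size
    if n == 0:
        return 0.0, 1.0
    ranks = sstats.rankdata(np.abs(v))
    w_plus = float(ranks[v > 0].sum())

    if n <= exact_max_n:
        dranks = np.rint(2.0 * ranks).astype(np.int64)
        return w_plus, min(1.0, _signed_rank_exact_p(dranks, 2.0 * w_plus))

    mu = float(ranks.sum()) / 2.0
    sigma = math.sqrt(float((ranks**2).sum()) / 4.0)
    if sigma == 0.0:
        return w_plus, 1.0
    diff = w_plus - mu
    z = (diff - 0.5 * np.sign(diff)) / sigma
    return w_plus, min(1.0, float(2.0 * sstats.norm.sf(abs(z))))
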