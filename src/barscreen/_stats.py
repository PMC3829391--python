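"""Two-sample significance testing with explicit degenerate-variance conventions.

All screen and assay p-values in this package flow through
:func:`two_sample_p`, so the conventions for degenerate inputs are defined in
exactly one place:

* both groups constant and equal -> p = 1.0 (no evidence of any difference);
* both groups constant but unequal -> p = the smallest positive normal float
  (the difference is infinitely significant relative to zero noise, but a
  literal 0 would be misleading and NaN would poison downstream filters).
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats

#: p-value assigned when two zero-variance groups have unequal means.
TINY = float(np.finfo(float).tiny)

#: Largest number of reassignments enumerated exhaustively by the
#: permutation test before falling back to Monte Carlo sampling.
EXACT_LIMIT = 100_000

METHODS = ("student", "welch", "permutation")


def two_sample_p(
    x,
    y,
    method: str = "student",
    rng=None,
    n_resamples: int = 10_000,
) -> float:
    """Two-sided p-value for a difference in location between two samples.

    Parameters
    ----------
    x, y
        1-d numeric samples, each non-empty.
    method
        ``"student"`` (pooled-variance t-test, the default), ``"welch"``
        (unequal-variance t-test) or ``"permutation"`` (difference of means
        against the reassignment null, exhaustive when feasible).
    rng
        Seed or ``numpy.random.Generator``, used only by the Monte Carlo
        branch of the permutation test.
    n_resamples
        Monte Carlo sample size when exhaustive enumeration is infeasible.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return TINY
    if method in ("student", "welch"):
        p = float(stats.ttest_ind(x, y, equal_var=(method == "student")).pvalue)
        if math.isnan(p):
            return float("nan")
        return max(p, TINY)
    if method == "permutation":
        return permutation_p(x, y, rng=rng, n_resamples=n_resamples)
    raise ValueError(f"unknown test method {method!r}; expected one of {METHODS}")


def permutation_p(x, y, rng=None, n_resamples: int = 10_000) -> float:
    """Two-sided permutation test on the difference of group means.

    Enumerates every reassignment of the pooled observations to the two
    group sizes when their number is at most :data:`EXACT_LIMIT`; otherwise
    draws ``n_resamples`` random reassignments (add-one corrected so the
    estimate is never exactly zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    nx, ny = x.size, y.size
    if np.ptp(pooled) == 0:
        return 1.0
    total_sum = float(pooled.sum())
    obs = abs(x.mean() - y.mean())
    # forgiving >= comparison: reassignments tying the observed statistic count
    tol = 1e-12 * max(1.0, obs)
    n_exact = math.comb(nx + ny, nx)
    if n_exact <= EXACT_LIMIT:
        vals = pooled.tolist()
        count = 0
        for combo in combinations(vals, nx):
            sx = sum(combo)
            d = abs(sx / nx - (total_sum - sx) / ny)
            if d >= obs - tol:
                count += 1
        return count / n_exact
    gen = np.random.default_rng(rng)
    count = 0
    for _ in range(n_resamples):
        perm = gen.permutation(pooled)
        d = abs(perm[:nx].mean() - perm[nx:].mean())
        if d >= obs - tol:
            count += 1
    return (count + 1) / (n_resamples + 1)
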