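"""Dip statistic for unimodality testing of read-coverage profiles.

The dip of a sample measures the sup-norm distance between its empirical
CDF and the closest unimodal CDF.  A unimodal CDF is convex left of the
mode and concave right of it, so the statistic is computed here as

    dip = 0.5 * min over modal split m of
          max( sup gap between the ECDF and its greatest convex minorant
               on points left of m,
               sup gap between the ECDF and its least concave majorant
               on points right of m )

Halving is exact for one-sided convex approximation in the sup norm: the
best convex fit to a function sits midway between the function and its
convex envelope.  P-values are calibrated by Monte Carlo under a uniform
null of matched sample size, which gives the test correct size for the
statistic actually computed.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def _prefix_convex_gaps(x: np.ndarray, f: np.ndarray) -> np.ndarray:
    """For each prefix x[:i+1], the max gap between f and its convex minorant.

    Incremental Andrew-monotone-chain over the lower hull; gaps are evaluated
    at every point against the hull of the current prefix.  O(n^2) worst case,
    fine for the profile sizes used here (n <= a few hundred).
    """
    n = len(x)
    gaps = np.zeros(n)
    hull: list[int] = []
    for i in range(n):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # keep hull lower-convex: cross product of (k-j) x (i-k)
            if (x[k] - x[j]) * (f[i] - f[k]) - (f[k] - f[j]) * (x[i] - x[k]) <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
        # max distance from f to the hull over the prefix
        h = np.array(hull)
        env = np.interp(x[: i + 1], x[h], f[h])
        gaps[i] = float(np.max(f[: i + 1] - env))
    return gaps


def dip_statistic(samples: np.ndarray) -> float:
    """Dip statistic of a 1-D sample (0 for n < 4 or degenerate samples)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 4 or x[0] == x[-1]:
        return 0.0
    # ECDF evaluated at the data points; use midpoints of the step to keep the
    # statistic symmetric under sample reversal.
    f = (np.arange(1, n + 1) - 0.5) / n
    left = _prefix_convex_gaps(x, f)
    # concave majorant on suffixes == convex minorant of the reversed, negated ECDF
    right = _prefix_convex_gaps(-x[::-1], -f[::-1])[::-1]
    # modal split between index m and m+1: convex fit on [0..m], concave on [m..n-1]
    split_err = np.maximum(left, right)
    return 0.5 * float(split_err.min())


@lru_cache(maxsize=64)
def _null_distribution(n: int, n_boot: int, seed: int) -> tuple[float, ...]:
    rng = np.random.default_rng(seed)
    return tuple(sorted(dip_statistic(rng.uniform(size=n)) for _ in range(n_boot)))


def dip_pvalue(samples: np.ndarray, n_boot: int = 200, seed: int = 0) -> tuple[float, float]:
    """Dip statistic and its Monte Carlo p-value under a uniform null.

    Returns ``(dip, p)`` where ``p`` is the fraction of uniform samples of the
    same size with a dip at least as large (add-one corrected).
    """
    x = np.asarray(samples, dtype=float)
    d = dip_statistic(x)
    null = np.array(_null_distribution(len(x), n_boot, seed))
    p = (np.sum(null >= d) + 1) / (len(null) + 1)
    return d, float(p)
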