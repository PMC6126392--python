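"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own code paths: the rate constant is
recovered by dense grid search over the RSS surface, and the Fisher exact
p-value by exact integer hypergeometric enumeration.
"""

import math
from math import comb

import numpy as np

GRID_STEP = 1e-4


def grid_search_k(points, k_max=2.5, step=GRID_STEP):
    """RSS-minimizing k on a dense grid; independent of the package's solver."""
    pts = np.asarray(points, dtype=float)
    t, ria = pts[:, 0], pts[:, 1]
    grid = np.arange(0.0, k_max + step, step)
    rss = ((1.0 - np.exp(-np.outer(grid, t)) - ria) ** 2).sum(axis=1)
    return float(grid[int(np.argmin(rss))])


def fisher_two_sided(a, b, c, d):
    """Two-sided Fisher exact p by integer hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (with the conventional
    tiny relative tolerance at ties).
    """
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = comb(r1, a) * comb(r2, c1 - a)
    tol = obs * (1 + 1e-7)
    num = sum(
        comb(r1, x) * comb(r2, c1 - x)
        for x in range(lo, hi + 1)
        if comb(r1, x) * comb(r2, c1 - x) <= tol
    )
    return num / denom


def closed_form_ria(k, t):
    """Scalar labeling curve via math.exp, independent of numpy vectorization."""
    return 1.0 - math.exp(-k * t)
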