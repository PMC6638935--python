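"""Independent oracles used to validate the production implementations.

The DTW oracle is a top-down recursion over the three admissible steps,
written without the accumulated-cost matrix or backtrace of the package's
dynamic program, so the two share no code path.
"""

from functools import lru_cache

import numpy as np


def brute_dtw_distance(x, y) -> float:
    """Minimal total |x_i - y_j| over all boundary-anchored monotone paths."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        cost = abs(x[i] - y[j])
        if i == 0 and j == 0:
            return cost
        best = float("inf")
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        if j > 0:
            best = min(best, rec(i, j - 1))
        if i > 0:
            best = min(best, rec(i - 1, j))
        return cost + best

    return rec(len(x) - 1, len(y) - 1)


def random_instance(rng: np.random.Generator, max_len: int = 7):
    n = rng.integers(1, max_len + 1)
    m = rng.integers(1, max_len + 1)
    return rng.normal(size=n), rng.normal(size=m)
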