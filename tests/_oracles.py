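"""Independent reference implementations used only to check the package.

The DTW oracle enumerates every monotone warping path explicitly (no
dynamic programming, no pruning) and is therefore only usable for tiny
windows; it accumulates path costs in the same left-to-right order as the
production DP, so agreement can be asserted exactly.
"""

from __future__ import annotations

import numpy as np


def local_cost(a: np.ndarray, b: np.ndarray, kind: str) -> float:
    d = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    if kind == "squared_diff_sum":
        return float(np.sum(d * d))
    return float(np.sum(np.abs(d)))


def dtw_bruteforce(a: np.ndarray, b: np.ndarray,
                   kind: str = "squared_diff_sum") -> float:
    """Minimum accumulated cost over all monotone paths (0,0) -> (n-1,m-1),
    stepping by (1,0), (0,1) or (1,1), by exhaustive enumeration."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    n, m = a.shape[0], b.shape[0]
    best = [np.inf]

    def rec(i: int, j: int, acc: float) -> None:
        acc = acc + local_cost(a[i], b[j], kind)
        if i == n - 1 and j == m - 1:
            if acc < best[0]:
                best[0] = acc
            return
        if i + 1 < n:
            rec(i + 1, j, acc)
        if j + 1 < m:
            rec(i, j + 1, acc)
        if i + 1 < n and j + 1 < m:
            rec(i + 1, j + 1, acc)

    rec(0, 0, 0.0)
    return best[0]
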