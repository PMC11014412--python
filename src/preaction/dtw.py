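"""Multivariate dynamic time warping.

Classic accumulated-cost DTW with the symmetric step pattern
(match / insert / delete), no window constraint, and a per-step local cost
summed over the three accelerometer axes (dependent multivariate DTW: one
shared warping path for X, Y and Z).

The full-matrix distance is deliberately computed as a sequence of
single-row extensions (:func:`_dp_first_row` / :func:`_dp_next_row`), the
same kernel :class:`GrowingDtw` uses to extend a query one sample at a
time.  Growing-window cost profiles from the incremental engine are
therefore bit-identical to per-length from-scratch recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numba import njit

__all__ = ["DtwConfig", "dtw_distance", "dtw_distance_1d", "GrowingDtw"]

LocalCost = Literal["squared_diff_sum", "abs_diff_sum"]

_LOCAL_COSTS = ("squared_diff_sum", "abs_diff_sum")


@dataclass(frozen=True)
class DtwConfig:
    """DTW settings.

    local_cost
        Per-sample-pair cost, summed over the three axes:
        ``squared_diff_sum`` (default) or ``abs_diff_sum``.
    """

    local_cost: LocalCost = "squared_diff_sum"

    def __post_init__(self) -> None:
        if self.local_cost not in _LOCAL_COSTS:
            raise ValueError(
                f"local_cost must be one of {_LOCAL_COSTS}, got {self.local_cost!r}"
            )


def _local_cost_rows(query: np.ndarray, template: np.ndarray,
                     local_cost: str) -> np.ndarray:
    """Local-cost matrix C[i, j] between query sample i and template sample j.

    Inputs are ``(n, 3)`` / ``(m, 3)`` arrays (a 1-D signal may be passed as
    ``(n, 1)``); cost is summed over the trailing axis.
    """
    diff = query[:, None, :] - template[None, :, :]
    if local_cost == "squared_diff_sum":
        return np.sum(diff * diff, axis=2)
    return np.sum(np.abs(diff), axis=2)


@njit(cache=True)
def _dp_first_row(crow: np.ndarray) -> np.ndarray:  # pragma: no cover - numba
    out = np.empty_like(crow)
    acc = 0.0
    for j in range(crow.shape[0]):
        acc += crow[j]
        out[j] = acc
    return out


@njit(cache=True)
def _dp_next_row(prev: np.ndarray, crow: np.ndarray) -> np.ndarray:  # pragma: no cover
    m = crow.shape[0]
    out = np.empty_like(crow)
    out[0] = prev[0] + crow[0]
    for j in range(1, m):
        best = prev[j]
        if prev[j - 1] < best:
            best = prev[j - 1]
        if out[j - 1] < best:
            best = out[j - 1]
        out[j] = crow[j] + best
    return out


def _as_window(a) -> np.ndarray:
    arr = np.asarray(getattr(a, "samples", a), dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] == 0:
        raise ValueError("DTW window must be non-empty")
    return np.ascontiguousarray(arr)


def dtw_distance(a, b, cfg: DtwConfig = DtwConfig()) -> float:
    """Accumulated DTW cost of the optimal warping path from (0,0) to (n-1,m-1).

    ``a`` and ``b`` are ``(n, 3)`` sample windows (or objects with a
    ``samples`` attribute, e.g. :class:`~preaction.io.AccelTrace`).
    """
    qa, qb = _as_window(a), _as_window(b)
    if qa.shape[1] != qb.shape[1]:
        raise ValueError("windows must have the same number of channels")
    C = _local_cost_rows(qa, qb, cfg.local_cost)
    row = _dp_first_row(np.ascontiguousarray(C[0]))
    for i in range(1, C.shape[0]):
        row = _dp_next_row(row, np.ascontiguousarray(C[i]))
    return float(row[-1])


def dtw_distance_1d(a: np.ndarray, b: np.ndarray,
                    cfg: DtwConfig = DtwConfig()) -> float:
    """Single-channel DTW distance (used by the whole-trace baseline)."""
    return dtw_distance(np.asarray(a, dtype=np.float64)[:, None],
                        np.asarray(b, dtype=np.float64)[:, None], cfg)


class GrowingDtw:
    """Incremental DTW against a fixed template for a query grown one sample
    at a time.

    After ``k`` calls to :meth:`extend`, :attr:`distance` equals
    ``dtw_distance(q[:k], template)`` exactly, where ``q`` is the sequence of
    extended samples.  Each extension costs O(m) for a template of length m.
    """

    def __init__(self, template, cfg: DtwConfig = DtwConfig()) -> None:
        self._template = _as_window(template)
        self._cfg = cfg
        self._row: np.ndarray | None = None
        self._n = 0

    @property
    def query_length(self) -> int:
        return self._n

    @property
    def distance(self) -> float:
        """Full-alignment distance for the current query; errors if empty."""
        if self._row is None:
            raise ValueError("no samples extended yet: distance undefined")
        return float(self._row[-1])

    def extend(self, sample) -> float:
        """Append one sample to the query; return the new distance."""
        s = np.asarray(sample, dtype=np.float64).reshape(1, -1)
        if s.shape[1] != self._template.shape[1]:
            raise ValueError("sample channel count does not match template")
        crow = np.ascontiguousarray(
            _local_cost_rows(s, self._template, self._cfg.local_cost)[0]
        )
        if self._row is None:
            self._row = _dp_first_row(crow)
        else:
            self._row = _dp_next_row(self._row, crow)
        self._n += 1
        return float(self._row[-1])
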