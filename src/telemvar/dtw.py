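"""Unconstrained dynamic time warping between successive days.

Classic dynamic-programming DTW with local cost |a_i − b_j| and the
symmetric step set {(1,0), (0,1), (1,1)}, with *no* warping-window
constraint: an index may in principle warp across the full day.  The
optimal cumulative cost ("warping distance", in signal units) between each
adjacent pair of an animal's days measures day-to-day self-similarity;
dividing by the individual's overall SD separates proportional structure
from variability scale.  DTW is not a metric (the triangle inequality can
fail), which is tolerated — only pairwise distances are consumed.

The O(n·m) table is filled by a numba-compiled kernel; at the default day
length (1440 samples) a pair costs ~2 M cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .simulate import PhysioSeries

__all__ = [
    "DtwResult",
    "dtw_distance",
    "consecutive_day_distances",
    "sd_normalized_distances",
]


@dataclass
class DtwResult:
    """Optimal warping distance and one optimal path."""

    distance: float
    path: np.ndarray | None = None  # (L, 2) index pairs, (0,0) .. (n-1, m-1)
    normalized_distance: float | None = None


@njit(cache=False)
def _dtw_table(a, b):
    n, m = len(a), len(b)
    d = np.empty((n + 1, m + 1))
    d[0, :] = np.inf
    d[:, 0] = np.inf
    d[0, 0] = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            cost = abs(ai - b[j - 1])
            best = d[i - 1, j - 1]
            if d[i - 1, j] < best:
                best = d[i - 1, j]
            if d[i, j - 1] < best:
                best = d[i, j - 1]
            d[i, j] = cost + best
    return d


@njit(cache=False)
def _dtw_distance_only(a, b):
    # rolling two-row evaluation; same recurrence as _dtw_table
    n, m = len(a), len(b)
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    prev[:] = np.inf
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur[0] = np.inf
        ai = a[i - 1]
        for j in range(1, m + 1):
            cost = abs(ai - b[j - 1])
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = cost + best
        prev, cur = cur, prev
    return prev[m]


def _backtrack(d: np.ndarray) -> np.ndarray:
    """One optimal path; ties prefer diagonal, then vertical."""
    i, j = d.shape[0] - 1, d.shape[1] - 1
    path = [(i - 1, j - 1)]
    while i > 1 or j > 1:
        diag, vert, horiz = d[i - 1, j - 1], d[i - 1, j], d[i, j - 1]
        if diag <= vert and diag <= horiz:
            i, j = i - 1, j - 1
        elif vert <= horiz:
            i -= 1
        else:
            j -= 1
        path.append((i - 1, j - 1))
    return np.array(path[::-1], dtype=np.int64)


def dtw_distance(a, b, return_path: bool = True) -> DtwResult:
    """Optimal DTW distance (and one optimal path) between two sequences."""
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("inputs must be nonempty")
    if not return_path:
        return DtwResult(distance=float(_dtw_distance_only(a, b)))
    d = _dtw_table(a, b)
    return DtwResult(distance=float(d[-1, -1]), path=_backtrack(d))


def consecutive_day_distances(series: PhysioSeries) -> np.ndarray:
    """DTW distance between each adjacent pair of the animal's days.

    Returns ``n_days − 1`` distances (13 for the default 14-day record).
    Estrous staggering, when wanted, is applied upstream on the cohort
    matrix before slicing days.
    """
    spd = series.samples_per_day
    values = np.ascontiguousarray(series.values, dtype=np.float64)
    if len(values) % spd != 0:
        raise ValueError("record must contain a whole number of days")
    n_days = len(values) // spd
    if n_days < 2:
        raise ValueError("need at least 2 whole days")
    days = values.reshape(n_days, spd)
    return np.array(
        [
            float(_dtw_distance_only(days[k], days[k + 1]))
            for k in range(n_days - 1)
        ]
    )


def sd_normalized_distances(distances, series: PhysioSeries) -> np.ndarray:
    """Divide distances by the SD of the individual's full (cleaned) record."""
    sd = series.sd()
    if sd <= 0:
        raise ValueError(f"series {series.animal_id} has non-positive SD")
    return np.asarray(distances, dtype=float) / sd
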