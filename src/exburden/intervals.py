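"""Interval arithmetic on 0-based half-open intervals.

Intervals are represented as integer numpy arrays of shape (n, 2); an empty
interval set is a (0, 2) array. All public functions return canonical form:
sorted by start, pairwise disjoint, with abutting intervals coalesced.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_intervals",
    "merge_intervals",
    "subtract_intervals",
    "clip_intervals",
    "total_length",
    "contains_positions",
    "interval_positions",
]


def as_intervals(iv) -> np.ndarray:
    """Coerce a sequence of (start, end) pairs to an (n, 2) int64 array."""
    arr = np.asarray(iv, dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("intervals must be (n, 2) pairs")
    if np.any(arr[:, 0] >= arr[:, 1]):
        raise ValueError("intervals must satisfy start < end")
    return arr


def merge_intervals(iv) -> np.ndarray:
    """Minimal sorted disjoint cover of the union; abutting intervals coalesce."""
    arr = as_intervals(iv)
    if len(arr) == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:  # overlap or abut
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def subtract_intervals(a, b) -> np.ndarray:
    """Positions in ``a`` not covered by ``b`` (both merged internally)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    if len(a) == 0 or len(b) == 0:
        return a
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64) if out else np.empty((0, 2), dtype=np.int64)


def clip_intervals(iv, lo: int, hi: int) -> np.ndarray:
    """Intersect intervals with [lo, hi)."""
    arr = as_intervals(iv)
    if len(arr) == 0:
        return arr
    arr = arr.copy()
    arr[:, 0] = np.maximum(arr[:, 0], lo)
    arr[:, 1] = np.minimum(arr[:, 1], hi)
    return arr[arr[:, 0] < arr[:, 1]]


def total_length(iv) -> int:
    arr = as_intervals(iv)
    return int((arr[:, 1] - arr[:, 0]).sum()) if len(arr) else 0


def contains_positions(iv, positions) -> np.ndarray:
    """Boolean mask: does each position fall inside the (merged) intervals?"""
    arr = merge_intervals(iv)
    pos = np.asarray(positions, dtype=np.int64)
    if len(arr) == 0 or pos.size == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(arr[:, 0], pos, side="right") - 1
    ok = idx >= 0
    ok[ok] &= pos[ok] < arr[idx[ok], 1]
    return ok


def interval_positions(iv) -> np.ndarray:
    """Explicit sorted array of every position covered by the intervals."""
    arr = merge_intervals(iv)
    if len(arr) == 0:
        return np.empty(0, dtype=np.int64)
    return np.concatenate([np.arange(s, e, dtype=np.int64) for s, e in arr])
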