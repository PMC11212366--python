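"""Half-open interval arithmetic on numpy arrays.

All coordinates are 0-based half-open [start, end). Intervals within a
chromosome are represented as two int64 arrays (starts, ends) or as an
(n, 2) array. Functions here are deliberately free of any genome-format
knowledge; callers group by chromosome.
"""

from __future__ import annotations

import numpy as np


def as_array(intervals) -> np.ndarray:
    """Coerce a sequence of (start, end) pairs to an (n, 2) int64 array."""
    arr = np.asarray(intervals, dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of [start, end) pairs")
    if np.any(arr[:, 1] <= arr[:, 0]):
        raise ValueError("interval end must exceed start")
    return arr


def merge(intervals) -> np.ndarray:
    """Sort and merge overlapping or touching intervals."""
    arr = as_array(intervals)
    if len(arr) == 0:
        return arr
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def total_length(intervals) -> int:
    m = merge(intervals)
    return int((m[:, 1] - m[:, 0]).sum()) if len(m) else 0


def intersect_length(a, b) -> int:
    """Total number of bases in the intersection of two interval sets."""
    ma, mb = merge(a), merge(b)
    if len(ma) == 0 or len(mb) == 0:
        return 0
    i = j = 0
    total = 0
    while i < len(ma) and j < len(mb):
        lo = max(ma[i, 0], mb[j, 0])
        hi = min(ma[i, 1], mb[j, 1])
        if hi > lo:
            total += hi - lo
        if ma[i, 1] < mb[j, 1]:
            i += 1
        else:
            j += 1
    return int(total)


def intersect(a, b) -> np.ndarray:
    """Interval set forming the intersection of two interval sets."""
    ma, mb = merge(a), merge(b)
    out = []
    i = j = 0
    while i < len(ma) and j < len(mb):
        lo = max(ma[i, 0], mb[j, 0])
        hi = min(ma[i, 1], mb[j, 1])
        if hi > lo:
            out.append((lo, hi))
        if ma[i, 1] < mb[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def subtract(a, b) -> np.ndarray:
    """Bases of interval set ``a`` not covered by ``b``."""
    ma, mb = merge(a), merge(b)
    if len(ma) == 0:
        return ma
    if len(mb) == 0:
        return ma
    out = []
    j = 0
    for s, e in ma:
        cur = s
        while j < len(mb) and mb[j, 1] <= cur:
            j += 1
        k = j
        while k < len(mb) and mb[k, 0] < e:
            if mb[k, 0] > cur:
                out.append((cur, mb[k, 0]))
            cur = max(cur, mb[k, 1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def coverage_fraction(target, cover) -> float:
    """Fraction of bases of ``target`` covered by ``cover``."""
    tot = total_length(target)
    if tot == 0:
        return 0.0
    return intersect_length(target, cover) / tot


def overlaps_any(intervals, start: int, end: int) -> bool:
    m = merge(intervals)
    if len(m) == 0:
        return False
    idx = np.searchsorted(m[:, 0], end)
    return bool(idx > 0 and m[idx - 1, 1] > start)
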