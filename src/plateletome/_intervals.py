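"""Low-level interval algebra on sorted numpy arrays.

All coordinates are 0-based half-open ``[start, end)`` on a single
chromosome. Interval sets are represented as a pair of equal-length int64
arrays ``(starts, ends)``. "Merged" means sorted by start, pairwise disjoint
and non-adjacent-collapsed (maximal runs).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_arrays",
    "merge_arrays",
    "subtract_arrays",
    "intersect_size",
    "total_length",
    "overlaps_any",
    "overlap_join",
]


def as_arrays(intervals) -> tuple[np.ndarray, np.ndarray]:
    """Coerce an iterable of (start, end) pairs to a pair of int64 arrays."""
    pairs = list(intervals)
    if not pairs:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy()
    arr = np.asarray(pairs, dtype=np.int64)
    return np.ascontiguousarray(arr[:, 0]), np.ascontiguousarray(arr[:, 1])


def merge_arrays(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Union of possibly-overlapping intervals as a merged set.

    Touching intervals ([0,5),[5,9)) are collapsed into one run.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts.copy(), ends.copy()
    if np.any(ends <= starts):
        raise ValueError("empty or inverted interval (end <= start)")
    order = np.argsort(starts, kind="stable")
    s = starts[order]
    e = ends[order]
    cmax = np.maximum.accumulate(e)
    new_run = np.empty(s.size, dtype=bool)
    new_run[0] = True
    new_run[1:] = s[1:] > cmax[:-1]
    first = np.flatnonzero(new_run)
    last = np.append(first[1:], s.size) - 1
    return s[first], cmax[last]


def total_length(starts, ends) -> int:
    return int(np.sum(np.asarray(ends, dtype=np.int64) - np.asarray(starts, dtype=np.int64)))


def subtract_arrays(a_starts, a_ends, b_starts, b_ends) -> tuple[np.ndarray, np.ndarray]:
    """Base-set difference {bases in a} \\ {bases in b} as a merged set."""
    a_s, a_e = merge_arrays(a_starts, a_ends)
    if a_s.size == 0:
        return a_s, a_e
    b_s, b_e = merge_arrays(b_starts, b_ends)
    if b_s.size == 0:
        return a_s, a_e
    out_s: list[int] = []
    out_e: list[int] = []
    for s, e in zip(a_s.tolist(), a_e.tolist()):
        # b intervals overlapping [s, e): a contiguous slice since b is merged
        lo = int(np.searchsorted(b_e, s, side="right"))
        hi = int(np.searchsorted(b_s, e, side="left"))
        cur = s
        for j in range(lo, hi):
            if b_s[j] > cur:
                out_s.append(cur)
                out_e.append(int(b_s[j]))
            cur = max(cur, int(b_e[j]))
        if cur < e:
            out_s.append(cur)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def _coverage_below(x, starts, ends, prefix) -> np.ndarray:
    """Number of covered bases strictly below position x (vectorized).

    ``starts``/``ends`` must be merged; ``prefix`` is the cumulative covered
    length with a leading 0.
    """
    x = np.asarray(x, dtype=np.int64)
    i = np.searchsorted(starts, x, side="right") - 1
    i0 = np.maximum(i, 0)
    inside = np.clip(x - starts[i0], 0, ends[i0] - starts[i0])
    return np.where(i >= 0, prefix[i0] + inside, 0)


def intersect_size(a_starts, a_ends, b_starts, b_ends) -> int:
    """Number of bases in the intersection of two interval sets."""
    a_s, a_e = merge_arrays(a_starts, a_ends)
    b_s, b_e = merge_arrays(b_starts, b_ends)
    if a_s.size == 0 or b_s.size == 0:
        return 0
    prefix = np.concatenate([[0], np.cumsum(b_e - b_s)])
    return int(np.sum(_coverage_below(a_e, b_s, b_e, prefix) - _coverage_below(a_s, b_s, b_e, prefix)))


def coverage_function(starts, ends):
    """Return f(xs) -> covered bases below each x, for a merged set."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    prefix = np.concatenate([[0], np.cumsum(ends - starts)])

    def f(xs):
        if starts.size == 0:
            return np.zeros(np.asarray(xs).shape, dtype=np.int64)
        return _coverage_below(xs, starts, ends, prefix)

    return f


def overlaps_any(q_starts, q_ends, t_starts, t_ends) -> np.ndarray:
    """Boolean per query: does it overlap the merged target set by >= 1 base?"""
    q_s = np.asarray(q_starts, dtype=np.int64)
    q_e = np.asarray(q_ends, dtype=np.int64)
    t_s, t_e = merge_arrays(t_starts, t_ends)
    if t_s.size == 0:
        return np.zeros(q_s.size, dtype=bool)
    i = np.searchsorted(t_s, q_e, side="left")
    hit = i > 0
    i0 = np.maximum(i - 1, 0)
    return hit & (t_e[i0] > q_s)


def overlap_join(q_starts, q_ends, f_starts, f_ends):
    """All (query index, feature index, overlap bases) pairs with overlap >= 1.

    Features may overlap each other. Complexity is O((n+m) log m + pairs),
    assuming bounded stacking depth of the feature set.
    """
    q_s = np.asarray(q_starts, dtype=np.int64)
    q_e = np.asarray(q_ends, dtype=np.int64)
    f_s = np.asarray(f_starts, dtype=np.int64)
    f_e = np.asarray(f_ends, dtype=np.int64)
    empty = np.empty(0, dtype=np.int64)
    if q_s.size == 0 or f_s.size == 0:
        return empty, empty.copy(), empty.copy()
    order = np.argsort(f_s, kind="stable")
    fs = f_s[order]
    fe = f_e[order]
    cmax = np.maximum.accumulate(fe)
    hi = np.searchsorted(fs, q_e, side="left")
    lo = np.searchsorted(cmax, q_s, side="right")
    width = np.maximum(hi - lo, 0)
    if width.max(initial=0) == 0:
        return empty, empty.copy(), empty.copy()
    qi_out = []
    fi_out = []
    ov_out = []
    for d in range(int(width.max())):
        mask = width > d
        qi = np.flatnonzero(mask)
        j = lo[qi] + d
        ov = np.minimum(q_e[qi], fe[j]) - np.maximum(q_s[qi], fs[j])
        keep = ov > 0
        qi_out.append(qi[keep])
        fi_out.append(order[j[keep]])
        ov_out.append(ov[keep])
    return (
        np.concatenate(qi_out),
        np.concatenate(fi_out),
        np.concatenate(ov_out),
    )
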