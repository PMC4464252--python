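"""Half-open interval set arithmetic on numpy arrays.

All intervals are 0-based half-open ``[start, end)``.  An interval *set* is a
pair of equal-length int64 arrays ``(starts, ends)`` that is sorted by start
and pairwise disjoint (the output of :func:`merge`).
"""
from __future__ import annotations

import numpy as np

IntervalSet = tuple[np.ndarray, np.ndarray]

_EMPTY = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))


def _as_arrays(starts, ends) -> IntervalSet:
    s = np.asarray(starts, dtype=np.int64)
    e = np.asarray(ends, dtype=np.int64)
    if s.shape != e.shape:
        raise ValueError("starts and ends must have equal length")
    if np.any(e < s):
        raise ValueError("interval end < start")
    return s, e


def merge(starts, ends) -> IntervalSet:
    """Sort and merge possibly-overlapping intervals into a disjoint set.

    Touching intervals ([0,5) and [5,9)) are coalesced; empty intervals are
    dropped.
    """
    s, e = _as_arrays(starts, ends)
    keep = e > s
    s, e = s[keep], e[keep]
    if s.size == 0:
        return _EMPTY
    order = np.lexsort((e, s))
    s, e = s[order], e[order]
    cummax = np.maximum.accumulate(e)
    brk = np.empty(s.size, dtype=bool)
    brk[0] = True
    brk[1:] = s[1:] > cummax[:-1]
    first = np.flatnonzero(brk)
    last = np.append(first[1:] - 1, s.size - 1)
    return s[first].copy(), cummax[last].copy()


def total_length(iset: IntervalSet) -> int:
    s, e = iset
    return int((e - s).sum())


def contains(iset: IntervalSet, points) -> np.ndarray:
    """Boolean membership of each point in a merged interval set."""
    s, e = iset
    p = np.asarray(points, dtype=np.int64)
    if s.size == 0:
        return np.zeros(p.shape, dtype=bool)
    idx = np.searchsorted(s, p, side="right") - 1
    ok = idx >= 0
    hit = np.zeros(p.shape, dtype=bool)
    hit[ok] = p[ok] < e[idx[ok]]
    return hit


def union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return merge(np.concatenate([a[0], b[0]]), np.concatenate([a[1], b[1]]))


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Set difference a \\ b; both inputs must already be merged."""
    sa, ea = a
    sb, eb = b
    if sa.size == 0 or sb.size == 0:
        return (sa.copy(), ea.copy())
    out_s: list[int] = []
    out_e: list[int] = []
    j = 0
    for s, e in zip(sa.tolist(), ea.tolist()):
        cur = s
        while j < sb.size and eb[j] <= cur:
            j += 1
        k = j
        while k < sb.size and sb[k] < e:
            if sb[k] > cur:
                out_s.append(cur)
                out_e.append(int(sb[k]))
            cur = max(cur, int(eb[k]))
            if cur >= e:
                break
            k += 1
        if cur < e:
            out_s.append(cur)
            out_e.append(e)
    return (np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64))


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Set intersection of two merged interval sets."""
    sa, ea = a
    sb, eb = b
    out_s: list[int] = []
    out_e: list[int] = []
    i = j = 0
    while i < sa.size and j < sb.size:
        lo = max(sa[i], sb[j])
        hi = min(ea[i], eb[j])
        if hi > lo:
            out_s.append(int(lo))
            out_e.append(int(hi))
        if ea[i] < eb[j]:
            i += 1
        else:
            j += 1
    return (np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64))


def overlap_pairs(starts_a, ends_a, starts_b, ends_b):
    """All index pairs (i, j) with intervals a_i and b_j sharing >= 1 bp.

    Inputs need not be sorted or disjoint.  Returns three arrays:
    a-indices, b-indices, and overlap lengths.
    """
    sa, ea = _as_arrays(starts_a, ends_a)
    sb, eb = _as_arrays(starts_b, ends_b)
    if sa.size == 0 or sb.size == 0:
        return (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.int64))
    order_b = np.argsort(sb, kind="stable")
    sb_s, eb_s = sb[order_b], eb[order_b]
    cummax_eb = np.maximum.accumulate(eb_s)
    out_i: list[int] = []
    out_j: list[int] = []
    out_len: list[int] = []
    for i in range(sa.size):
        lo = np.searchsorted(cummax_eb, sa[i], side="right")
        hi = np.searchsorted(sb_s, ea[i], side="left")
        for j in range(lo, hi):
            length = min(ea[i], eb_s[j]) - max(sa[i], sb_s[j])
            if length >= 1:
                out_i.append(i)
                out_j.append(int(order_b[j]))
                out_len.append(int(length))
    return (
        np.asarray(out_i, dtype=np.int64),
        np.asarray(out_j, dtype=np.int64),
        np.asarray(out_len, dtype=np.int64),
    )
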