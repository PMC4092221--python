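"""Genomic interval arithmetic on half-open coordinates.

All coordinates are 0-based half-open ``[start, end)``; intervals are numpy
integer arrays of shape ``(n, 2)``.  Functions here operate on a single
chromosome; multi-chromosome callers group by chromosome first.
"""

from __future__ import annotations

import numpy as np

from .errors import PlacementError

__all__ = [
    "as_intervals",
    "merge_intervals",
    "total_length",
    "bp_overlap",
    "intersect_intervals",
    "complement_intervals",
    "overlaps_any",
    "interval_gap",
    "shuffle_intervals",
]


def as_intervals(intervals) -> np.ndarray:
    """Coerce to an ``(n, 2)`` int64 array and validate ``start <= end``."""
    arr = np.asarray(intervals, dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) interval array, got shape {arr.shape}")
    if np.any(arr[:, 0] > arr[:, 1]):
        raise ValueError("interval with start > end")
    return arr


def merge_intervals(intervals) -> np.ndarray:
    """Union-preserving minimal disjoint cover of the input intervals.

    Touching intervals (end == next start) are fused; zero-length intervals
    vanish into the union.
    """
    arr = as_intervals(intervals)
    arr = arr[arr[:, 0] < arr[:, 1]]
    if len(arr) == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    # a new merged block begins where start exceeds the running max end
    run_end = np.maximum.accumulate(arr[:, 1])
    new_block = np.ones(len(arr), dtype=bool)
    new_block[1:] = arr[1:, 0] > run_end[:-1]
    idx = np.flatnonzero(new_block)
    starts = arr[idx, 0]
    ends = np.append(run_end[idx[1:] - 1], run_end[-1])
    return np.column_stack([starts, ends])


def total_length(intervals) -> int:
    merged = merge_intervals(intervals)
    if len(merged) == 0:
        return 0
    return int((merged[:, 1] - merged[:, 0]).sum())


def bp_overlap(set_a, set_b) -> int:
    """Total base pairs in the intersection of two interval sets."""
    return total_length(intersect_intervals(set_a, set_b))


def intersect_intervals(set_a, set_b) -> np.ndarray:
    """Pairwise intersection of two interval sets as a merged disjoint cover."""
    a = merge_intervals(set_a)
    b = merge_intervals(set_b)
    if len(a) == 0 or len(b) == 0:
        return np.empty((0, 2), dtype=np.int64)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo < hi:
            out.append((lo, hi))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    return np.asarray(out, dtype=np.int64)


def complement_intervals(intervals, chrom_length: int) -> np.ndarray:
    """Gaps of ``[0, chrom_length)`` not covered by the (merged) input."""
    merged = merge_intervals(intervals)
    bounds = np.concatenate([[0], merged.ravel(), [chrom_length]])
    gaps = bounds.reshape(-1, 2)
    return gaps[gaps[:, 0] < gaps[:, 1]]


def overlaps_any(starts, ends, merged) -> np.ndarray:
    """Vectorised test of query intervals against a merged disjoint set.

    Returns a boolean array: query i overlaps some interval of ``merged``.
    """
    starts = np.atleast_1d(np.asarray(starts, dtype=np.int64))
    ends = np.atleast_1d(np.asarray(ends, dtype=np.int64))
    merged = as_intervals(merged)
    if len(merged) == 0:
        return np.zeros(len(starts), dtype=bool)
    # candidate: rightmost merged interval whose start < query end
    idx = np.searchsorted(merged[:, 0], ends, side="left") - 1
    hit = idx >= 0
    hit[hit] = merged[idx[hit], 1] > starts[hit]
    return hit


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two intervals; 0 when they overlap or touch."""
    return max(0, max(a_start, b_start) - min(a_end, b_end))


def shuffle_intervals(
    intervals,
    chrom_length: int,
    exclusions=None,
    *,
    rng=None,
    seed: int | None = None,
    max_retries: int = 1000,
    max_restarts: int = 20,
) -> np.ndarray:
    """Relocate intervals uniformly at random on the same chromosome.

    Each output interval keeps its input length, avoids ``exclusions``, and the
    outputs are mutually non-overlapping.  Placement is rejection sampling:
    each interval start is drawn uniformly from ``[0, chrom_length - size]``
    and redrawn (up to ``max_retries`` times) while it overlaps an exclusion
    or a previously placed interval; after a failure the whole set is
    restarted, up to ``max_restarts`` times, before ``PlacementError``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    arr = as_intervals(intervals)
    sizes = arr[:, 1] - arr[:, 0]
    excl = merge_intervals(exclusions) if exclusions is not None else np.empty((0, 2), np.int64)
    if np.any(sizes > chrom_length):
        raise PlacementError("an interval is longer than the chromosome")
    # place longest first: improves success odds without biasing the
    # per-interval uniform proposal
    order = np.argsort(-sizes)
    for _ in range(max_restarts):
        placed = np.empty((len(arr), 2), dtype=np.int64)
        taken = excl
        ok = True
        for rank, i in enumerate(order):
            size = int(sizes[i])
            hi = chrom_length - size
            for _ in range(max_retries):
                start = int(rng.integers(0, hi + 1))
                if not overlaps_any([start], [start + size], taken)[0]:
                    break
            else:
                ok = False
                break
            placed[i] = (start, start + size)
            taken = merge_intervals(np.vstack([taken, placed[i][None, :]]))
        if ok:
            return placed
    raise PlacementError(
        f"could not place {len(arr)} intervals after {max_restarts} restarts"
    )
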