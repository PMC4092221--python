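"""In-silico reversal of chromosomal inversions and synteny labelling.

Reverting an inversion ``[s, e)`` maps an interval ``[a, b)`` lying fully
inside it to ``[s + e - b, s + e - a)`` (reflection about the inversion
midpoint, length preserving); intervals fully outside are unchanged.
Intervals straddling a breakpoint are rejected and reported rather than
split (a split mode is available).  Applying inversions in series reverses
evolutionary events in order, most recent first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BreakpointSpanningError
from .hic import BinInteractionSet
from .intervals import as_intervals, overlaps_any

__all__ = [
    "Inversion",
    "invert_interval",
    "apply_inversion_series",
    "remap_links",
    "label_by_synteny",
]


@dataclass(frozen=True)
class Inversion:
    """A half-open chromosomal span ``[start, end)`` that was inverted."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("inversion needs start < end")


def invert_interval(interval: tuple[int, int], inversion: Inversion) -> tuple[int, int]:
    """Remap one interval through an inversion; straddling is an error."""
    a, b = interval
    s, e = inversion.start, inversion.end
    if b <= s or a >= e:
        return (a, b)
    if a >= s and b <= e:
        return (s + e - b, s + e - a)
    raise BreakpointSpanningError(
        f"interval [{a}, {b}) straddles inversion breakpoint of [{s}, {e})")


def _apply_one(starts: np.ndarray, ends: np.ndarray, inv: Inversion,
               split: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised single-inversion remap.

    Returns (starts, ends, straddle_mask) for the input order; in split mode
    straddlers are clipped into their inside and outside parts and appended,
    with the mask all-False.
    """
    s, e = inv.start, inv.end
    inside = (starts >= s) & (ends <= e)
    outside = (ends <= s) | (starts >= e)
    straddle = ~(inside | outside)
    new_s = starts.copy()
    new_e = ends.copy()
    new_s[inside] = s + e - ends[inside]
    new_e[inside] = s + e - starts[inside]
    if split and straddle.any():
        parts_s, parts_e = [new_s[~straddle]], [new_e[~straddle]]
        for a, b in zip(starts[straddle], ends[straddle]):
            for lo, hi in ((a, min(b, s)), (max(a, s), min(b, e)), (max(a, e), b)):
                if lo < hi:
                    ns, ne = invert_interval((int(lo), int(hi)), inv)
                    parts_s.append(np.array([ns]))
                    parts_e.append(np.array([ne]))
        new_s = np.concatenate(parts_s)
        new_e = np.concatenate(parts_e)
        straddle = np.zeros(len(new_s), dtype=bool)
    return new_s, new_e, straddle


def apply_inversion_series(
    features,
    inversions: list[Inversion],
    *,
    split: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Sequentially revert inversions (most recent event first) on intervals.

    Returns the remapped intervals of the surviving features and a rejection
    report of breakpoint-straddling intervals with the inversion that caused
    the rejection.  In split mode nothing is rejected; straddlers are cut at
    the breakpoints and each piece is remapped (feature count may grow).
    """
    arr = as_intervals(features)
    starts, ends = arr[:, 0].copy(), arr[:, 1].copy()
    rejected = []
    for order, inv in enumerate(inversions):
        starts, ends, straddle = _apply_one(starts, ends, inv, split)
        if straddle.any():
            for a, b in zip(starts[straddle], ends[straddle]):
                rejected.append((int(a), int(b), inv.chrom, inv.start, inv.end, order))
            starts, ends = starts[~straddle], ends[~straddle]
    report = pd.DataFrame(
        rejected,
        columns=["start", "end", "inv_chrom", "inv_start", "inv_end", "inv_index"])
    return np.column_stack([starts, ends]), report


def remap_links(
    bis: BinInteractionSet, inversions: list[Inversion]
) -> tuple[BinInteractionSet, pd.DataFrame]:
    """Remap both bin endpoints of every interaction through the inversions.

    Counts are unchanged; endpoint order is re-normalised afterwards
    (binA_start <= binB_start).  Links with a breakpoint-straddling bin are
    rejected and reported.
    """
    w = bis.bin_size
    a = bis.df["binA_start"].to_numpy().copy()
    b = bis.df["binB_start"].to_numpy().copy()
    alive = np.ones(len(a), dtype=bool)
    rejected = []
    for order, inv in enumerate(inversions):
        for arr in (a, b):
            ns, ne, straddle = _apply_one(arr[alive], arr[alive] + w, inv, False)
            sub = arr[alive]
            sub[~straddle] = ns[~straddle]
            arr[alive] = sub
            if straddle.any():
                idx = np.flatnonzero(alive)[straddle]
                for i in idx:
                    rejected.append((int(bis.df["binA_start"].iloc[i]),
                                     int(bis.df["binB_start"].iloc[i]),
                                     inv.chrom, inv.start, inv.end, order))
                alive[idx] = False
    df = bis.df[alive].copy()
    df["binA_start"] = a[alive]
    df["binB_start"] = b[alive]
    report = pd.DataFrame(
        rejected,
        columns=["binA_start", "binB_start", "inv_chrom", "inv_start", "inv_end",
                 "inv_index"])
    # reverted coordinates are generally off the bin grid
    return bis.replace(df, grid_aligned=False), report


def label_by_synteny(
    bin_starts,
    bin_size: int,
    synteny_blocks: pd.DataFrame,
    target_chrom: str,
) -> np.ndarray:
    """Binary label per bin: 1 iff the bin overlaps a block homologous to
    ``target_chrom`` (columns: start, end, target_chrom)."""
    starts = np.asarray(bin_starts, dtype=np.int64)
    blocks = synteny_blocks[synteny_blocks["target_chrom"] == target_chrom]
    if len(blocks) == 0:
        return np.zeros(len(starts), dtype=np.int64)
    from .intervals import merge_intervals

    merged = merge_intervals(blocks[["start", "end"]].to_numpy())
    return overlaps_any(starts, starts + bin_size, merged).astype(np.int64)
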