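"""Per-bin interaction profiles and genomic feature tracks.

Covers span-size decomposition of interaction counts per bin, interaction
intensity relative to the chromosome median, G-quadruplex motif scanning,
GC content, per-bin feature counts, gene density with a permutation p-value,
density comparison by Fisher's exact test, and intron size statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hic import BinInteractionSet
from .intervals import as_intervals, merge_intervals, overlaps_any

__all__ = [
    "SPAN_CLASS_EDGES",
    "SPAN_CLASS_NAMES",
    "Gene",
    "span_profile",
    "interaction_intensity",
    "g4_scan",
    "gc_track",
    "count_track",
    "gene_density_test",
    "region_count_fisher",
    "intron_size_stats",
]

# half-open span-size classes: <0.5, 0.5-1, 1-5, 5-10, 10-25, >=25 Mb
SPAN_CLASS_EDGES = np.array(
    [0, 500_000, 1_000_000, 5_000_000, 10_000_000, 25_000_000], dtype=np.int64)
SPAN_CLASS_NAMES = ["lt0.5Mb", "0.5to1Mb", "1to5Mb", "5to10Mb", "10to25Mb",
                    "ge25Mb"]


@dataclass
class Gene:
    """A gene model with absolute-coordinate exon blocks."""

    chrom: str
    start: int
    end: int
    name: str = "gene"
    strand: str = "+"
    exons: list = field(default_factory=list)  # [(start, end), ...] sorted

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons; single-exon genes yield none."""
        ex = sorted(self.exons)
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)
                if ex[i][1] < ex[i + 1][0]]


def span_profile(bis: BinInteractionSet, chrom_length: int) -> pd.DataFrame:
    """Relative contribution of each span-size class to each bin's total score.

    Every interaction credits its full count to both of its bins; per bin, the
    category scores are divided by the bin total (all-zero row when the bin
    has no interactions).
    """
    w = bis.bin_size
    n_bins = -(-chrom_length // w)
    cls = np.searchsorted(SPAN_CLASS_EDGES, bis.spans, side="right") - 1
    scores = np.zeros((n_bins, len(SPAN_CLASS_NAMES)))
    counts = bis.df["count"].to_numpy(dtype=float)
    for col in ("binA_start", "binB_start"):
        idx = bis.df[col].to_numpy() // w
        np.add.at(scores, (idx, cls), counts)
    totals = scores.sum(axis=1)
    fractions = np.divide(scores, totals[:, None],
                          out=np.zeros_like(scores), where=totals[:, None] > 0)
    out = pd.DataFrame(fractions, columns=SPAN_CLASS_NAMES)
    out.insert(0, "bin_start", np.arange(n_bins, dtype=np.int64) * w)
    out["total_score"] = totals
    return out


def interaction_intensity(bis: BinInteractionSet, chrom_length: int) -> pd.DataFrame:
    """Summed interaction counts per bin divided by the chromosome-wide median
    of those per-bin sums (all tiling bins enter the median)."""
    w = bis.bin_size
    n_bins = -(-chrom_length // w)
    totals = np.zeros(n_bins)
    counts = bis.df["count"].to_numpy(dtype=float)
    for col in ("binA_start", "binB_start"):
        np.add.at(totals, bis.df[col].to_numpy() // w, counts)
    med = float(np.median(totals))
    if med == 0:
        raise ValueError("median per-bin interaction count is zero")
    return pd.DataFrame({"bin_start": np.arange(n_bins, dtype=np.int64) * w,
                         "value": totals / med})


def _g_runs(codes: np.ndarray, base: int, min_tract: int) -> np.ndarray:
    """Maximal runs of ``base`` with length >= min_tract, as (start, end)."""
    mask = codes == base
    edges = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [len(codes)]])
    keep = (ends - starts) >= min_tract
    return np.column_stack([starts[keep], ends[keep]])


def _scan_one_strand(codes: np.ndarray, base: int, min_tract: int,
                     loop_min: int, loop_max: int) -> np.ndarray:
    runs = _g_runs(codes, base, min_tract)
    if len(runs) < 4:
        return np.empty((0, 2), dtype=np.int64)
    gaps = runs[1:, 0] - runs[:-1, 1]
    gap_ok = (gaps >= loop_min) & (gaps <= loop_max)
    # motif = runs i..i+3 with all three intervening gaps admissible
    quad_ok = gap_ok[:-2] & gap_ok[1:-1] & gap_ok[2:]
    idx = np.flatnonzero(quad_ok)
    return np.column_stack([runs[idx, 0], runs[idx + 3, 1]])


def g4_scan(
    sequence: str,
    min_tract: int = 3,
    loop_min: int = 1,
    loop_max: int = 7,
) -> pd.DataFrame:
    """Scan both strands for quadruplex-forming motifs.

    A motif is four maximal G-tracts of length >= ``min_tract`` separated by
    three loops of ``loop_min``..``loop_max`` bases (loops may contain G-runs
    shorter than ``min_tract`` but never a qualifying tract).  Overlapping
    calls within one strand are merged.  The reverse strand is scanned as the
    C-pattern and reported on plus-strand genome coordinates.  Ambiguous
    bases (N etc.) never extend a tract.
    """
    if len(sequence) == 0:
        return pd.DataFrame(columns=["start", "end", "strand"])
    codes = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = []
    for strand, base in (("+", ord("G")), ("-", ord("C"))):
        hits = _scan_one_strand(codes, base, min_tract, loop_min, loop_max)
        for s, e in merge_intervals(hits):
            out.append((int(s), int(e), strand))
    return pd.DataFrame(out, columns=["start", "end", "strand"])


def gc_track(sequence: str, bin_size: int = 100_000) -> pd.DataFrame:
    """Per-bin GC fraction among non-N bases; all-N bins are NaN."""
    seq = sequence.upper()
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = (codes == ord("G")) | (codes == ord("C"))
    is_base = is_gc | (codes == ord("A")) | (codes == ord("T"))
    n_bins = -(-len(seq) // bin_size)
    gc = np.zeros(n_bins)
    denom = np.zeros(n_bins)
    bin_idx = np.arange(len(seq)) // bin_size
    np.add.at(gc, bin_idx, is_gc)
    np.add.at(denom, bin_idx, is_base)
    vals = np.divide(gc, denom, out=np.full(n_bins, np.nan), where=denom > 0)
    return pd.DataFrame({"bin_start": np.arange(n_bins, dtype=np.int64) * bin_size,
                         "value": vals})


def count_track(
    intervals,
    chrom_length: int,
    bin_size: int = 100_000,
    mode: str = "start",
) -> pd.DataFrame:
    """Number of intervals per tiling bin.

    ``start`` mode assigns each interval to the bin containing its start
    (conserves the total count); ``overlap`` mode counts every bin an
    interval touches.
    """
    arr = as_intervals(intervals)
    n_bins = -(-chrom_length // bin_size)
    vals = np.zeros(n_bins, dtype=np.int64)
    if mode == "start":
        if len(arr):
            np.add.at(vals, arr[:, 0] // bin_size, 1)
    elif mode == "overlap":
        for s, e in arr:
            lo = int(s) // bin_size
            hi = (int(e) - 1) // bin_size if e > s else lo
            vals[lo:hi + 1] += 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame({"bin_start": np.arange(n_bins, dtype=np.int64) * bin_size,
                         "value": vals})


def _genes_overlapping(gene_intervals: np.ndarray, start: int, end: int) -> int:
    s, e = gene_intervals[:, 0], gene_intervals[:, 1]
    return int(((s < end) & (e > start)).sum())


def gene_density_test(
    genes,
    query_region: tuple[int, int],
    chrom_length: int,
    gaps=None,
    n_sim: int = 100_000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Gene density of a region with an empirical p-value from random regions.

    Density is genes overlapping the region per Mb.  The null re-places the
    query region uniformly on the chromosome (avoiding ``gaps``) ``n_sim``
    times; p = (1 + #{simulated density >= observed}) / (n_sim + 1).  Returns
    (density per Mb, mean simulated density per Mb, p).
    """
    rng = np.random.default_rng(seed)
    giv = np.array([(g.start, g.end) for g in genes], dtype=np.int64).reshape(-1, 2)
    qs, qe = query_region
    size = qe - qs
    if size <= 0 or qe > chrom_length:
        raise ValueError("query region must be a non-empty span on the chromosome")
    observed = _genes_overlapping(giv, qs, qe)
    starts = rng.integers(0, chrom_length - size + 1, size=n_sim)
    if gaps is not None:
        excl = merge_intervals(gaps)
        for _ in range(1000):
            bad = overlaps_any(starts, starts + size, excl)
            if not bad.any():
                break
            starts[bad] = rng.integers(0, chrom_length - size + 1, size=int(bad.sum()))
        else:
            raise RuntimeError("could not place simulated regions outside gaps")
    # vectorised overlap count: genes with start < region_end minus genes
    # with end <= region_start
    gs = np.sort(giv[:, 0])
    ge = np.sort(giv[:, 1])
    sim = (np.searchsorted(gs, starts + size, side="left")
           - np.searchsorted(ge, starts, side="right"))
    b = int((sim >= observed).sum())
    mb = size / 1e6
    return observed / mb, float(sim.mean()) / mb, (b + 1) / (n_sim + 1)


def region_count_fisher(
    count_a: int, size_a: int, count_b: int, size_b: int,
    size_unit: int = 100_000,
) -> float:
    """Two-sided Fisher exact p comparing feature densities of two regions.

    The 2x2 table is [[count_a, count_b], [windows_a - count_a,
    windows_b - count_b]] with windows the region sizes in ``size_unit``
    units; a negative cell is an error.
    """
    wa = round(size_a / size_unit)
    wb = round(size_b / size_unit)
    table = [[count_a, count_b], [wa - count_a, wb - count_b]]
    if min(table[1]) < 0:
        raise ValueError("feature count exceeds the number of windows; "
                         "choose a smaller size_unit")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def intron_size_stats(
    genes, region: tuple[int, int] | None = None, statistic: str = "median"
) -> tuple[float, np.ndarray]:
    """Intron lengths of genes (optionally restricted to those overlapping a
    region) and a summary statistic (median by default, or mean)."""
    lengths = []
    for g in genes:
        if region is not None and not (g.start < region[1] and g.end > region[0]):
            continue
        lengths.extend(e - s for s, e in g.introns())
    arr = np.asarray(lengths, dtype=np.int64)
    if len(arr) == 0:
        return float("nan"), arr
    if statistic == "median":
        return float(np.median(arr)), arr
    if statistic == "mean":
        return float(arr.mean()), arr
    raise ValueError(f"unknown statistic {statistic!r}")
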