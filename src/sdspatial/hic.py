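"""Binned Hi-C interactions: loading, count/span filtering, SD-aware removal,
and read-level unique-k-mer masking with distance re-normalisation.

The central container is :class:`BinInteractionSet`, a thin validated wrapper
around a pandas DataFrame with columns ``binA_start``, ``binB_start``,
``count`` (normalised contact count) for one chromosome at a fixed bin width.
Interactions are intrachromosomal and each unordered bin pair appears at most
once with ``binA_start <= binB_start``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IntegrityError, ParseError
from .intervals import as_intervals, merge_intervals, overlaps_any

__all__ = [
    "BinInteractionSet",
    "SDFilterReport",
    "UniqueMask",
    "similarity_class",
    "validate_sds",
    "sd_footprint",
    "load_interactions",
    "filter_count_span",
    "filter_sd_overlap",
    "build_unique_mask",
    "filter_reads_by_mask",
    "bin_and_renormalise",
]

SIMILARITY_CLASSES = ("lt98", "s98to99", "gt99")

READ_PAIR_COLUMNS = [
    "chromA", "posA", "strandA", "chromB", "posB", "strandB", "pair_id", "flag",
]


def similarity_class(identity: float) -> str:
    """UCSC-style colouring classes: <98%, 98-99%, >99% sequence identity."""
    if identity < 0.9:
        raise ValueError(f"identity {identity} below the 0.9 SD definition floor")
    if identity < 0.98:
        return "lt98"
    if identity <= 0.99:
        return "s98to99"
    return "gt99"


def validate_sds(sds: pd.DataFrame) -> pd.DataFrame:
    """Validate an SD table and (re)derive ``similarity_class`` from identity.

    Expected columns: chrom, start, end, paralog_chrom, paralog_start,
    paralog_end, identity (fraction of matching bases, >= 0.9).
    """
    required = ["chrom", "start", "end", "paralog_chrom", "paralog_start",
                "paralog_end", "identity"]
    missing = [c for c in required if c not in sds.columns]
    if missing:
        raise ValueError(f"SD table missing columns: {missing}")
    if len(sds) and sds["identity"].min() < 0.9:
        raise ValueError("SD identity below 0.9 violates the SD definition")
    sds = sds.copy()
    sds["similarity_class"] = [similarity_class(x) for x in sds["identity"]]
    return sds


def sd_footprint(sds: pd.DataFrame, chrom: str | None = None) -> np.ndarray:
    """Merged union of SD intervals and their paralog intervals on ``chrom``."""
    pieces = []
    own = sds if chrom is None else sds[sds["chrom"] == chrom]
    if len(own):
        pieces.append(own[["start", "end"]].to_numpy())
    par = sds if chrom is None else sds[sds["paralog_chrom"] == chrom]
    if len(par):
        pieces.append(par[["paralog_start", "paralog_end"]].to_numpy())
    if not pieces:
        return np.empty((0, 2), dtype=np.int64)
    return merge_intervals(np.vstack(pieces))


@dataclass
class BinInteractionSet:
    """Intrachromosomal binned interactions for one chromosome."""

    df: pd.DataFrame
    bin_size: int
    chrom: str = "chr1"
    # inversion remapping can move bins off the bin_size grid; remapped sets
    # carry grid_aligned=False to skip the modulus check
    grid_aligned: bool = True

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        for col in ("binA_start", "binB_start", "count"):
            if col not in df.columns:
                raise ValueError(f"missing column {col!r}")
        a = df["binA_start"].to_numpy()
        b = df["binB_start"].to_numpy()
        swap = a > b
        if swap.any():
            df = df.copy()
            df.loc[swap, ["binA_start", "binB_start"]] = df.loc[
                swap, ["binB_start", "binA_start"]].to_numpy()
            a, b = df["binA_start"].to_numpy(), df["binB_start"].to_numpy()
        if len(df):
            if self.grid_aligned and (
                    (a % self.bin_size != 0) | (b % self.bin_size != 0)).any():
                raise ValueError("bin starts must be multiples of bin_size")
            if (df["count"].to_numpy() < 0).any():
                raise ValueError("negative interaction count")
            if pd.DataFrame({"a": a, "b": b}).duplicated().any():
                raise IntegrityError("duplicate unordered bin pair")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def spans(self) -> np.ndarray:
        """Linear genomic span (bp) between the two bins of each interaction."""
        return (self.df["binB_start"] - self.df["binA_start"]).to_numpy()

    def replace(self, df: pd.DataFrame, grid_aligned: bool | None = None) -> "BinInteractionSet":
        if grid_aligned is None:
            grid_aligned = self.grid_aligned
        return BinInteractionSet(df, bin_size=self.bin_size, chrom=self.chrom,
                                 grid_aligned=grid_aligned)

    def to_tsv(self, path) -> None:
        self.df[["binA_start", "binB_start", "count"]].to_csv(
            path, sep="\t", header=False, index=False)


@dataclass
class SDFilterReport:
    """Tally of interaction rows and distinct genomic windows removed."""

    mode: str
    removed_rows: int
    removed_windows: int


@dataclass
class UniqueMask:
    """Start positions inside the SD footprint whose k-mers are genome-unique."""

    chrom: str
    unique_intervals: np.ndarray  # intervals of unique k-mer START positions
    footprint: np.ndarray         # merged SD footprint the mask lives in
    k: int = 30
    max_edits: int = 2


def load_interactions(path, bin_size: int, chrom: str = "chr1") -> BinInteractionSet:
    """Read tab-separated ``binA_start  binB_start  count`` triplets."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"expected 3 tab-separated fields, got {len(parts)}",
                                 line=lineno)
            try:
                a, b, c = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            rows.append((a, b, c))
    df = pd.DataFrame(rows, columns=["binA_start", "binB_start", "count"])
    return BinInteractionSet(df, bin_size=bin_size, chrom=chrom)


def filter_count_span(bis: BinInteractionSet, min_count: float,
                      min_span_bp: int) -> BinInteractionSet:
    """Keep interactions with ``count >= min_count`` and span ``>= min_span_bp``.

    Both thresholds are inclusive ("at least 15 counts", "at least 25 Mb").
    """
    if min_count < 0 or min_span_bp < 0:
        raise ValueError("thresholds must be non-negative")
    keep = (bis.df["count"] >= min_count) & (bis.spans >= min_span_bp)
    return bis.replace(bis.df[keep])


def _bin_overlap_flags(bis: BinInteractionSet, merged) -> tuple[np.ndarray, np.ndarray]:
    a = bis.df["binA_start"].to_numpy()
    b = bis.df["binB_start"].to_numpy()
    w = bis.bin_size
    return (overlaps_any(a, a + w, merged), overlaps_any(b, b + w, merged))


def filter_sd_overlap(
    bis: BinInteractionSet,
    sds: pd.DataFrame,
    mode: str = "none",
) -> tuple[BinInteractionSet, SDFilterReport]:
    """Remove interactions by SD overlap.

    ``paralog_pairs``: a row is removed iff one bin overlaps an SD interval S
    and the other bin overlaps S's paralog interval (an alignment-artifact
    candidate: a short-range contact misread as long-range).  ``any_sd``: a
    row is removed iff either bin overlaps any SD or paralog interval.
    ``none`` is the identity.
    """
    if mode not in ("none", "paralog_pairs", "any_sd"):
        raise ValueError(f"unknown SD filter mode {mode!r}")
    n = len(bis)
    if mode == "none" or n == 0 or len(sds) == 0:
        return bis, SDFilterReport(mode, 0, 0)
    sds = validate_sds(sds)
    w = bis.bin_size
    if mode == "any_sd":
        merged = sd_footprint(sds, bis.chrom)
        hit_a, hit_b = _bin_overlap_flags(bis, merged)
        remove = hit_a | hit_b
    else:
        remove = np.zeros(n, dtype=bool)
        a = bis.df["binA_start"].to_numpy()
        b = bis.df["binB_start"].to_numpy()
        for sd in sds.itertuples(index=False):
            in_s_a = in_s_b = in_p_a = in_p_b = None
            if sd.chrom == bis.chrom:
                seg = np.array([[sd.start, sd.end]])
                in_s_a = overlaps_any(a, a + w, seg)
                in_s_b = overlaps_any(b, b + w, seg)
            if sd.paralog_chrom == bis.chrom:
                par = np.array([[sd.paralog_start, sd.paralog_end]])
                in_p_a = overlaps_any(a, a + w, par)
                in_p_b = overlaps_any(b, b + w, par)
            if in_s_a is None or in_p_a is None:
                continue
            remove |= (in_s_a & in_p_b) | (in_p_a & in_s_b)
    removed = bis.df[remove]
    windows = {*removed["binA_start"], *removed["binB_start"]}
    report = SDFilterReport(mode, int(remove.sum()), len(windows))
    return bis.replace(bis.df[~remove]), report


def _hamming_unique(seq_codes: np.ndarray, starts: np.ndarray, k: int,
                    max_edits: int) -> np.ndarray:
    """Boolean per start: the k-mer has no second occurrence within Hamming
    distance ``max_edits`` anywhere in the genome (brute force; desk scale)."""
    L = len(seq_codes)
    n_win = L - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(seq_codes, k)
    if max_edits == 0:
        # hash exact k-mers over the whole genome
        counts: dict[bytes, int] = {}
        raw = windows.tobytes()
        itemsize = k * seq_codes.itemsize
        keys = [raw[i * itemsize:(i + 1) * itemsize] for i in range(n_win)]
        for key in keys:
            counts[key] = counts.get(key, 0) + 1
        return np.array([counts[keys[p]] == 1 for p in starts])
    out = np.empty(len(starts), dtype=bool)
    for i, p in enumerate(starts):
        mism = (windows != windows[p]).sum(axis=1)
        mism[p] = max_edits + 1  # ignore self
        out[i] = not np.any(mism <= max_edits)
    return out


def _edit_distance_leq(a: str, b: str, bound: int) -> bool:
    """Banded Levenshtein distance test ``d(a, b) <= bound``."""
    la, lb = len(a), len(b)
    if abs(la - lb) > bound:
        return False
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        lo = max(1, i - bound)
        hi = min(lb, i + bound)
        if lo > 1:
            cur[lo - 1] = bound + 1
        for j in range(lo, hi + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (a[i - 1] != b[j - 1]))
        if min(cur[lo:hi + 1]) > bound:
            return False
        prev = cur
    return prev[lb] <= bound


def build_unique_mask(
    sequence: str,
    sds: pd.DataFrame,
    k: int = 30,
    max_edits: int = 0,
    *,
    chrom: str = "chr1",
    edit_mode: str = "hamming",
) -> UniqueMask:
    """Tile the merged SD footprint into k-mers and keep genome-unique starts.

    A start position p (with ``[p, p+k)`` inside one footprint interval) is
    unique iff the k-mer beginning there occurs nowhere else in the genome
    within the edit bound.  ``edit_mode='hamming'`` (default) counts
    substitutions only; ``'levenshtein'`` allows indels and is intended for
    small genomes (quadratic scan).
    """
    sds = validate_sds(sds)
    footprint = sd_footprint(sds, chrom)
    seq = sequence.upper()
    starts = []
    for s, e in footprint:
        if e - s >= k:
            starts.extend(range(int(s), int(e) - k + 1))
    if not starts:
        warnings.warn(f"k={k} exceeds every SD region; unique mask is empty")
        return UniqueMask(chrom, np.empty((0, 2), np.int64), footprint, k, max_edits)
    starts = np.asarray(starts, dtype=np.int64)
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if edit_mode == "hamming":
        unique = _hamming_unique(codes, starts, k, max_edits)
    elif edit_mode == "levenshtein":
        if max_edits == 0:
            unique = _hamming_unique(codes, starts, k, 0)
        else:
            unique = np.empty(len(starts), dtype=bool)
            for i, p in enumerate(starts):
                kmer = seq[p:p + k]
                hits = 0
                for q in range(0, len(seq) - k + 1):
                    if q == p:
                        continue
                    if _edit_distance_leq(kmer, seq[q:q + k], max_edits):
                        hits += 1
                        break
                unique[i] = hits == 0
    else:
        raise ValueError(f"unknown edit_mode {edit_mode!r}")
    ustarts = starts[unique]
    if len(ustarts) == 0:
        runs = np.empty((0, 2), dtype=np.int64)
    else:
        brk = np.flatnonzero(np.diff(ustarts) != 1)
        run_start = np.concatenate([[0], brk + 1])
        run_end = np.concatenate([brk, [len(ustarts) - 1]])
        runs = np.column_stack([ustarts[run_start], ustarts[run_end] + 1])
    return UniqueMask(chrom, runs, footprint, k, max_edits)


def filter_reads_by_mask(
    reads: pd.DataFrame, mask: UniqueMask
) -> tuple[pd.DataFrame, int]:
    """Drop read pairs with an end inside the SD footprint but outside the mask.

    Ends outside the footprint are always acceptable; an end inside the
    footprint must start within a unique interval of the mask.
    """
    keep = np.ones(len(reads), dtype=bool)
    for col, chrom_col in (("posA", "chromA"), ("posB", "chromB")):
        pos = reads[col].to_numpy()
        on_chrom = (reads[chrom_col] == mask.chrom).to_numpy()
        in_fp = overlaps_any(pos, pos + 1, mask.footprint) & on_chrom
        in_mask = overlaps_any(pos, pos + 1, mask.unique_intervals)
        keep &= ~(in_fp & ~in_mask)
    retained = reads[keep].reset_index(drop=True)
    return retained, int((~keep).sum())


def _bin_pairs(reads: pd.DataFrame, bin_size: int) -> pd.DataFrame:
    a = (reads["posA"].to_numpy() // bin_size) * bin_size
    b = (reads["posB"].to_numpy() // bin_size) * bin_size
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    return (pd.DataFrame({"binA_start": lo, "binB_start": hi})
            .groupby(["binA_start", "binB_start"], as_index=False)
            .size().rename(columns={"size": "count"}))


def bin_and_renormalise(
    retained: pd.DataFrame,
    unfiltered: pd.DataFrame,
    bin_size: int,
    chrom_length: int,
    chrom: str = "chr1",
) -> BinInteractionSet:
    """Bin read pairs and normalise by distance-stratified expected contacts.

    The expected count at bin distance d is the mean unfiltered read-pair
    count over all possible bin pairs of the chromosome at distance d; the
    re-normalised count of an observed filtered bin pair is observed /
    expected(d).  Strata with zero expected count are dropped.
    """
    n_bins = -(-chrom_length // bin_size)
    obs = _bin_pairs(retained, bin_size)
    unf = _bin_pairs(unfiltered, bin_size)
    d_unf = (unf["binB_start"] - unf["binA_start"]) // bin_size
    totals = unf.groupby(d_unf)["count"].sum()
    d_obs = ((obs["binB_start"] - obs["binA_start"]) // bin_size).to_numpy()
    n_pairs_at = (n_bins - d_obs).astype(float)
    expected = totals.reindex(d_obs).fillna(0.0).to_numpy() / n_pairs_at
    keep = expected > 0
    out = obs[keep].copy()
    out["count"] = obs["count"].to_numpy()[keep] / expected[keep]
    return BinInteractionSet(out, bin_size=bin_size, chrom=chrom)
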