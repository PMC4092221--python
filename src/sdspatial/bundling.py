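"""Bundling of long-distance interactions and threshold-sweep intersection.

A bundle aggregates interactions whose start-side bins and target-side bins
each lie within a maximum gap of one another (the Circos ``bundlelinks``
criterion: at least ``min_membership`` interactions within ``bundle_gap`` at
both the start and the target site).  The default grouping is transitive
single linkage; a sorted-order greedy chaining variant is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hic import BinInteractionSet, filter_count_span, filter_sd_overlap
from .intervals import merge_intervals, overlaps_any, total_length

__all__ = [
    "Bundle",
    "SweepConfig",
    "SweepResult",
    "default_sweep_configs",
    "bundle_links",
    "bundle_coverage",
    "threshold_sweep",
    "core_shared_target_bundles",
]


@dataclass
class Bundle:
    """A start-region/target-region pair with its member interaction count."""

    start_region: tuple[int, int]
    target_region: tuple[int, int]
    members: int
    member_index: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64),
                                     repr=False)


@dataclass
class SweepConfig:
    """One combination of filter cut-offs for the threshold sweep."""

    min_count: float = 15.0
    max_count: float | None = None
    min_span: int = 25_000_000
    sd_mode: str = "none"
    bundle_gap: int = 500_000
    min_membership: int = 5

    def __post_init__(self):
        if self.max_count is not None and self.min_count > self.max_count:
            raise ValueError("min_count > max_count")

    def label(self) -> str:
        hi = "inf" if self.max_count is None else f"{self.max_count:g}"
        return (f"count[{self.min_count:g},{hi}]_span{self.min_span}"
                f"_sd-{self.sd_mode}")


def default_sweep_configs(
    min_counts=((10.0, None), (15.0, None), (10.0, 50.0)),
    min_spans=(10_000_000, 25_000_000),
    sd_modes=("none", "paralog_pairs"),
    bundle_gap: int = 500_000,
    min_membership: int = 5,
) -> list[SweepConfig]:
    """The default 12-combination preset: 3 count cut-offs x 2 span sizes x
    2 SD-overlap handling modes."""
    return [
        SweepConfig(lo, hi, span, mode, bundle_gap, min_membership)
        for (lo, hi) in min_counts for span in min_spans for mode in sd_modes
    ]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _single_linkage_groups(ia: np.ndarray, ib: np.ndarray, g: int) -> np.ndarray:
    """Connected components of links under 'gap <= bundle_gap on both sides'.

    In bin units the adjacency is a Chebyshev-style ball: two links connect
    iff |dA| <= g AND |dB| <= g.  Links are hashed to cells of width g+1 in
    (binA, binB) space: same-cell links are always adjacent, so exact single
    linkage needs pairwise checks only between neighbouring occupied cells.
    """
    n = len(ia)
    cell = g + 1
    ca, cb = ia // cell, ib // cell
    cells: dict[tuple[int, int], list[int]] = {}
    for i in range(n):
        cells.setdefault((int(ca[i]), int(cb[i])), []).append(i)
    uf = _UnionFind(n)
    for members in cells.values():
        for j in members[1:]:
            uf.union(members[0], j)
    offsets = [(0, 1), (1, -1), (1, 0), (1, 1)]
    for (cx, cy), members in cells.items():
        for dx, dy in offsets:
            other = cells.get((cx + dx, cy + dy))
            if not other:
                continue
            u = np.asarray(members)
            v = np.asarray(other)
            close = (np.abs(ia[u][:, None] - ia[v]) <= g) & \
                    (np.abs(ib[u][:, None] - ib[v]) <= g)
            if close.any():
                # all links within one cell are already unioned, so a single
                # qualifying cross pair merges both cells; but partial
                # adjacency cannot occur here for that reason
                pairs = np.argwhere(close)
                uf.union(int(u[pairs[0, 0]]), int(v[pairs[0, 1]]))
    roots = np.fromiter((uf.find(i) for i in range(n)), dtype=np.int64, count=n)
    return roots


def _greedy_groups(ia: np.ndarray, ib: np.ndarray, g: int) -> np.ndarray:
    """Sorted-order chaining: each link joins the previous link's group iff
    adjacent to it; mimics a greedy streaming bundler."""
    order = np.lexsort((ib, ia))
    roots = np.empty(len(ia), dtype=np.int64)
    group = -1
    prev = None
    for idx in order:
        if prev is None or abs(ia[idx] - ia[prev]) > g or abs(ib[idx] - ib[prev]) > g:
            group = idx
        roots[idx] = group
        prev = idx
    return roots


def bundle_links(
    bis: BinInteractionSet,
    bundle_gap: int = 500_000,
    min_membership: int = 5,
    method: str = "single",
) -> list[Bundle]:
    """Fuse interactions into bundles; groups below ``min_membership`` drop.

    Two links are adjacent iff the gap between their start-side bin intervals
    and the gap between their target-side bin intervals are both
    ``<= bundle_gap`` (boundary inclusive; overlapping bins have gap 0).
    Emitted regions are the bounding spans of member bins.
    """
    if len(bis) == 0:
        return []
    w = bis.bin_size
    ia = (bis.df["binA_start"].to_numpy() // w).astype(np.int64)
    ib = (bis.df["binB_start"].to_numpy() // w).astype(np.int64)
    # interval gap <= bundle_gap  <=>  |start difference| <= bundle_gap + w,
    # i.e. in bin units |di| <= g with g = bundle_gap // w + 1 (w | bundle_gap
    # not required; use exact bp arithmetic on the bin grid)
    g = (bundle_gap + w) // w  # |di| * w - w <= bundle_gap
    if method == "single":
        roots = _single_linkage_groups(ia, ib, g)
    elif method == "greedy":
        roots = _greedy_groups(ia, ib, g)
    else:
        raise ValueError(f"unknown bundling method {method!r}")
    bundles = []
    for root in pd.unique(roots):
        idx = np.flatnonzero(roots == root)
        if len(idx) < min_membership:
            continue
        sa = bis.df["binA_start"].to_numpy()[idx]
        sb = bis.df["binB_start"].to_numpy()[idx]
        bundles.append(Bundle(
            start_region=(int(sa.min()), int(sa.max()) + w),
            target_region=(int(sb.min()), int(sb.max()) + w),
            members=len(idx),
            member_index=idx,
        ))
    bundles.sort(key=lambda b: (b.start_region, b.target_region))
    return bundles


def _bundle_regions(bundles: list[Bundle]) -> np.ndarray:
    if not bundles:
        return np.empty((0, 2), dtype=np.int64)
    return np.asarray(
        [b.start_region for b in bundles] + [b.target_region for b in bundles],
        dtype=np.int64)


def bundle_coverage(bundles: list[Bundle], chrom_length: int) -> tuple[int, float]:
    """Union coverage (bp, fraction of chromosome) of all bundle regions."""
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    covered = total_length(_bundle_regions(bundles))
    return covered, covered / chrom_length


@dataclass
class SweepResult:
    """Per-bin bundle-coverage frequency across sweep configurations."""

    bin_size: int
    bin_starts: np.ndarray
    frequency: np.ndarray          # fraction of configs covering each bin
    bundles_per_config: list[list[Bundle]]
    configs: list[SweepConfig]

    @property
    def core_bins(self) -> np.ndarray:
        """Starts of bins covered by bundle regions in every configuration."""
        return self.bin_starts[self.frequency >= 1.0]

    def frequency_table(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_start": self.bin_starts,
                             "frequency": self.frequency})


def threshold_sweep(
    raw: BinInteractionSet,
    configs: list[SweepConfig],
    chrom_length: int,
    sds: pd.DataFrame | None = None,
    method: str = "single",
) -> SweepResult:
    """Run filter+bundle for every configuration and intersect coverage.

    For every genomic bin the frequency is the fraction of configurations
    whose bundle regions cover that bin; core bins have frequency 1 (the
    threshold-independent interaction pattern).
    """
    if not configs:
        raise ValueError("at least one sweep configuration is required")
    w = raw.bin_size
    n_bins = -(-chrom_length // w)
    starts = np.arange(n_bins, dtype=np.int64) * w
    covered_count = np.zeros(n_bins, dtype=np.int64)
    per_config = []
    for cfg in configs:
        bis = filter_count_span(raw, cfg.min_count, cfg.min_span)
        if cfg.max_count is not None:
            bis = bis.replace(bis.df[bis.df["count"] <= cfg.max_count])
        if cfg.sd_mode != "none":
            if sds is None:
                raise ValueError(f"config {cfg.label()} needs an SD table")
            bis, _ = filter_sd_overlap(bis, sds, cfg.sd_mode)
        bundles = bundle_links(bis, cfg.bundle_gap, cfg.min_membership, method)
        per_config.append(bundles)
        regions = merge_intervals(_bundle_regions(bundles))
        covered_count += overlaps_any(starts, starts + w, regions)
    return SweepResult(w, starts, covered_count / len(configs), per_config, configs)


def _regions_close(r1: tuple[int, int], r2: tuple[int, int], gap: int) -> bool:
    return max(r1[0], r2[0]) - min(r1[1], r2[1]) <= gap


def core_shared_target_bundles(
    sweep: SweepResult, bundle_gap: int = 500_000
) -> list[Bundle]:
    """Bundles restricted to core regions that map to the same target sites.

    A bundle of the first configuration is emitted iff its start and target
    regions both touch core bins and every other configuration has a bundle
    whose start and target regions are each within ``bundle_gap`` of it.
    """
    core = sweep.core_bins
    if len(core) == 0:
        return []
    w = sweep.bin_size
    core_iv = merge_intervals(np.column_stack([core, core + w]))
    out = []
    for cand in sweep.bundles_per_config[0]:
        if not (overlaps_any([cand.start_region[0]], [cand.start_region[1]], core_iv)[0]
                and overlaps_any([cand.target_region[0]], [cand.target_region[1]],
                                 core_iv)[0]):
            continue
        shared = all(
            any(_regions_close(cand.start_region, b.start_region, bundle_gap)
                and _regions_close(cand.target_region, b.target_region, bundle_gap)
                for b in bundles)
            for bundles in sweep.bundles_per_config[1:]
        )
        if shared:
            out.append(cand)
    return out
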