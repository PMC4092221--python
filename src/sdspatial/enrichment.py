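"""Enrichment statistics.

Two engines drive the analysis:

* a Monte-Carlo base-pair-overlap test, where a feature interval set (e.g. an
  SD similarity category) is repeatedly relocated by a constrained shuffle
  (same chromosome, same sizes, mutually non-overlapping, gap exclusions) and
  the observed overlap with a bundle set is compared with the resampled
  overlaps; p = (b + 1) / (n_sim + 1) with b the number of simulations whose
  overlap is greater than or equal to the observed one, and per-category
  p-values are adjusted jointly by Benjamini-Hochberg;

* the minimum hypergeometric (mHG) statistic on a ranked binary label list,
  with its exact p-value computed by path counting on the (n, b) lattice.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats

from .intervals import (bp_overlap, merge_intervals, shuffle_intervals,
                        total_length)

__all__ = [
    "OverlapTestResult",
    "MHGResult",
    "merge_intervals",
    "bp_overlap",
    "shuffle_intervals",
    "overlap_permutation_test",
    "overlap_enrichment_panel",
    "bh_adjust",
    "mhg_statistic",
    "mhg_exact_pvalue",
    "ranked_bin_enrichment",
    "spearman_track_correlation",
]


@dataclass
class OverlapTestResult:
    """Outcome of one Monte-Carlo base-pair-overlap test."""

    category: str
    observed_bp: int
    expected_mean_bp: float
    fold_change: float  # nan when the null mean is zero (undefined)
    exceed_count: int   # simulations with expected >= observed
    n_sim: int
    p: float
    p_adjusted: float | None = None
    degenerate: bool = False


def overlap_permutation_test(
    feature_intervals,
    bundle_intervals,
    chrom_length: int,
    *,
    exclusions=None,
    n_sim: int = 10_000,
    seed: int | None = None,
    rng=None,
    category: str = "features",
) -> OverlapTestResult:
    """Monte-Carlo overlap test of a feature set against bundle regions.

    Both inputs are merged before testing.  Exceedance is inclusive
    ("greater or equal"), so p never returns 0 and the minimum achievable
    p is 1 / (n_sim + 1).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    features = merge_intervals(feature_intervals)
    bundles = merge_intervals(bundle_intervals)
    if total_length(features) == 0:
        return OverlapTestResult(category, 0, 0.0, float("nan"), n_sim,
                                 n_sim, 1.0, degenerate=True)
    observed = bp_overlap(features, bundles)
    expected = np.empty(n_sim, dtype=np.int64)
    for i in range(n_sim):
        placed = shuffle_intervals(features, chrom_length, exclusions, rng=rng)
        expected[i] = bp_overlap(placed, bundles)
    b = int((expected >= observed).sum())
    mean = float(expected.mean())
    fold = observed / mean if mean > 0 else float("nan")
    p = (b + 1) / (n_sim + 1)
    return OverlapTestResult(category, int(observed), mean, fold, b, n_sim, p)


def overlap_enrichment_panel(
    categories: dict,
    bundle_intervals,
    chrom_length: int,
    *,
    exclusions=None,
    n_sim: int = 10_000,
    seed: int | None = None,
) -> list[OverlapTestResult]:
    """Run the overlap test per category and BH-adjust across the panel.

    The adjustment family is exactly the set of categories passed in one call.
    """
    rng = np.random.default_rng(seed)
    results = [
        overlap_permutation_test(iv, bundle_intervals, chrom_length,
                                 exclusions=exclusions, n_sim=n_sim, rng=rng,
                                 category=name)
        for name, iv in categories.items()
    ]
    adjusted = bh_adjust([r.p for r in results])
    for r, q in zip(results, adjusted):
        r.p_adjusted = float(q)
    return results


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return stats.false_discovery_control(p, method="bh")


@dataclass
class MHGResult:
    """Minimum-hypergeometric enrichment over the prefixes of a ranked list."""

    N: int
    B: int
    scores: np.ndarray  # hypergeometric tail HGT(b_n; N, B, n) per prefix n=1..N
    mhg: float
    n_star: int         # prefix length attaining the minimum (first argmin)
    p_exact: float | None = None
    direction: str | None = None


def mhg_statistic(labels) -> MHGResult:
    """mHG over all prefixes of a binary label vector in ranked order.

    HGT(b; N, B, n) is the upper hypergeometric tail P[X >= b] for X drawn
    as the number of labelled items in an n-prefix of a random permutation.
    By convention mhg = 1 when B = 0.
    """
    lab = np.asarray(labels, dtype=np.int64)
    if lab.ndim != 1 or len(lab) == 0:
        raise ValueError("labels must be a non-empty 1-D binary vector")
    if np.any((lab != 0) & (lab != 1)):
        raise ValueError("labels must be 0/1")
    N = len(lab)
    B = int(lab.sum())
    n = np.arange(1, N + 1)
    b = np.cumsum(lab)
    scores = stats.hypergeom.sf(b - 1, N, B, n)
    if B == 0:
        return MHGResult(N, B, scores, 1.0, 1)
    n_star = int(np.argmin(scores)) + 1
    return MHGResult(N, B, scores, float(scores[n_star - 1]), n_star)


_REL_TOL = 1e-9  # guard float HGT comparisons at the threshold


def mhg_exact_pvalue(mhg: float, N: int, B: int) -> float:
    """Exact p-value of an mHG score by lattice path counting.

    Under a uniform random permutation of B labels among N positions, counts
    the label orderings whose own mHG is <= the given score: paths on the
    (n, b) lattice are blocked at every cell whose hypergeometric tail is
    <= mhg, and the surviving path count at (N, B) is compared with C(N, B).
    Path counts are exact integers; only the tail comparisons are floating
    point (with a small relative guard).
    """
    if not (0 < mhg <= 1):
        raise ValueError("mhg must lie in (0, 1]")
    if B == 0 or mhg >= 1.0:
        return 1.0
    thresh = mhg * (1 + _REL_TOL)
    # pi[b] = number of length-n binary prefixes with b ones avoiding all
    # blocked cells; python ints keep the DP exact at any N
    pi = [1] + [0] * B
    for n in range(1, N + 1):
        b_lo = max(0, n - (N - B))
        b_hi = min(n, B)
        tails = stats.hypergeom.sf(np.arange(b_lo, b_hi + 1) - 1, N, B, n)
        for b in range(b_hi, -1, -1):
            prev = pi[b]
            if b > 0:
                prev += pi[b - 1]
            if b_lo <= b <= b_hi and tails[b - b_lo] <= thresh:
                prev = 0
            pi[b] = prev
    # exact integer numerator: avoids float cancellation at p ~ 1e-12
    total = comb(N, B)
    return (total - pi[B]) / total


def ranked_bin_enrichment(
    feature_counts,
    membership_labels,
    *,
    seed: int | None = None,
    direction: str = "descending",
    compute_exact: bool = True,
) -> MHGResult:
    """mHG enrichment of labelled bins within the feature-count ranking.

    The natural genomic order of bins is first shuffled with the given seed to
    break ties between bins with identical counts, then bins are sorted by
    feature count (``descending`` puts feature-rich bins first; ``ascending``
    is also supported) and the induced binary label order is scored.
    """
    counts = np.asarray(feature_counts, dtype=float)
    labels = np.asarray(membership_labels, dtype=np.int64)
    if counts.shape != labels.shape:
        raise ValueError("counts and labels must be aligned")
    if direction not in ("descending", "ascending"):
        raise ValueError(f"unknown direction {direction!r}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(counts))
    counts, labels = counts[perm], labels[perm]
    key = -counts if direction == "descending" else counts
    order = np.argsort(key, kind="stable")
    res = mhg_statistic(labels[order])
    res.direction = direction
    if compute_exact:
        res.p_exact = mhg_exact_pvalue(res.mhg, res.N, res.B)
    return res


def spearman_track_correlation(track_a, track_b) -> tuple[float, float]:
    """Spearman rank correlation between two binned tracks on identical bins.

    Bins where either track is missing (NaN) are dropped pairwise; fewer than
    three complete bins is an error.
    """
    a = np.asarray(track_a, dtype=float)
    b = np.asarray(track_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tracks must share the same bins")
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete bins")
    rho, p = stats.spearmanr(a[ok], b[ok])
    return float(rho), float(p)
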